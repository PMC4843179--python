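"""Area-level socio-economic deprivation index.

A composite score of socio-economic disadvantage built from a declared set
of census variables (family composition, employment, education, household
size, age composition, housing, density, migration). Each variable carries a
*deprivation direction* (+1: higher value means more deprived); variables
are z-standardised across area units, sign-flipped to the deprivation
direction, and combined either as an equal/explicitly weighted mean of
z-scores (default) or as the first principal component oriented to correlate
positively with the unemployment rate. Both are standard deprivation-index
constructions; the variable set and directions live in a metadata file so a
locally calibrated index can be swapped in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "load_variable_metadata",
    "standardise_variables",
    "compute_ses_index",
    "SESResult",
]


def load_variable_metadata(source: str | Path | None = None) -> pd.DataFrame:
    """Variable metadata table (name, units, direction); packaged set by default."""
    path = (
        Path(source)
        if source is not None
        else Path(str(resources.files("mhatlas").joinpath("data/ses_variables.json")))
    )
    with open(path) as fh:
        raw = json.load(fh)
    df = pd.DataFrame(raw["variables"]).set_index("name")
    if not set(df["direction"].unique()) <= {1, -1}:
        raise ValueError("variable directions must be +1 or -1")
    return df


@dataclass
class SESResult:
    """Deprivation scores and ranks per area unit (rank 1 = most deprived)."""

    scores: pd.Series
    ranks: pd.Series
    method: str
    variables_used: list[str]
    info: dict = field(default_factory=dict)


def standardise_variables(
    units: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    ddof: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Direction-signed z-scores of census variables across area units.

    ``units`` is indexed by unit id with one column per declared variable.
    Missing values are mean-imputed (recorded in the returned info dict);
    all-missing or zero-variance variables are dropped with a warning.
    Positive z means more deprived on every retained variable.
    """
    if len(units) < 2:
        raise ValueError("at least two area units are required for standardisation")
    metadata = metadata if metadata is not None else load_variable_metadata()
    info: dict = {"imputed": {}, "dropped": []}
    cols = [c for c in units.columns if c in metadata.index]
    z = {}
    constant: dict[str, pd.Series] = {}
    for name in cols:
        x = pd.to_numeric(units[name], errors="coerce").astype(float)
        if x.isna().all():
            warnings.warn(f"variable {name!r} all missing; dropped", UserWarning, stacklevel=2)
            info["dropped"].append(name)
            continue
        if x.isna().any():
            info["imputed"][name] = x.index[x.isna()].tolist()
            x = x.fillna(x.mean())
        sd = x.std(ddof=ddof)
        # relative tolerance: identical raw values can leave an O(eps) std
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
            constant[name] = pd.Series(0.0, index=units.index)
            continue
        direction = int(metadata.loc[name, "direction"])
        z[name] = direction * (x - x.mean()) / sd
    if not z and constant:
        # every variable is constant across units: the units are
        # indistinguishable, so all z-scores (and scores) are 0
        z = constant
    elif constant:
        for name in constant:
            warnings.warn(
                f"variable {name!r} has zero variance; dropped", UserWarning, stacklevel=2
            )
            info["dropped"].append(name)
    zdf = pd.DataFrame(z, index=units.index)
    if zdf.empty:
        raise ValueError("no usable variables after dropping")
    return zdf, info


def compute_ses_index(
    units: pd.DataFrame,
    method: str = "zmean",
    weights: Mapping[str, float] | None = None,
    metadata: pd.DataFrame | None = None,
    ddof: int = 1,
) -> SESResult:
    """Composite deprivation index across area units.

    ``method='zmean'`` averages the direction-signed z-scores (optionally
    weighted); ``method='pca_first_component'`` projects units on the first
    principal component of the standardised table, oriented so the score
    correlates positively with the unemployment rate (more deprived = higher).
    """
    zdf, info = standardise_variables(units, metadata=metadata, ddof=ddof)

    if method == "zmean":
        if weights is not None:
            w = pd.Series({k: float(v) for k, v in weights.items()}).reindex(zdf.columns).fillna(0.0)
            if w.sum() <= 0:
                raise ValueError("weights must sum to a positive value")
        else:
            w = pd.Series(1.0, index=zdf.columns)
        scores = (zdf * w).sum(axis=1) / w.sum()
    elif method == "pca_first_component":
        X = zdf.to_numpy(dtype=float)
        # columns are already centred; first right singular vector = first PC
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        pc1 = vt[0]
        scores = pd.Series(X @ pc1, index=zdf.index)
        anchor = zdf["unemployment_rate"] if "unemployment_rate" in zdf else zdf.mean(axis=1)
        if scores.std(ddof=0) > 0 and np.corrcoef(scores, anchor)[0, 1] < 0:
            scores = -scores
        info["explained_variance_share"] = (
            float(np.var(scores.to_numpy())) / float(np.var(X, axis=0).sum())
            if np.var(X, axis=0).sum() > 0
            else float("nan")
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.isfinite(scores).all():
        raise ValueError("non-finite deprivation scores")
    ranks = scores.rank(ascending=False, method="first").astype(int)
    return SESResult(
        scores=scores,
        ranks=ranks,
        method=method,
        variables_used=list(zdf.columns),
        info=info,
    )
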
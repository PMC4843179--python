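"""Multi-judge agreement statistics for categorical service-code ratings.

Quality control for coder training: several evaluators code the same set of
case vignettes with main-type-of-care codes, and agreement is summarised as
raw pairwise proportion agreement — the grand mean over all rater pairs and,
per rater, the mean agreement with each of the remaining raters. Agreement
against a gold standard is reported per item and banded
(poor/fair/good/excellent). A chance-corrected multi-rater statistic
(Fleiss' kappa) is available as an optional, non-canonical method.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .taxonomy import CodeRegistry, branch_group

__all__ = [
    "AgreementResult",
    "GoldAgreementResult",
    "multi_rater_agreement",
    "gold_standard_agreement",
    "band_agreement",
    "fleiss_kappa",
    "DEFAULT_BAND_THRESHOLDS",
]

DEFAULT_BAND_THRESHOLDS = (0.40, 0.60, 0.75)
_BANDS = ("poor", "fair", "good", "excellent")


@dataclass
class AgreementResult:
    """Pairwise proportion agreement: grand mean, per rater, per pair."""

    overall: float
    per_rater: pd.Series
    pairwise: pd.DataFrame
    match_level: str
    dropped_items: list[str] = field(default_factory=list)


def _check_ratings(ratings: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    if ratings.shape[0] < 2:
        raise ValueError("at least two raters are required")
    if ratings.shape[1] < 1:
        raise ValueError("at least one item is required")
    all_missing = [c for c in ratings.columns if ratings[c].isna().all()]
    if all_missing:
        warnings.warn(
            f"items with no ratings dropped: {all_missing}", UserWarning, stacklevel=3
        )
        ratings = ratings.drop(columns=all_missing)
        if ratings.shape[1] == 0:
            raise ValueError("no rated items left")
    return ratings, all_missing


def _matchable(ratings: pd.DataFrame, match_level: str) -> pd.DataFrame:
    if match_level == "exact":
        return ratings
    if match_level == "branch":
        return ratings.map(lambda c: branch_group(str(c)) if pd.notna(c) else c)
    raise ValueError(f"unknown match level {match_level!r}")


def multi_rater_agreement(
    ratings: pd.DataFrame, match_level: str = "exact"
) -> AgreementResult:
    """Raw pairwise proportion agreement between all raters.

    ``ratings`` has one row per rater and one column per item; cells are code
    strings (missing cells are excluded pairwise). ``match_level='branch'``
    scores two codes as agreeing when their main branch letters match.
    The overall statistic equals the mean of the per-rater means exactly.
    """
    ratings, dropped = _check_ratings(ratings)
    coded = _matchable(ratings, match_level)

    raters = list(coded.index)
    pairwise = pd.DataFrame(np.nan, index=raters, columns=raters, dtype=float)
    for a, b in itertools.combinations(raters, 2):
        ra, rb = coded.loc[a], coded.loc[b]
        both = ra.notna() & rb.notna()
        if both.sum() == 0:
            continue  # no overlapping items: pair excluded
        p = float((ra[both] == rb[both]).mean())
        pairwise.at[a, b] = pairwise.at[b, a] = p

    per_rater = pairwise.mean(axis=1, skipna=True)
    overall = float(per_rater.mean())
    return AgreementResult(
        overall=overall,
        per_rater=per_rater,
        pairwise=pairwise,
        match_level=match_level,
        dropped_items=dropped,
    )


def band_agreement(
    value: float, thresholds: tuple[float, float, float] = DEFAULT_BAND_THRESHOLDS
) -> str:
    """Band a proportion as poor/fair/good/excellent; a boundary value goes
    to the higher band."""
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"agreement proportion {value} not in [0, 1]")
    if len(thresholds) != 3 or any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be three ascending cut points, got {thresholds}")
    idx = sum(value >= t for t in thresholds)
    return _BANDS[idx]


@dataclass
class GoldAgreementResult:
    """Per-item agreement with a gold standard plus banded summary."""

    per_item: pd.Series  # item -> proportion of raters matching gold
    bands: pd.Series  # item -> band name
    band_shares: dict[str, float]  # band -> share of items
    thresholds: tuple[float, float, float]


def gold_standard_agreement(
    ratings: pd.DataFrame,
    gold: Mapping[str, str],
    thresholds: tuple[float, float, float] = DEFAULT_BAND_THRESHOLDS,
    match_level: str = "exact",
    registry: CodeRegistry | None = None,
) -> GoldAgreementResult:
    """Proportion of raters matching the gold code, per item, with bands."""
    ratings, _ = _check_ratings(ratings)
    missing_gold = [c for c in ratings.columns if c not in gold]
    if missing_gold:
        raise ValueError(f"gold standard undefined for items: {missing_gold}")
    if registry is not None:
        for item, code in gold.items():
            registry.get(str(code))  # raises UnknownCodeError if absent
    coded = _matchable(ratings, match_level)
    per_item = {}
    for item in coded.columns:
        g = gold[item]
        g = branch_group(str(g)) if match_level == "branch" else str(g)
        col = coded[item].dropna()
        per_item[item] = float((col == g).mean())
    per_item = pd.Series(per_item, name="gold_agreement")
    bands = per_item.map(lambda v: band_agreement(v, thresholds))
    shares = {b: float((bands == b).mean()) for b in _BANDS}
    return GoldAgreementResult(
        per_item=per_item, bands=bands, band_shares=shares, thresholds=thresholds
    )


def fleiss_kappa(ratings: pd.DataFrame) -> float:
    """Chance-corrected multi-rater agreement (Fleiss' kappa).

    Optional, non-canonical summary alongside the raw proportion agreement;
    requires a complete ratings matrix (no missing cells).
    """
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _fleiss

    if ratings.isna().any().any():
        raise ValueError("Fleiss' kappa requires a complete ratings matrix")
    # statsmodels expects subjects (items) in rows, raters aggregated to counts
    table, _ = aggregate_raters(ratings.T.to_numpy())
    return float(_fleiss(table))
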
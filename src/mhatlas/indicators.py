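"""Provision indicators standardised per 100,000 adult population.

Four indicator families are computed per study area (and per catchment when
zoning is available):

* availability — count of principal main types of care per 100,000 adults,
  in total and by taxonomy branch;
* placement capacity — hospital/residential beds and structured day-care
  places per 100,000 adults;
* workforce — clinical staff in full-time equivalents (FTE) per 100,000
  adults, in total and by professional group;
* utilisation — admissions and outpatient contacts per 100,000 adults, mean
  length of stay (bed-days per admission) and mean visits per user.

The adult denominator defaults to the 18+ population (18–64 plus 65 and
older) and can be restricted to 18–64. Rates for a catchment use that
catchment's own population; a pooled rate therefore equals the population
-weighted mean of the catchment rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory import BSIC, STAFF_GROUPS, Service
from .taxonomy import branch_group

__all__ = [
    "AGE_BANDS",
    "StudyArea",
    "availability_rate",
    "capacity_rates",
    "workforce_rates",
    "utilisation_rates",
    "INDICATOR_COLUMNS",
]

AGE_BANDS = ("0-17", "18-64", "65+")
INDICATOR_COLUMNS = [
    "area_id",
    "catchment_id",
    "indicator",
    "group",
    "numerator",
    "denominator",
    "value",
    "rate_per_100k",
]

SCALE = 100_000.0


class ZeroDenominatorError(ValueError):
    pass


class InconsistencyError(ValueError):
    pass


@dataclass
class StudyArea:
    """Denominators: population by sex and age band per area unit, plus zoning."""

    id: str
    name: str = ""
    population: pd.DataFrame = field(default_factory=pd.DataFrame)
    area_km2: float = float("nan")
    zoning: dict[str, str] | None = None  # unit_id -> catchment_id

    def __post_init__(self) -> None:
        required = {"unit_id", "sex", "age_band", "population"}
        missing = required - set(self.population.columns)
        if missing:
            raise ValueError(f"population table missing columns {sorted(missing)}")
        bands = set(self.population["age_band"].unique())
        if not bands <= set(AGE_BANDS):
            raise ValueError(f"unknown age bands {sorted(bands - set(AGE_BANDS))}")
        if (self.population["population"] < 0).any():
            raise ValueError("negative population counts")

    def adult_population(self, denominator: str = "18+") -> float:
        """Adult population: 18+ by default, or 18-64 only."""
        bands = ("18-64", "65+") if denominator == "18+" else ("18-64",)
        mask = self.population["age_band"].isin(bands)
        return float(self.population.loc[mask, "population"].sum())

    def total_population(self) -> float:
        return float(self.population["population"].sum())

    def catchment_adult_population(self, denominator: str = "18+") -> dict[str, float]:
        """Adult population per catchment via the unit->catchment zoning map."""
        if self.zoning is None:
            return {}
        bands = ("18-64", "65+") if denominator == "18+" else ("18-64",)
        sub = self.population[self.population["age_band"].isin(bands)].copy()
        sub["catchment_id"] = sub["unit_id"].map(self.zoning)
        out = sub.dropna(subset=["catchment_id"]).groupby("catchment_id")["population"].sum()
        return {str(k): float(v) for k, v in out.items()}


def _rate(numerator: float, denominator: float) -> float:
    return numerator / denominator * SCALE


def _row(area_id, catchment_id, indicator, group, num, den, value=None, rate=None):
    if rate is None and den is not None and den > 0 and num is not None:
        rate = _rate(num, den)
    if value is None:
        value = rate
    return {
        "area_id": area_id,
        "catchment_id": catchment_id,
        "indicator": indicator,
        "group": group,
        "numerator": num,
        "denominator": den,
        "value": value,
        "rate_per_100k": rate,
    }


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=INDICATOR_COLUMNS)
    return df.sort_values(["indicator", "catchment_id", "group"], na_position="first").reset_index(
        drop=True
    )


def _adults_or_raise(area: StudyArea, denominator: str) -> float:
    adults = area.adult_population(denominator)
    if adults <= 0:
        raise ZeroDenominatorError(f"area {area.id}: adult population is zero")
    return adults


def availability_rate(
    bsics: Iterable[BSIC],
    area: StudyArea,
    level: str = "branch",
    denominator: str = "18+",
) -> pd.DataFrame:
    """Availability of main types of care per 100,000 adults.

    Each BSIC is counted once through its principal MTC; ``level`` chooses
    the grouping of the per-type rows ('branch', 'code' or 'total').
    Branch rates therefore sum exactly to the total rate.
    """
    bsics = list(bsics)
    uncoded = [b.id for b in bsics if not b.mtc_codes]
    if uncoded:
        raise ValueError(f"uncoded BSICs: {uncoded}")
    adults = _adults_or_raise(area, denominator)

    rows = [_row(area.id, None, "availability", "total", float(len(bsics)), adults)]
    if level in ("branch", "code"):
        key = (lambda b: branch_group(b.principal_code)) if level == "branch" else (
            lambda b: b.principal_code
        )
        counts: dict[str, int] = {}
        for b in bsics:
            counts[key(b)] = counts.get(key(b), 0) + 1
        for group in sorted(counts):
            rows.append(_row(area.id, None, "availability", group, float(counts[group]), adults))
    elif level != "total":
        raise ValueError(f"unknown level {level!r}")
    return _finish(rows)


def _per_catchment(
    bsics: Sequence[BSIC],
    area: StudyArea,
    service_catchments: Mapping[str, str] | None,
    denominator: str,
    numerator_of,
    indicator: str,
    group: str,
    rows: list[dict],
) -> None:
    """Append per-catchment rows for one indicator when zoning is available."""
    if not service_catchments or area.zoning is None:
        return
    catch_adults = area.catchment_adult_population(denominator)
    by_catch: dict[str, float] = {c: 0.0 for c in catch_adults}
    for b in bsics:
        c = service_catchments.get(b.service_id)
        if c is None:
            continue
        by_catch[c] = by_catch.get(c, 0.0) + numerator_of(b)
    for c in sorted(by_catch):
        den = catch_adults.get(c)
        if den is None or den <= 0:
            raise ZeroDenominatorError(f"catchment {c}: adult population missing or zero")
        rows.append(_row(area.id, c, indicator, group, by_catch[c], den))


def capacity_rates(
    bsics: Iterable[BSIC],
    area: StudyArea,
    service_catchments: Mapping[str, str] | None = None,
    denominator: str = "18+",
) -> pd.DataFrame:
    """Placement capacity: residential beds and structured day places per 100,000.

    Beds are counted on BSICs whose principal code is in the residential (R)
    branch and places on the day-care (D) branch; beds reported elsewhere
    raise a validation warning and are not counted.
    """
    bsics = list(bsics)
    adults = _adults_or_raise(area, denominator)

    residential = []
    day = []
    for b in bsics:
        branch = branch_group(b.principal_code) if b.principal_code else None
        if b.beds > 0 and branch != "R":
            warnings.warn(
                f"BSIC {b.id}: {b.beds} beds reported on non-residential principal "
                f"code {b.principal_code}; not counted",
                UserWarning,
                stacklevel=2,
            )
        if branch == "R":
            residential.append(b)
        if branch == "D":
            day.append(b)

    beds = float(sum(b.beds for b in residential))
    places = float(sum(b.day_places for b in day))
    rows = [
        _row(area.id, None, "beds", "total", beds, adults),
        _row(area.id, None, "day_places", "total", places, adults),
    ]
    _per_catchment(
        residential, area, service_catchments, denominator,
        lambda b: float(b.beds), "beds", "total", rows,
    )
    _per_catchment(
        day, area, service_catchments, denominator,
        lambda b: float(b.day_places), "day_places", "total", rows,
    )
    return _finish(rows)


def workforce_rates(
    bsics: Iterable[BSIC],
    area: StudyArea,
    service_catchments: Mapping[str, str] | None = None,
    denominator: str = "18+",
) -> pd.DataFrame:
    """Workforce capacity in FTE per 100,000 adults, total and by profession."""
    bsics = list(bsics)
    adults = _adults_or_raise(area, denominator)

    rows = [
        _row(area.id, None, "workforce_fte", "total",
             float(sum(b.total_fte() for b in bsics)), adults)
    ]
    for group in STAFF_GROUPS:
        total = float(sum(b.staff_fte.get(group, 0.0) for b in bsics))
        rows.append(_row(area.id, None, "workforce_fte", group, total, adults))
    _per_catchment(
        bsics, area, service_catchments, denominator,
        lambda b: b.total_fte(), "workforce_fte", "total", rows,
    )
    return _finish(rows)


def utilisation_rates(
    bsics: Iterable[BSIC],
    area: StudyArea,
    denominator: str = "18+",
) -> pd.DataFrame:
    """Utilisation: admission/contact rates, mean stay, mean visits per user.

    Missing utilisation counts propagate as missing values (NaN) — they are
    data gaps, never zeros. An admission count of zero alongside positive
    bed-days is inconsistent and raises.
    """
    bsics = list(bsics)
    adults = _adults_or_raise(area, denominator)

    def collected(fields: tuple[str, ...]) -> list[tuple[float, ...]]:
        out = []
        for b in bsics:
            vals = tuple(b.utilisation.get(f) for f in fields)
            if all(v is not None for v in vals):
                out.append(tuple(float(v) for v in vals))
        return out

    for b in bsics:
        adm = b.utilisation.get("admissions")
        bd = b.utilisation.get("bed_days")
        if adm == 0 and bd is not None and bd > 0:
            raise InconsistencyError(
                f"BSIC {b.id}: {bd} bed-days reported with zero admissions"
            )

    rows: list[dict] = []

    adm = [v[0] for v in collected(("admissions",))]
    rows.append(
        _row(area.id, None, "admissions", "total",
             float(sum(adm)) if adm else None, adults,
             rate=None if adm else float("nan"),
             value=None if adm else float("nan"))
    )
    con = [v[0] for v in collected(("contacts",))]
    rows.append(
        _row(area.id, None, "contacts", "total",
             float(sum(con)) if con else None, adults,
             rate=None if con else float("nan"),
             value=None if con else float("nan"))
    )

    stay = collected(("admissions", "bed_days"))
    total_adm = sum(v[0] for v in stay)
    mls = (sum(v[1] for v in stay) / total_adm) if total_adm > 0 else float("nan")
    rows.append(
        _row(area.id, None, "mean_length_of_stay", "total",
             sum(v[1] for v in stay) if stay else None,
             total_adm if total_adm > 0 else None,
             value=mls, rate=float("nan"))
    )

    visits = collected(("contacts", "users"))
    total_users = sum(v[1] for v in visits)
    mvu = (sum(v[0] for v in visits) / total_users) if total_users > 0 else float("nan")
    rows.append(
        _row(area.id, None, "mean_visits_per_user", "total",
             sum(v[0] for v in visits) if visits else None,
             total_users if total_users > 0 else None,
             value=mvu, rate=float("nan"))
    )
    return _finish(rows)


def all_indicators(
    bsics: Iterable[BSIC],
    area: StudyArea,
    service_catchments: Mapping[str, str] | None = None,
    denominator: str = "18+",
    level: str = "branch",
) -> pd.DataFrame:
    """Concatenate the four indicator families into one table."""
    bsics = list(bsics)
    parts = [
        availability_rate(bsics, area, level=level, denominator=denominator),
        capacity_rates(bsics, area, service_catchments, denominator=denominator),
        workforce_rates(bsics, area, service_catchments, denominator=denominator),
        utilisation_rates(bsics, area, denominator=denominator),
    ]
    return pd.concat(parts, ignore_index=True)
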
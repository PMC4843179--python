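"""Spatial accessibility of services from origin–destination travel times.

Implements catchment-style accessibility analysis on a precomputed
origin–destination (OD) travel-time matrix:

* isochrone coverage — how much of the population lives within a travel-time
  threshold of its nearest service (and how much lives beyond it);
* nearest-provider statistics — per-unit nearest travel time,
  population-weighted mean impedance, and the provider-to-population ratio;
* the enhanced two-step floating catchment area (E2SFCA) — step 1 computes a
  supply-to-weighted-demand ratio R_j for each service, step 2 sums those
  ratios back onto each population unit, both over discrete travel-time
  zones weighted by a Gaussian distance-decay function.

Routing engines are out of scope: matrices come in precomputed, or from a
great-circle (haversine) fallback at a constant travel speed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationUnit",
    "SupplySite",
    "TravelTimeMatrix",
    "ZoneScheme",
    "AccessibilitySurface",
    "CoverageReport",
    "NearestProviderSummary",
    "gaussian_zone_weights",
    "e2sfca",
    "isochrone_coverage",
    "nearest_provider_stats",
    "euclidean_ttm",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class PopulationUnit:
    """Demand point: the potential users of services at one location."""

    id: str
    lon: float
    lat: float
    population: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"unit {self.id}: negative population")
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"unit {self.id}: non-finite coordinates")


@dataclass(frozen=True)
class SupplySite:
    """Supply point: a service with a capacity (beds, places or FTE)."""

    id: str
    lon: float
    lat: float
    capacity: float
    mtc_branch: str | None = None

    def __post_init__(self) -> None:
        if self.capacity < 0:
            raise ValueError(f"site {self.id}: negative capacity")


class TravelTimeMatrix:
    """Origin-destination travel times in minutes; NaN marks unreachable pairs."""

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("travel times must be non-negative")
        self.frame = frame.astype(float).rename_axis(index="origin_id", columns="dest_id")

    @classmethod
    def from_long(cls, records: pd.DataFrame) -> "TravelTimeMatrix":
        """Build from a long table with columns origin_id, dest_id, minutes."""
        required = {"origin_id", "dest_id", "minutes"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"OD table missing columns {sorted(missing)}")
        dup = records.duplicated(subset=["origin_id", "dest_id"])
        if dup.any():
            pairs = records.loc[dup, ["origin_id", "dest_id"]].values.tolist()
            raise ValueError(f"duplicate OD pairs: {pairs}")
        minutes = pd.to_numeric(records["minutes"], errors="raise")
        if (minutes.dropna() < 0).any():
            raise ValueError("negative travel times in OD table")
        frame = records.assign(minutes=minutes).pivot(
            index="origin_id", columns="dest_id", values="minutes"
        )
        return cls(frame.sort_index().sort_index(axis=1))

    def to_long(self) -> pd.DataFrame:
        long = (
            self.frame.rename_axis("origin_id")
            .reset_index()
            .melt(id_vars="origin_id", var_name="dest_id", value_name="minutes")
            .dropna(subset=["minutes"])
            .sort_values(["origin_id", "dest_id"])
            .reset_index(drop=True)
        )
        return long

    def minutes(self, origin: str, dest: str) -> float:
        try:
            return float(self.frame.at[origin, dest])
        except KeyError:
            return float("nan")

    def submatrix(self, origins: Sequence[str], dests: Sequence[str]) -> np.ndarray:
        return (
            self.frame.reindex(index=list(origins), columns=list(dests))
            .to_numpy(dtype=float)
        )

    @property
    def origins(self) -> list[str]:
        return list(self.frame.index)

    @property
    def destinations(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class ZoneScheme:
    """Discrete travel-time zones with distance-decay weights.

    ``breaks`` are ascending upper zone bounds ending at the catchment limit
    t_max; zone r covers (breaks[r-1], breaks[r]] (the first from 0).
    Weights must be non-increasing from at most 1 down to at least 0.
    """

    breaks: tuple[float, ...]
    weights: tuple[float, ...]
    beta: float | None = None

    def __post_init__(self) -> None:
        if not self.breaks:
            raise ValueError("at least one zone break required")
        if any(b <= 0 for b in self.breaks) or any(
            b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])
        ):
            raise ValueError(f"zone breaks must be positive and strictly ascending: {self.breaks}")
        if len(self.weights) != len(self.breaks):
            raise ValueError("one weight per zone required")
        if any(not (0.0 <= w <= 1.0) for w in self.weights):
            raise ValueError("zone weights must lie in [0, 1]")
        if any(w2 >= w1 for w1, w2 in zip(self.weights, self.weights[1:])):
            raise ValueError("zone weights must be strictly decreasing")

    @property
    def t_max(self) -> float:
        return self.breaks[-1]

    def decay(self, minutes: float) -> float:
        """Continuous Gaussian decay exp(-t^2/beta): 1 at t=0, w_min at t_max.

        Only available for schemes built by :func:`gaussian_zone_weights`;
        zone weights are this function evaluated at zone midpoints.
        """
        if self.beta is None:
            raise ValueError("decay parameter beta is not set for this scheme")
        return math.exp(-(float(minutes) ** 2) / self.beta)

    def weight(self, minutes: np.ndarray | float) -> np.ndarray | float:
        """Decay weight for travel time(s); 0 beyond t_max or unreachable."""
        t = np.asarray(minutes, dtype=float)
        idx = np.searchsorted(np.asarray(self.breaks), t, side="left")
        w = np.append(np.asarray(self.weights), 0.0)  # overflow zone -> 0
        out = np.where(np.isnan(t), 0.0, w[np.minimum(idx, len(self.breaks))])
        return out if out.shape else float(out)


def gaussian_zone_weights(
    breaks: Sequence[float], w_min: float = 0.01
) -> ZoneScheme:
    """Gaussian distance-decay weights per travel-time zone.

    The decay parameter beta solves exp(-t_max^2 / beta) = w_min, so the
    Gaussian equals 1 at t = 0 and w_min at the catchment limit. Each zone's
    weight is the Gaussian evaluated at the zone midpoint.
    """
    if not (0.0 < w_min < 1.0):
        raise ValueError(f"w_min must be in (0, 1), got {w_min}")
    breaks = tuple(float(b) for b in breaks)
    t_max = breaks[-1]
    beta = -(t_max**2) / math.log(w_min)
    lowers = (0.0,) + breaks[:-1]
    midpoints = tuple((lo + hi) / 2.0 for lo, hi in zip(lowers, breaks))
    weights = tuple(math.exp(-(m**2) / beta) for m in midpoints)
    return ZoneScheme(breaks=breaks, weights=weights, beta=beta)


@dataclass
class AccessibilitySurface:
    """E2SFCA output: per-unit accessibility A_i and per-site ratio R_j."""

    scores: pd.Series  # unit id -> A_i (capacity per person)
    ratios: pd.Series  # site id -> R_j (NaN when the site reaches no demand)
    excluded_sites: list[str] = field(default_factory=list)


def _as_demand_arrays(demand: Sequence[PopulationUnit]):
    ids = [u.id for u in demand]
    pop = np.array([u.population for u in demand], dtype=float)
    return ids, pop


def e2sfca(
    supply: Sequence[SupplySite],
    demand: Sequence[PopulationUnit],
    ttm: TravelTimeMatrix,
    zones: ZoneScheme,
) -> AccessibilitySurface:
    """Enhanced two-step floating catchment area accessibility.

    Step 1: each site's ratio R_j = S_j / sum_i P_i W(d_ij) over population
    units within t_max. Step 2: each unit's score A_i = sum_j R_j W(d_ij)
    over sites within t_max. Sites whose weighted demand is zero get an
    undefined ratio, contribute nothing, and are reported in
    ``excluded_sites``. By construction sum_i P_i A_i = sum_j S_j over the
    contributing sites.
    """
    supply = list(supply)
    demand = list(demand)
    if not supply or not demand:
        raise ValueError("supply and demand must both be non-empty")
    unit_ids, pop = _as_demand_arrays(demand)
    site_ids = [s.id for s in supply]
    cap = np.array([s.capacity for s in supply], dtype=float)

    minutes = ttm.submatrix(unit_ids, site_ids)  # units x sites
    W = np.asarray(zones.weight(minutes), dtype=float)
    if not W.any():
        warnings.warn(
            "no population unit is within the catchment of any site; all scores are 0",
            UserWarning,
            stacklevel=2,
        )

    weighted_demand = pop @ W  # per site
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(weighted_demand > 0, cap / weighted_demand, np.nan)
    excluded = [site_ids[j] for j in range(len(site_ids)) if weighted_demand[j] <= 0]
    if excluded:
        warnings.warn(
            f"sites with zero weighted demand excluded from accessibility: {excluded}",
            UserWarning,
            stacklevel=2,
        )
    contrib = np.nan_to_num(ratios, nan=0.0)
    scores = W @ contrib
    return AccessibilitySurface(
        scores=pd.Series(scores, index=pd.Index(unit_ids, name="unit_id"), name="accessibility"),
        ratios=pd.Series(ratios, index=pd.Index(site_ids, name="site_id"), name="ratio"),
        excluded_sites=excluded,
    )


@dataclass
class CoverageReport:
    """Isochrone coverage: population within/beyond a travel-time threshold."""

    threshold_minutes: float
    covered_population: float
    total_population: float
    nearest_minutes: pd.Series

    @property
    def share_covered(self) -> float:
        return self.covered_population / self.total_population if self.total_population else 0.0

    @property
    def uncovered_population(self) -> float:
        return self.total_population - self.covered_population

    @property
    def share_uncovered(self) -> float:
        return 1.0 - self.share_covered


def _nearest_minutes(
    demand: Sequence[PopulationUnit], supply: Sequence[SupplySite], ttm: TravelTimeMatrix
) -> tuple[pd.Series, pd.Series]:
    unit_ids = [u.id for u in demand]
    site_ids = sorted(s.id for s in supply)  # stable id order breaks ties
    arr = ttm.submatrix(unit_ids, site_ids)
    filled = np.where(np.isnan(arr), np.inf, arr)
    j = filled.argmin(axis=1)  # first (lowest id) among ties
    best = filled[np.arange(len(unit_ids)), j]
    nearest = pd.Series(np.where(np.isfinite(best), best, np.nan), index=unit_ids)
    nearest_site = pd.Series(
        [site_ids[jj] if np.isfinite(b) else None for jj, b in zip(j, best)], index=unit_ids
    )
    return nearest, nearest_site


def isochrone_coverage(
    supply: Sequence[SupplySite],
    demand: Sequence[PopulationUnit],
    ttm: TravelTimeMatrix,
    threshold_minutes: float,
) -> CoverageReport:
    """Population living within ``threshold_minutes`` of the nearest service."""
    if threshold_minutes <= 0:
        raise ValueError("threshold must be positive")
    demand = list(demand)
    total = float(sum(u.population for u in demand))
    if not supply:
        warnings.warn("no qualifying services; coverage is zero", UserWarning, stacklevel=2)
        nearest = pd.Series(np.nan, index=[u.id for u in demand])
        return CoverageReport(threshold_minutes, 0.0, total, nearest)
    nearest, _ = _nearest_minutes(demand, supply, ttm)
    covered = float(
        sum(u.population for u, t in zip(demand, nearest) if np.isfinite(t) and t <= threshold_minutes)
    )
    return CoverageReport(threshold_minutes, covered, total, nearest)


@dataclass
class NearestProviderSummary:
    nearest_minutes: pd.Series
    nearest_site: pd.Series
    weighted_mean_minutes: float
    provider_to_population_ratio: float  # total capacity per 100,000 people
    unreachable_units: list[str]


def nearest_provider_stats(
    demand: Sequence[PopulationUnit],
    supply: Sequence[SupplySite],
    ttm: TravelTimeMatrix,
) -> NearestProviderSummary:
    """Nearest travel time per unit, population-weighted mean impedance and
    provider-to-population ratio (capacity per 100,000)."""
    demand = list(demand)
    supply = list(supply)
    if not demand or not supply:
        raise ValueError("demand and supply must both be non-empty")
    nearest, nearest_site = _nearest_minutes(demand, supply, ttm)
    pop = pd.Series({u.id: u.population for u in demand})
    reachable = nearest.notna()
    unreachable = nearest.index[~reachable].tolist()
    if unreachable:
        warnings.warn(
            f"units unreachable from every site excluded from the weighted mean: {unreachable}",
            UserWarning,
            stacklevel=2,
        )
    w = pop[reachable]
    weighted_mean = float((nearest[reachable] * w).sum() / w.sum()) if w.sum() > 0 else float("nan")
    total_pop = pop.sum()
    ratio = float(sum(s.capacity for s in supply) / total_pop * 100_000) if total_pop > 0 else float("nan")
    return NearestProviderSummary(
        nearest_minutes=nearest,
        nearest_site=nearest_site,
        weighted_mean_minutes=weighted_mean,
        provider_to_population_ratio=ratio,
        unreachable_units=unreachable,
    )


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 lon/lat points (array-aware)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return _EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(a))


def euclidean_ttm(
    demand: Sequence[PopulationUnit],
    supply: Sequence[SupplySite],
    speed_kmh: float,
) -> TravelTimeMatrix:
    """Travel-time fallback: great-circle distance at a constant speed."""
    if speed_kmh <= 0:
        raise ValueError("speed must be positive")
    demand = list(demand)
    supply = list(supply)
    lon_u = np.array([u.lon for u in demand])[:, None]
    lat_u = np.array([u.lat for u in demand])[:, None]
    lon_s = np.array([s.lon for s in supply])[None, :]
    lat_s = np.array([s.lat for s in supply])[None, :]
    km = haversine_km(lon_u, lat_u, lon_s, lat_s)
    minutes = km / speed_kmh * 60.0
    frame = pd.DataFrame(minutes, index=[u.id for u in demand], columns=[s.id for s in supply])
    return TravelTimeMatrix(frame)
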
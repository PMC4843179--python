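"""Synthetic study areas, inventories and rating exercises.

Generates a complete, internally consistent study area — population units,
zoning, a coded service inventory with staff/capacity/utilisation, census
variables driven by a latent deprivation factor, and an origin–destination
travel-time matrix — so every pipeline stage is testable without external
data. Defaults mirror the comparative-mapping study conditions: a study
area of 200,000–1,500,000 inhabitants, three-quarters of care units
described by a single main type of care, and capacity/workforce rates
planted exactly so the indicator pipeline can recover them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .accessibility import PopulationUnit, SupplySite, TravelTimeMatrix, euclidean_ttm
from .indicators import AGE_BANDS, StudyArea
from .inventory import BSIC, STABILITY_CRITERIA, STAFF_GROUPS, Service
from .taxonomy import CodeRegistry, load_registry

__all__ = [
    "GeneratorConfig",
    "SyntheticStudyArea",
    "Vignette",
    "generate_study_area",
    "generate_ratings",
    "packaged_vignettes",
]

POPULATION_BAND = (200_000, 1_500_000)  # admissible total inhabitants
_DEFAULT_FTE_PER_100K = {
    "physicians": 10.0,
    "psychologists": 12.0,
    "nurses": 40.0,
    "social_workers": 15.0,
    "occupational_therapists": 8.0,
    "other_workers": 20.0,
}
# Share of BSIC principal codes per taxonomy branch.
_BRANCH_MIX = {"R": 0.30, "D": 0.25, "O": 0.35, "A": 0.05, "I": 0.025, "S": 0.025}

# Census variable generation: (base level, scale of the latent effect).
_CENSUS_SPECS = {
    "single_parent_families": (0.08, 0.02, 0.0, 1.0),
    "divorced_widowed": (0.12, 0.03, 0.0, 1.0),
    "employed_industry": (0.25, 0.05, 0.0, 1.0),
    "employed_services": (0.55, 0.05, 0.0, 1.0),
    "unemployment_rate": (0.10, 0.03, 0.0, 1.0),
    "tertiary_education_15plus": (0.20, 0.05, 0.0, 1.0),
    "mean_household_size": (2.5, 0.3, 1.0, 8.0),
    "households_1person": (0.30, 0.05, 0.0, 1.0),
    "households_5plus": (0.06, 0.02, 0.0, 1.0),
    "ageing_index": (120.0, 25.0, 0.0, np.inf),
    "dependency_ratio": (50.0, 8.0, 0.0, np.inf),
    "under5": (0.05, 0.01, 0.0, 1.0),
    "rented_accommodation": (0.25, 0.07, 0.0, 1.0),
    "population_density": (300.0, 120.0, 1.0, np.inf),
    "immigrants": (0.10, 0.04, 0.0, 1.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-conditions knobs of the synthetic generator."""

    seed: int = 42
    n_population_units: int = 60
    total_adult_population: int = 500_000
    n_services: int = 80
    n_bsics: int = 200
    single_mtc_fraction: float = 0.75
    beds_per_100k: float = 50.0
    places_per_100k: float = 30.0
    fte_per_100k: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FTE_PER_100K)
    )
    ses_noise_sd: float = 0.3
    speed_kmh: float = 50.0
    bbox: tuple[float, float, float, float] = (-1.0, 40.0, 0.0, 41.0)  # lon/lat box
    check_population_band: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.single_mtc_fraction <= 1.0):
            raise ValueError("single_mtc_fraction must be in [0, 1]")
        if self.beds_per_100k < 0 or self.places_per_100k < 0:
            raise ValueError("planted rates must be >= 0")
        if any(v < 0 for v in self.fte_per_100k.values()):
            raise ValueError("planted FTE rates must be >= 0")
        if self.n_population_units < 2 or self.n_services < 1 or self.n_bsics < self.n_services:
            raise ValueError("need >=2 units, >=1 service and n_bsics >= n_services")


@dataclass
class SyntheticStudyArea:
    """A full generated input bundle plus the planted ground truth."""

    area: StudyArea
    units: list[PopulationUnit]
    services: list[Service]
    bsics: list[BSIC]
    census: pd.DataFrame  # indexed by unit_id
    od: TravelTimeMatrix
    ground_truth: dict
    config: GeneratorConfig


def _integer_split(total: int, weights: np.ndarray) -> np.ndarray:
    """Split an integer total proportionally to weights, exactly (largest remainder)."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _exact_float_split(total: float, weights: np.ndarray) -> np.ndarray:
    """Split a float total by weights so the parts sum to the total exactly."""
    parts = weights / weights.sum() * total
    parts[-1] = total - parts[:-1].sum()
    return parts


def generate_study_area(
    config: GeneratorConfig | None = None, registry: CodeRegistry | None = None
) -> SyntheticStudyArea:
    """Generate a synthetic study area with planted, exactly recoverable rates.

    The same configuration (including seed) regenerates identical output.
    """
    config = config or GeneratorConfig()
    registry = registry or load_registry()
    rng = np.random.default_rng(config.seed)
    lon0, lat0, lon1, lat1 = config.bbox

    # --- population units (log-normal sizes scaled to the exact adult total)
    n = config.n_population_units
    unit_ids = [f"U{i:03d}" for i in range(1, n + 1)]
    lons = rng.uniform(lon0, lon1, size=n)
    lats = rng.uniform(lat0, lat1, size=n)
    adult_counts = _integer_split(
        config.total_adult_population, rng.lognormal(mean=0.0, sigma=1.0, size=n)
    )
    pop_rows = []
    children_total = 0
    for uid, adults in zip(unit_ids, adult_counts):
        a1864 = int(round(adults * 0.8))
        a65 = int(adults) - a1864
        child = int(round(adults * 0.28))
        children_total += child
        for band, count in (("0-17", child), ("18-64", a1864), ("65+", a65)):
            male = count // 2
            pop_rows.append({"unit_id": uid, "sex": "male", "age_band": band, "population": male})
            pop_rows.append(
                {"unit_id": uid, "sex": "female", "age_band": band, "population": count - male}
            )
    population = pd.DataFrame(pop_rows)
    total_inhabitants = config.total_adult_population + children_total
    if config.check_population_band and not (
        POPULATION_BAND[0] <= total_inhabitants <= POPULATION_BAND[1]
    ):
        raise ValueError(
            f"total population {total_inhabitants} outside the admissible band {POPULATION_BAND}"
        )

    # --- H3 zoning: two hospital catchments split at the median longitude
    median_lon = float(np.median(lons))
    zoning = {
        uid: ("H3-1" if lon <= median_lon else "H3-2") for uid, lon in zip(unit_ids, lons)
    }
    area = StudyArea(
        id="SYN1",
        name="Synthetic study area",
        population=population,
        area_km2=float(
            (lon1 - lon0) * 111.32 * np.cos(np.radians((lat0 + lat1) / 2)) * (lat1 - lat0) * 110.57
        ),
        zoning=zoning,
    )
    units = [
        PopulationUnit(id=uid, lon=float(lo), lat=float(la), population=float(ad))
        for uid, lo, la, ad in zip(unit_ids, lons, lats, adult_counts)
    ]

    # --- services
    svc_ids = [f"S{i:03d}" for i in range(1, config.n_services + 1)]
    svc_lons = rng.uniform(lon0, lon1, size=config.n_services)
    svc_lats = rng.uniform(lat0, lat1, size=config.n_services)
    services = [
        Service(
            id=sid,
            name=f"Synthetic service {sid}",
            governance="public",
            publicly_funded=True,
            universal_access=True,
            sector="health",
            lon=float(lo),
            lat=float(la),
            zoning_level="H3",
            catchment_id="H3-1" if lo <= median_lon else "H3-2",
            reference_year=2010,
            inside_study_area=True,
            target_group_tags=frozenset({"adult_mh"}),
        )
        for sid, lo, la in zip(svc_ids, svc_lons, svc_lats)
    ]

    # --- BSICs: branch mix, single-MTC share, planted capacity and staffing
    m = config.n_bsics
    bsic_ids = [f"B{i:04d}" for i in range(1, m + 1)]
    owner = list(svc_ids) + list(rng.choice(svc_ids, size=m - len(svc_ids), replace=True))

    branches = list(_BRANCH_MIX)
    branch_counts = _integer_split(m, np.array([_BRANCH_MIX[b] for b in branches]))
    branch_of = np.repeat(branches, branch_counts)
    rng.shuffle(branch_of)
    branch_pool = {b: [c.code for c in registry.branch_codes(b)] for b in branches}
    principals = [str(rng.choice(branch_pool[b])) for b in branch_of]

    n_multi = m - int(round(config.single_mtc_fraction * m))
    multi_idx = set(rng.choice(m, size=n_multi, replace=False).tolist())
    codes_per_bsic: list[list[str]] = []
    for i, principal in enumerate(principals):
        codes = [principal]
        if i in multi_idx:
            other_branches = [b for b in branches if b != branch_of[i]]
            ob = str(rng.choice(other_branches))
            codes.append(str(rng.choice(branch_pool[ob])))
        codes_per_bsic.append(codes)

    adults = float(config.total_adult_population)
    r_idx = [i for i in range(m) if branch_of[i] == "R"]
    d_idx = [i for i in range(m) if branch_of[i] == "D"]
    total_beds = int(round(config.beds_per_100k * adults / 100_000))
    total_places = int(round(config.places_per_100k * adults / 100_000))
    if total_beds > 0 and not r_idx:
        raise ValueError("planted beds but no residential BSICs generated")
    if total_places > 0 and not d_idx:
        raise ValueError("planted day places but no day-care BSICs generated")
    beds = np.zeros(m, dtype=int)
    places = np.zeros(m, dtype=int)
    if r_idx:
        beds[r_idx] = rng.multinomial(total_beds, np.full(len(r_idx), 1.0 / len(r_idx)))
    if d_idx:
        places[d_idx] = rng.multinomial(total_places, np.full(len(d_idx), 1.0 / len(d_idx)))

    fte = {g: np.zeros(m) for g in STAFF_GROUPS}
    for g in STAFF_GROUPS:
        total_g = config.fte_per_100k.get(g, 0.0) * adults / 100_000
        if total_g > 0:
            fte[g] = _exact_float_split(total_g, rng.dirichlet(np.ones(m)))

    bsics = []
    for i, bid in enumerate(bsic_ids):
        util: dict[str, float | None] = {
            "admissions": None, "contacts": None, "bed_days": None, "users": None,
        }
        if branch_of[i] == "R":
            admissions = int(rng.poisson(80)) + 1
            util["admissions"] = float(admissions)
            util["bed_days"] = float(admissions * int(rng.integers(5, 30)))
        if branch_of[i] in ("O", "D"):
            users = int(rng.poisson(350)) + 1
            util["users"] = float(users)
            util["contacts"] = float(users * int(rng.integers(2, 12)))
        bsics.append(
            BSIC(
                id=bid,
                service_id=str(owner[i]),
                stability={c: True for c in STABILITY_CRITERIA},
                mtc_codes=codes_per_bsic[i],
                beds=int(beds[i]),
                day_places=int(places[i]),
                staff_fte={g: float(fte[g][i]) for g in STAFF_GROUPS},
                utilisation=util,
            )
        )

    # --- census variables from a latent deprivation factor
    latent = rng.standard_normal(n)
    meta_dirs = {
        "single_parent_families": 1, "divorced_widowed": 1, "employed_industry": 1,
        "employed_services": -1, "unemployment_rate": 1, "tertiary_education_15plus": -1,
        "mean_household_size": 1, "households_1person": 1, "households_5plus": 1,
        "ageing_index": 1, "dependency_ratio": 1, "under5": 1,
        "rented_accommodation": 1, "population_density": 1, "immigrants": 1,
    }
    census = {}
    for name, (base, scale, lo, hi) in _CENSUS_SPECS.items():
        noise = rng.normal(0.0, config.ses_noise_sd, size=n)
        values = base + scale * (meta_dirs[name] * latent + noise)
        census[name] = np.clip(values, lo, hi)
    census_df = pd.DataFrame(census, index=pd.Index(unit_ids, name="unit_id"))

    sites = [
        SupplySite(id=s.id, lon=s.lon, lat=s.lat, capacity=1.0) for s in services
    ]
    od = euclidean_ttm(units, sites, config.speed_kmh)

    ground_truth = {
        "latent_deprivation": pd.Series(latent, index=unit_ids, name="latent"),
        # achievable planted rates after integer rounding of the totals; equal
        # to the configured rates whenever the totals divide evenly
        "beds_per_100k": total_beds / adults * 100_000,
        "places_per_100k": total_places / adults * 100_000,
        "fte_per_100k": dict(config.fte_per_100k),
        "planted_total_beds": int(total_beds),
        "planted_total_places": int(total_places),
        "single_mtc_fraction": 1.0 - n_multi / m,
    }
    return SyntheticStudyArea(
        area=area,
        units=units,
        services=services,
        bsics=bsics,
        census=census_df,
        od=od,
        ground_truth=ground_truth,
        config=config,
    )


def generate_ratings(
    registry: CodeRegistry,
    n_raters: int = 19,
    n_items: int = 12,
    accuracy: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulated vignette-coding exercise: raters match gold with a given accuracy.

    Gold codes are drawn without replacement from the registry; each rater
    reproduces the gold code with probability ``accuracy`` and otherwise
    picks a different registry code uniformly at random.
    """
    if n_raters < 2:
        raise ValueError("at least two raters are required")
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError("accuracy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    all_codes = sorted(c.code for c in registry)
    gold_codes = rng.choice(all_codes, size=n_items, replace=False)
    items = [f"item_{i:02d}" for i in range(1, n_items + 1)]
    gold = dict(zip(items, (str(c) for c in gold_codes)))
    rows = {}
    for r in range(1, n_raters + 1):
        cells = []
        for item in items:
            if rng.random() < accuracy:
                cells.append(gold[item])
            else:
                others = [c for c in all_codes if c != gold[item]]
                cells.append(str(rng.choice(others)))
        rows[f"rater_{r:02d}"] = cells
    ratings = pd.DataFrame.from_dict(rows, orient="index", columns=items)
    return ratings, gold


@dataclass(frozen=True)
class Vignette:
    """One synthetic training vignette with its gold MTC codes."""

    id: str
    title: str
    text: str
    gold_codes: tuple[str, ...]
    incomplete: bool

    @property
    def principal_code(self) -> str:
        return self.gold_codes[0]


def packaged_vignettes() -> list[Vignette]:
    """The packaged synthetic coding-exercise fixture.

    Twelve authored service vignettes covering 14 distinct gold MTC codes;
    some are deliberately incomplete to mimic real data-gathering problems.
    """
    path = Path(str(resources.files("mhatlas").joinpath("data/vignettes_synthetic.json")))
    with open(path) as fh:
        raw = json.load(fh)
    return [
        Vignette(
            id=v["id"],
            title=v["title"],
            text=v["text"],
            gold_codes=tuple(v["gold_codes"]),
            incomplete=bool(v["incomplete"]),
        )
        for v in raw["vignettes"]
    ]
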
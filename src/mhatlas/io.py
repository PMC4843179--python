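"""Readers and writers for the documented interchange formats.

Tabular data travels as UTF-8 CSV (services, BSICs, population, census,
origin–destination matrices, ratings, indicator tables); geographic data as
GeoJSON in WGS84. All writers emit stable, id-sorted row and column
ordering so re-exports of the same inputs are byte-identical.

Inventory CSV schema (versioned by header):

* services: id, name, governance, publicly_funded, universal_access, sector,
  lon, lat, address, zoning_level, catchment_id, reference_year,
  inside_study_area, target_group_tags (semicolon-separated),
  pct_users_with_mental_disorder
* bsics: id, service_id, the five stability flags, mtc_codes
  (semicolon-separated, first = principal), beds, day_places,
  fte_physicians ... fte_other_workers, admissions, contacts, bed_days, users
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accessibility import PopulationUnit, TravelTimeMatrix
from .indicators import AGE_BANDS
from .inventory import BSIC, STABILITY_CRITERIA, STAFF_GROUPS, UTILISATION_FIELDS, Service

__all__ = [
    "InventoryFormatError",
    "read_inventory",
    "write_inventory",
    "read_population",
    "write_population",
    "read_census",
    "write_census",
    "read_od_matrix",
    "write_od_matrix",
    "read_ratings",
    "read_gold",
    "read_units_geojson",
    "write_units_geojson",
    "export_atlas",
    "AtlasBundle",
]

_SERVICE_REQUIRED = [
    "id", "name", "governance", "publicly_funded", "universal_access", "sector",
    "zoning_level", "inside_study_area", "target_group_tags",
]
_SERVICE_OPTIONAL = [
    "lon", "lat", "address", "catchment_id", "reference_year",
    "pct_users_with_mental_disorder",
]
_BSIC_REQUIRED = (
    ["id", "service_id"]
    + list(STABILITY_CRITERIA)
    + ["mtc_codes", "beds", "day_places"]
    + [f"fte_{g}" for g in STAFF_GROUPS]
)
_BSIC_OPTIONAL = list(UTILISATION_FIELDS)


class InventoryFormatError(ValueError):
    """One or more rows of an inventory file failed to parse; carries
    (file, row number, message) triples."""

    def __init__(self, errors: Sequence[tuple[str, int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"{f} row {r}: {m}" for f, r, m in self.errors)
        super().__init__(f"inventory parse errors: {lines}")


def _check_columns(df: pd.DataFrame, required: list[str], optional: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InventoryFormatError([(name, 0, f"missing required columns {missing}")])
    unknown = [c for c in df.columns if c not in required + optional]
    if unknown:
        warnings.warn(f"{name}: unknown columns ignored: {unknown}", UserWarning, stacklevel=3)


def _parse_bool(value, what: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"{what}: cannot parse boolean from {value!r}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    return float(value)


def read_inventory(
    services_path: str | Path, bsics_path: str | Path
) -> tuple[list[Service], list[BSIC]]:
    """Read the two-file inventory; all row-level errors are collected and
    reported together with their row numbers."""
    errors: list[tuple[str, int, str]] = []
    sdf = pd.read_csv(services_path, dtype=str, keep_default_na=False)
    _check_columns(sdf, _SERVICE_REQUIRED, _SERVICE_OPTIONAL, str(services_path))
    services: list[Service] = []
    for i, row in sdf.iterrows():
        rownum = int(i) + 2  # header is row 1
        try:
            tags = frozenset(t for t in str(row["target_group_tags"]).split(";") if t)
            services.append(
                Service(
                    id=row["id"],
                    name=row.get("name", ""),
                    governance=row["governance"],
                    publicly_funded=_parse_bool(row["publicly_funded"], "publicly_funded"),
                    universal_access=_parse_bool(row["universal_access"], "universal_access"),
                    sector=row["sector"],
                    lon=_opt_float(row.get("lon")),
                    lat=_opt_float(row.get("lat")),
                    address=row.get("address", ""),
                    zoning_level=row["zoning_level"],
                    catchment_id=(row.get("catchment_id") or None),
                    reference_year=(
                        int(row["reference_year"]) if row.get("reference_year") else None
                    ),
                    inside_study_area=_parse_bool(row["inside_study_area"], "inside_study_area"),
                    target_group_tags=tags,
                    pct_users_with_mental_disorder=_opt_float(
                        row.get("pct_users_with_mental_disorder")
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append((str(services_path), rownum, str(exc)))

    bdf = pd.read_csv(bsics_path, dtype=str, keep_default_na=False)
    _check_columns(bdf, _BSIC_REQUIRED, _BSIC_OPTIONAL, str(bsics_path))
    bsics: list[BSIC] = []
    for i, row in bdf.iterrows():
        rownum = int(i) + 2
        try:
            beds = int(row["beds"]) if row["beds"] != "" else 0
            places = int(row["day_places"]) if row["day_places"] != "" else 0
            if beds < 0:
                raise ValueError(f"beds must be >= 0, got {beds}")
            if places < 0:
                raise ValueError(f"day_places must be >= 0, got {places}")
            bsics.append(
                BSIC(
                    id=row["id"],
                    service_id=row["service_id"],
                    stability={
                        c: _parse_bool(row[c], c) for c in STABILITY_CRITERIA
                    },
                    mtc_codes=[c for c in str(row["mtc_codes"]).split(";") if c],
                    beds=beds,
                    day_places=places,
                    staff_fte={
                        g: float(row[f"fte_{g}"]) if row[f"fte_{g}"] != "" else 0.0
                        for g in STAFF_GROUPS
                    },
                    utilisation={
                        f: _opt_float(row.get(f)) for f in UTILISATION_FIELDS
                    },
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append((str(bsics_path), rownum, str(exc)))

    if errors:
        raise InventoryFormatError(errors)
    return services, bsics


def write_inventory(
    services: Iterable[Service],
    bsics: Iterable[BSIC],
    services_path: str | Path,
    bsics_path: str | Path,
) -> None:
    srows = []
    for s in sorted(services, key=lambda s: s.id):
        srows.append(
            {
                "id": s.id,
                "name": s.name,
                "governance": s.governance,
                "publicly_funded": str(s.publicly_funded).lower(),
                "universal_access": str(s.universal_access).lower(),
                "sector": s.sector,
                "lon": s.lon,
                "lat": s.lat,
                "address": s.address,
                "zoning_level": s.zoning_level,
                "catchment_id": s.catchment_id or "",
                "reference_year": s.reference_year if s.reference_year is not None else "",
                "inside_study_area": str(s.inside_study_area).lower(),
                "target_group_tags": ";".join(sorted(s.target_group_tags)),
                "pct_users_with_mental_disorder": (
                    s.pct_users_with_mental_disorder
                    if s.pct_users_with_mental_disorder is not None
                    else ""
                ),
            }
        )
    service_cols = [
        "id", "name", "governance", "publicly_funded", "universal_access", "sector",
        "lon", "lat", "address", "zoning_level", "catchment_id", "reference_year",
        "inside_study_area", "target_group_tags", "pct_users_with_mental_disorder",
    ]
    pd.DataFrame(srows, columns=service_cols).to_csv(services_path, index=False)

    brows = []
    for b in sorted(bsics, key=lambda b: b.id):
        row = {
            "id": b.id,
            "service_id": b.service_id,
            **{c: str(bool(b.stability.get(c, False))).lower() for c in STABILITY_CRITERIA},
            "mtc_codes": ";".join(b.mtc_codes),
            "beds": b.beds,
            "day_places": b.day_places,
            **{f"fte_{g}": repr(float(b.staff_fte.get(g, 0.0))) for g in STAFF_GROUPS},
            **{
                f: ("" if b.utilisation.get(f) is None else b.utilisation[f])
                for f in UTILISATION_FIELDS
            },
        }
        brows.append(row)
    pd.DataFrame(brows, columns=_BSIC_REQUIRED + _BSIC_OPTIONAL).to_csv(bsics_path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "sex": str, "age_band": str})
    required = {"unit_id", "sex", "age_band", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population file missing columns {sorted(missing)}")
    return df


def write_population(population: pd.DataFrame, path: str | Path) -> None:
    population.sort_values(["unit_id", "age_band", "sex"]).to_csv(path, index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    if "unit_id" not in df.columns:
        raise ValueError("census file missing unit_id column")
    return df.set_index("unit_id")


def write_census(census: pd.DataFrame, path: str | Path) -> None:
    census.sort_index().rename_axis("unit_id").reset_index().to_csv(path, index=False)


def read_od_matrix(path: str | Path) -> TravelTimeMatrix:
    """Long-format OD CSV: origin_id, dest_id, minutes. An absent pair is
    unreachable; duplicate pairs and negative minutes are errors."""
    df = pd.read_csv(path, dtype={"origin_id": str, "dest_id": str})
    return TravelTimeMatrix.from_long(df)


def write_od_matrix(ttm: TravelTimeMatrix, path: str | Path) -> None:
    ttm.to_long().to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Ratings CSV: first column rater id, remaining columns item ids."""
    df = pd.read_csv(path, dtype=str).set_index("rater_id")
    return df.where(df.notna() & (df != ""), other=pd.NA)


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.rename_axis("rater_id").reset_index().to_csv(path, index=False)


def read_gold(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"item_id", "code"} <= set(df.columns):
        raise ValueError("gold file requires columns item_id, code")
    return dict(zip(df["item_id"], df["code"]))


def write_gold(gold: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(gold.items()), columns=["item_id", "code"]
    ).to_csv(path, index=False)


def read_units_geojson(path: str | Path) -> list[PopulationUnit]:
    with open(path) as fh:
        gj = json.load(fh)
    units = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        lon, lat = feat["geometry"]["coordinates"]
        units.append(
            PopulationUnit(
                id=str(props["unit_id"]),
                lon=float(lon),
                lat=float(lat),
                population=float(props.get("adult_population", 0.0)),
            )
        )
    return units


def write_units_geojson(units: Iterable[PopulationUnit], path: str | Path,
                        extra: Mapping[str, Mapping[str, object]] | None = None) -> None:
    features = []
    for u in sorted(units, key=lambda u: u.id):
        props: dict[str, object] = {"unit_id": u.id, "adult_population": u.population}
        if extra and u.id in extra:
            props.update(extra[u.id])
        features.append(
            {
                "type": "Feature",
                "id": u.id,
                "geometry": {"type": "Point", "coordinates": [u.lon, u.lat]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")


@dataclass
class AtlasBundle:
    """Paths and metadata of an exported atlas directory."""

    out_dir: Path
    layers: dict[str, Path] = field(default_factory=dict)
    tables: dict[str, Path] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def export_atlas(
    layers: Mapping[str, pd.DataFrame],
    tables: Mapping[str, pd.DataFrame],
    geometries: str | Path | dict,
    out_dir: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> AtlasBundle:
    """Write an atlas bundle: one GeoJSON layer per mapping family plus the
    indicator tables and a metadata snapshot.

    ``layers`` maps layer name to a DataFrame of per-unit properties indexed
    by unit id; ``geometries`` is a GeoJSON FeatureCollection (or path) whose
    feature ids cover every unit id in every layer. Output ordering is stable
    (sorted ids/columns) so re-exports are byte-identical.
    """
    if not layers and not tables:
        raise ValueError("nothing to export: no layers and no tables")
    if isinstance(geometries, (str, Path)):
        with open(geometries) as fh:
            geometries = json.load(fh)
    feat_by_id = {
        str(f.get("id", f.get("properties", {}).get("unit_id"))): f
        for f in geometries.get("features", [])
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = AtlasBundle(out_dir=out_dir, metadata=dict(metadata or {}))

    for name in sorted(layers):
        props = layers[name]
        unmatched = [str(i) for i in props.index if str(i) not in feat_by_id]
        if unmatched:
            raise ValueError(f"layer {name!r}: no geometry for ids {unmatched}")
        features = []
        for uid in sorted(str(i) for i in props.index):
            base = feat_by_id[uid]
            row = props.loc[uid]
            extra = {
                k: (None if pd.isna(v) else (v.item() if hasattr(v, "item") else v))
                for k, v in row.items()
            }
            features.append(
                {
                    "type": "Feature",
                    "id": uid,
                    "geometry": base["geometry"],
                    "properties": {**base.get("properties", {}), **extra},
                }
            )
        path = out_dir / f"{name}.geojson"
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
            fh.write("\n")
        bundle.layers[name] = path

    for name in sorted(tables):
        path = out_dir / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        bundle.tables[name] = path

    meta_path = out_dir / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(bundle.metadata, fh, indent=1, default=str)
        fh.write("\n")
    return bundle


def write_bundle(synth, out_dir: str | Path) -> dict[str, Path]:
    """Write a generated synthetic study area as a full input bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "services": out_dir / "services.csv",
        "bsics": out_dir / "bsics.csv",
        "population": out_dir / "population.csv",
        "census": out_dir / "census.csv",
        "od_matrix": out_dir / "od_matrix.csv",
        "units": out_dir / "units.geojson",
        "zoning": out_dir / "zoning.csv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_inventory(synth.services, synth.bsics, paths["services"], paths["bsics"])
    write_population(synth.area.population, paths["population"])
    write_census(synth.census, paths["census"])
    write_od_matrix(synth.od, paths["od_matrix"])
    write_units_geojson(synth.units, paths["units"])
    pd.DataFrame(
        sorted((synth.area.zoning or {}).items()), columns=["unit_id", "catchment_id"]
    ).to_csv(paths["zoning"], index=False)
    gt = {
        k: (v.to_dict() if isinstance(v, pd.Series) else v)
        for k, v in synth.ground_truth.items()
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
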
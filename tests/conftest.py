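import pandas as pd
import pytest

from mhatlas import GeneratorConfig, StudyArea, generate_study_area, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def synth_area():
    """Default-configuration synthetic study area (seed 42)."""
    return generate_study_area(GeneratorConfig())


def make_area(adults: float, area_id: str = "A", n_units: int = 1,
              zoning: dict | None = None, elderly_share: float = 0.2,
              child_share: float = 0.25) -> StudyArea:
    """Single- or multi-unit study area with the given total adult population."""
    rows = []
    per_unit = adults / n_units
    for i in range(n_units):
        uid = f"U{i + 1}"
        a65 = per_unit * elderly_share
        a1864 = per_unit - a65
        child = per_unit * child_share
        for band, count in (("0-17", child), ("18-64", a1864), ("65+", a65)):
            rows.append({"unit_id": uid, "sex": "female", "age_band": band,
                         "population": count / 2})
            rows.append({"unit_id": uid, "sex": "male", "age_band": band,
                         "population": count / 2})
    return StudyArea(id=area_id, population=pd.DataFrame(rows), zoning=zoning)
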
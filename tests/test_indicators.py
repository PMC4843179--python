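import numpy as np
import pandas as pd
import pytest

from mhatlas.indicators import (
    InconsistencyError,
    StudyArea,
    ZeroDenominatorError,
    availability_rate,
    capacity_rates,
    utilisation_rates,
    workforce_rates,
)
from mhatlas.inventory import BSIC, STABILITY_CRITERIA

from conftest import make_area


def bsic(bid, codes, service_id="S1", **kw):
    return BSIC(id=bid, service_id=service_id,
                stability={c: True for c in STABILITY_CRITERIA},
                mtc_codes=list(codes), **kw)


def total_rate(table, indicator):
    sub = table[(table.indicator == indicator) & (table.group == "total")
                & (table.catchment_id.isna())]
    return float(sub.rate_per_100k.iloc[0])


# ---------------------------------------------------------------- availability

def test_availability_total_rate():
    bsics = [bsic(f"B{i}", ["O5"]) for i in range(7)]
    table = availability_rate(bsics, make_area(350_000))
    assert total_rate(table, "availability") == pytest.approx(2.0)


def test_availability_zero_bsics_is_zero_rate():
    table = availability_rate([], make_area(100_000))
    assert total_rate(table, "availability") == 0.0


def test_availability_by_branch():
    bsics = [bsic("B1", ["R1"]), bsic("B2", ["R2.1"]),
             bsic("B3", ["D1"]), bsic("B4", ["D2"]), bsic("B5", ["D3"])]
    table = availability_rate(bsics, make_area(250_000), level="branch")
    rows = table.set_index("group").rate_per_100k
    assert rows["R"] == pytest.approx(0.8)
    assert rows["D"] == pytest.approx(1.2)


def test_branch_rates_sum_to_total(synth_area):
    table = availability_rate(synth_area.bsics, synth_area.area, level="branch")
    total = total_rate(table, "availability")
    branches = table[table.group != "total"].rate_per_100k.sum()
    assert branches == pytest.approx(total, rel=1e-12)


def test_zero_adult_denominator_raises():
    with pytest.raises(ZeroDenominatorError, match="A"):
        availability_rate([], make_area(0))


def test_uncoded_bsic_raises():
    with pytest.raises(ValueError, match="uncoded"):
        availability_rate([bsic("B1", [])], make_area(1000))


# -------------------------------------------------------------------- capacity

def test_beds_rate():
    bsics = [bsic("B1", ["R1"], beds=120)]
    table = capacity_rates(bsics, make_area(240_000))
    assert total_rate(table, "beds") == pytest.approx(50.0)


def test_no_day_bsics_gives_zero_places_rate():
    table = capacity_rates([bsic("B1", ["R1"], beds=10)], make_area(100_000))
    assert total_rate(table, "day_places") == 0.0


def test_beds_on_non_residential_principal_warns_and_not_counted():
    with pytest.warns(UserWarning, match="non-residential"):
        table = capacity_rates([bsic("B1", ["O5"], beds=9)], make_area(100_000))
    assert total_rate(table, "beds") == 0.0


def test_per_catchment_rates_and_pooled_mean():
    zoning = {"U1": "C1", "U2": "C2"}
    area = make_area(200_000, n_units=2, zoning=zoning)  # 100k adults each
    bsics = [bsic("B1", ["R1"], service_id="S1", beds=40),
             bsic("B2", ["R1"], service_id="S2", beds=80)]
    table = capacity_rates(bsics, area, service_catchments={"S1": "C1", "S2": "C2"})
    beds = table[table.indicator == "beds"]
    per_catch = beds.dropna(subset=["catchment_id"]).set_index("catchment_id").rate_per_100k
    assert per_catch["C1"] == pytest.approx(40.0)
    assert per_catch["C2"] == pytest.approx(80.0)
    pooled = total_rate(table, "beds")
    assert pooled == pytest.approx(60.0)
    # pooled rate equals the population-weighted mean of catchment rates
    weights = pd.Series({"C1": 100_000, "C2": 100_000})
    assert pooled == pytest.approx(float((per_catch * weights).sum() / weights.sum()))


# ------------------------------------------------------------------- workforce

def test_physician_fte_rate():
    bsics = [bsic("B1", ["O5"], staff_fte={"physicians": 14.0})]
    table = workforce_rates(bsics, make_area(700_000))
    rows = table[table.catchment_id.isna()].set_index("group").rate_per_100k
    assert rows["physicians"] == pytest.approx(2.0)


def test_all_zero_staffing_gives_zero_rates():
    table = workforce_rates([bsic("B1", ["O5"])], make_area(100_000))
    assert (table.rate_per_100k == 0).all()


def test_staff_summed_across_bsics():
    bsics = [bsic(f"B{i}", ["O5"], staff_fte={"nurses": f})
             for i, f in enumerate((2.5, 3.5, 1.0))]
    table = workforce_rates(bsics, make_area(350_000))
    rows = table.set_index("group").rate_per_100k
    assert rows["nurses"] == pytest.approx(2.0)


def test_negative_fte_rejected_at_construction():
    with pytest.raises(ValueError, match="negative FTE"):
        bsic("B1", ["O5"], staff_fte={"nurses": -1.0})


# ----------------------------------------------------------------- utilisation

def util_bsic(bid, admissions=None, bed_days=None, contacts=None, users=None):
    return bsic(bid, ["R1"], utilisation={"admissions": admissions, "bed_days": bed_days,
                                          "contacts": contacts, "users": users})


def test_mean_length_of_stay():
    table = utilisation_rates([util_bsic("B1", admissions=500, bed_days=5000)],
                              make_area(100_000))
    row = table[table.indicator == "mean_length_of_stay"]
    assert float(row.value.iloc[0]) == pytest.approx(10.0)


def test_missing_contacts_propagate_as_missing_not_zero():
    table = utilisation_rates([util_bsic("B1", admissions=10, bed_days=50)],
                              make_area(100_000))
    row = table[table.indicator == "contacts"]
    assert np.isnan(row.value.iloc[0])


def test_pooled_mean_stay_over_bsics():
    bsics = [util_bsic("B1", 10, 50), util_bsic("B2", 20, 100), util_bsic("B3", 10, 250)]
    table = utilisation_rates(bsics, make_area(100_000))
    row = table[table.indicator == "mean_length_of_stay"]
    assert float(row.value.iloc[0]) == pytest.approx(10.0)  # 400 / 40


def test_bed_days_without_admissions_is_inconsistent():
    with pytest.raises(InconsistencyError):
        utilisation_rates([util_bsic("B1", admissions=0, bed_days=10)], make_area(1000))


# ------------------------------------------------------------------ properties

def test_scale_equivariance_doubling_population_halves_rates(synth_area):
    area = synth_area.area
    doubled = StudyArea(
        id=area.id,
        population=area.population.assign(population=area.population.population * 2),
        zoning=area.zoning,
    )
    for fn in (availability_rate, capacity_rates, workforce_rates):
        base = fn(synth_area.bsics, area)
        scaled = fn(synth_area.bsics, doubled)
        np.testing.assert_allclose(
            scaled.rate_per_100k.to_numpy(dtype=float),
            base.rate_per_100k.to_numpy(dtype=float) / 2.0,
            rtol=1e-12,
        )


def test_random_fixture_invariants():
    """Branch-sum and scale-equivariance on randomised small inventories."""
    rng = np.random.default_rng(7)
    codes = ["R1", "R2.1", "D1", "D2", "O5", "O6", "S1"]
    for _ in range(100):
        n = int(rng.integers(1, 12))
        bsics = [bsic(f"B{i}", [codes[rng.integers(len(codes))]],
                      beds=int(rng.integers(0, 50)))
                 for i in range(n)]
        for b in bsics:  # beds only live on residential units
            if not b.principal_code.startswith("R"):
                b.beds = 0
        adults = float(rng.integers(50_000, 500_000))
        table = availability_rate(bsics, make_area(adults), level="branch")
        total = total_rate(table, "availability")
        assert table[table.group != "total"].rate_per_100k.sum() == pytest.approx(total)
        half = availability_rate(bsics, make_area(2 * adults), level="branch")
        assert total_rate(half, "availability") == pytest.approx(total / 2)


def test_planted_rates_recovered_exactly(synth_area):
    cap = capacity_rates(synth_area.bsics, synth_area.area)
    assert total_rate(cap, "beds") == pytest.approx(
        synth_area.ground_truth["beds_per_100k"], abs=0)
    assert total_rate(cap, "day_places") == pytest.approx(
        synth_area.ground_truth["places_per_100k"], abs=0)
    wf = workforce_rates(synth_area.bsics, synth_area.area)
    rows = wf[wf.catchment_id.isna()].set_index("group").rate_per_100k
    for group, planted in synth_area.ground_truth["fte_per_100k"].items():
        assert rows[group] == pytest.approx(planted, rel=1e-9)


def test_adult_denominator_can_exclude_elderly():
    bsics = [bsic("B1", ["R1"], beds=80)]
    area = make_area(100_000, elderly_share=0.2)
    full = capacity_rates(bsics, area, denominator="18+")
    working = capacity_rates(bsics, area, denominator="18-64")
    assert total_rate(full, "beds") == pytest.approx(80.0)
    assert total_rate(working, "beds") == pytest.approx(100.0)
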
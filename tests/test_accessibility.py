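import math

import numpy as np
import pandas as pd
import pytest

from mhatlas.accessibility import (
    PopulationUnit,
    SupplySite,
    TravelTimeMatrix,
    ZoneScheme,
    e2sfca,
    euclidean_ttm,
    gaussian_zone_weights,
    haversine_km,
    isochrone_coverage,
    nearest_provider_stats,
)


def unit(uid, pop, lon=0.0, lat=0.0):
    return PopulationUnit(id=uid, lon=lon, lat=lat, population=pop)


def site(sid, cap, lon=0.0, lat=0.0):
    return SupplySite(id=sid, lon=lon, lat=lat, capacity=cap)


def ttm_from(units, sites, matrix):
    frame = pd.DataFrame(matrix, index=[u.id for u in units], columns=[s.id for s in sites],
                         dtype=float)
    return TravelTimeMatrix(frame)


SINGLE_ZONE = ZoneScheme(breaks=(30.0,), weights=(1.0,))


# ------------------------------------------------------------------ zone scheme

def test_gaussian_decay_is_one_at_origin_and_w_min_at_limit():
    zones = gaussian_zone_weights([10, 20, 30], w_min=0.01)
    assert zones.decay(0.0) == pytest.approx(1.0)
    assert zones.decay(zones.t_max) == pytest.approx(0.01)


def test_gaussian_zone_weights_at_midpoints_strictly_decreasing():
    zones = gaussian_zone_weights([10, 20, 30], w_min=0.01)
    beta = -(30.0**2) / math.log(0.01)
    expected = [math.exp(-(m**2) / beta) for m in (5.0, 15.0, 25.0)]
    assert zones.weights == pytest.approx(expected)
    assert expected[0] > expected[1] > expected[2]


def test_zone_lookup_assigns_upper_break_to_its_zone():
    zones = gaussian_zone_weights([10, 20, 30])
    assert zones.weight(10.0) == zones.weights[0]
    assert zones.weight(10.1) == zones.weights[1]
    assert zones.weight(31.0) == 0.0
    assert zones.weight(float("nan")) == 0.0


def test_non_ascending_breaks_rejected():
    with pytest.raises(ValueError, match="ascending"):
        gaussian_zone_weights([20, 10, 30])
    with pytest.raises(ValueError, match="w_min"):
        gaussian_zone_weights([10, 20], w_min=1.5)


# ---------------------------------------------------------------------- e2sfca

def test_single_pair_closed_form():
    units = [unit("U1", 1000.0)]
    sites = [site("S1", 10.0)]
    surface = e2sfca(sites, units, ttm_from(units, sites, [[5.0]]), SINGLE_ZONE)
    assert surface.ratios["S1"] == pytest.approx(0.01)
    assert surface.scores["U1"] == pytest.approx(0.01)


def test_unit_beyond_catchment_gets_zero():
    units = [unit("U1", 500.0), unit("U2", 100.0)]
    sites = [site("S1", 10.0)]
    surface = e2sfca(sites, units, ttm_from(units, sites, [[5.0], [45.0]]), SINGLE_ZONE)
    assert surface.scores["U2"] == 0.0


def brute_force_e2sfca(pop, cap, minutes, zones):
    """Independent double-loop oracle for the two-step sums."""
    n, m = minutes.shape
    R = np.full(m, np.nan)
    for j in range(m):
        denom = 0.0
        for i in range(n):
            t = minutes[i, j]
            if not np.isnan(t) and t <= zones.t_max:
                denom += pop[i] * float(zones.weight(t))
        if denom > 0:
            R[j] = cap[j] / denom
    A = np.zeros(n)
    for i in range(n):
        for j in range(m):
            t = minutes[i, j]
            if not np.isnan(t) and t <= zones.t_max and not np.isnan(R[j]):
                A[i] += R[j] * float(zones.weight(t))
    return R, A


def _random_instance(rng):
    n = int(rng.integers(1, 11))
    m = int(rng.integers(1, 11))
    pop = rng.integers(0, 5000, size=n).astype(float)
    cap = rng.uniform(0, 50, size=m)
    minutes = rng.uniform(0, 45, size=(n, m))
    minutes[rng.random((n, m)) < 0.1] = np.nan  # unreachable pairs
    return pop, cap, minutes


def test_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    zones = gaussian_zone_weights([10, 20, 30], w_min=0.01)
    import warnings
    for _ in range(200):
        pop, cap, minutes = _random_instance(rng)
        units = [unit(f"U{i}", p) for i, p in enumerate(pop)]
        sites = [site(f"S{j}", c) for j, c in enumerate(cap)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surface = e2sfca(sites, units, ttm_from(units, sites, minutes), zones)
        R, A = brute_force_e2sfca(pop, cap, minutes, zones)
        np.testing.assert_allclose(surface.scores.to_numpy(), A, atol=1e-9)
        np.testing.assert_allclose(surface.ratios.to_numpy(), R, atol=1e-9)
        # conservation: total capacity of contributing sites is redistributed
        served = ~np.isnan(R)
        np.testing.assert_allclose(
            float(np.sum(pop * A)), float(np.sum(cap[served])), atol=1e-9
        )


def test_single_zone_reduces_to_plain_2sfca():
    rng = np.random.default_rng(12)
    pop, cap, minutes = _random_instance(rng)
    units = [unit(f"U{i}", p) for i, p in enumerate(pop)]
    sites = [site(f"S{j}", c) for j, c in enumerate(cap)]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surface = e2sfca(sites, units, ttm_from(units, sites, minutes), SINGLE_ZONE)
    # plain 2SFCA: unweighted demand within the catchment radius
    t_max = SINGLE_ZONE.t_max
    within = (~np.isnan(minutes)) & (minutes <= t_max)
    A = np.zeros(len(pop))
    for j in range(len(cap)):
        denom = pop[within[:, j]].sum()
        if denom > 0:
            A[within[:, j]] += cap[j] / denom
    np.testing.assert_allclose(surface.scores.to_numpy(), A, atol=1e-12)


def test_accessibility_monotone_in_capacity():
    rng = np.random.default_rng(13)
    pop, cap, minutes = _random_instance(rng)
    units = [unit(f"U{i}", p) for i, p in enumerate(pop)]
    zones = gaussian_zone_weights([10, 20, 30])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = e2sfca([site(f"S{j}", c) for j, c in enumerate(cap)], units,
                      ttm_from(units, [site(f"S{j}", c) for j, c in enumerate(cap)], minutes),
                      zones).scores
        more = cap.copy()
        more[0] += 10.0
        bigger = e2sfca([site(f"S{j}", c) for j, c in enumerate(more)], units,
                        ttm_from(units, [site(f"S{j}", c) for j, c in enumerate(more)], minutes),
                        zones).scores
    assert (bigger.to_numpy() >= base.to_numpy() - 1e-12).all()


def test_empty_supply_or_demand_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        e2sfca([], [unit("U1", 1.0)], ttm_from([unit("U1", 1.0)], [], [[]]), SINGLE_ZONE)


def test_all_unreachable_warns_and_scores_zero():
    units = [unit("U1", 100.0)]
    sites = [site("S1", 5.0)]
    with pytest.warns(UserWarning):
        surface = e2sfca(sites, units, ttm_from(units, sites, [[np.nan]]), SINGLE_ZONE)
    assert (surface.scores == 0).all()
    assert surface.excluded_sites == ["S1"]


# -------------------------------------------------------------------- coverage

def test_coverage_share_at_threshold():
    units = [unit("U1", 600.0), unit("U2", 400.0)]
    sites = [site("S1", 1.0)]
    cov = isochrone_coverage(sites, units, ttm_from(units, sites, [[30.0], [90.0]]), 60.0)
    assert cov.share_covered == pytest.approx(0.60)
    assert cov.uncovered_population == pytest.approx(400.0)


def test_threshold_beyond_max_time_covers_everyone():
    units = [unit("U1", 600.0), unit("U2", 400.0)]
    sites = [site("S1", 1.0)]
    cov = isochrone_coverage(sites, units, ttm_from(units, sites, [[30.0], [90.0]]), 1e6)
    assert cov.share_covered == pytest.approx(1.0)


def test_nearest_time_vector_is_row_minimum():
    rng = np.random.default_rng(14)
    minutes = rng.uniform(1, 120, size=(5, 2))
    units = [unit(f"U{i}", 100.0) for i in range(5)]
    sites = [site(f"S{j}", 1.0) for j in range(2)]
    cov = isochrone_coverage(sites, units, ttm_from(units, sites, minutes), 60.0)
    np.testing.assert_allclose(cov.nearest_minutes.to_numpy(), minutes.min(axis=1))


def test_no_qualifying_services_warns_with_zero_coverage():
    units = [unit("U1", 100.0)]
    with pytest.warns(UserWarning, match="no qualifying"):
        cov = isochrone_coverage([], units, ttm_from(units, [], [[]]), 60.0)
    assert cov.share_covered == 0.0


# ------------------------------------------------------------ nearest provider

def test_single_pair_nearest_stats():
    units = [unit("U1", 100.0)]
    sites = [site("S1", 3.0)]
    stats = nearest_provider_stats(units, sites, ttm_from(units, sites, [[12.0]]))
    assert stats.nearest_minutes["U1"] == 12.0
    assert stats.weighted_mean_minutes == pytest.approx(12.0)
    assert stats.provider_to_population_ratio == pytest.approx(3.0 / 100.0 * 100_000)


def test_ties_resolved_by_stable_site_id_order():
    units = [unit("U1", 100.0)]
    sites = [site("S2", 1.0), site("S1", 1.0)]
    stats = nearest_provider_stats(units, sites, ttm_from(units, sites, [[7.0, 7.0]]))
    assert stats.nearest_minutes["U1"] == 7.0
    assert stats.nearest_site["U1"] == "S1"


def test_population_weighted_mean_travel_time():
    units = [unit("U1", 100.0), unit("U2", 300.0), unit("U3", 600.0)]
    sites = [site("S1", 1.0)]
    stats = nearest_provider_stats(units, sites,
                                   ttm_from(units, sites, [[10.0], [20.0], [40.0]]))
    expected = (100 * 10 + 300 * 20 + 600 * 40) / 1000
    assert stats.weighted_mean_minutes == pytest.approx(expected)


def test_unreachable_unit_excluded_from_mean_with_warning():
    units = [unit("U1", 100.0), unit("U2", 300.0)]
    sites = [site("S1", 1.0)]
    with pytest.warns(UserWarning, match="unreachable"):
        stats = nearest_provider_stats(units, sites,
                                       ttm_from(units, sites, [[10.0], [np.nan]]))
    assert stats.unreachable_units == ["U2"]
    assert stats.weighted_mean_minutes == pytest.approx(10.0)


# ----------------------------------------------------------- euclidean fallback

def test_coincident_points_have_zero_travel_time():
    u = unit("U1", 1.0, lon=2.0, lat=41.0)
    s = site("S1", 1.0, lon=2.0, lat=41.0)
    assert euclidean_ttm([u], [s], 50.0).minutes("U1", "S1") == 0.0


def test_one_km_at_sixty_kmh_is_one_minute():
    u = unit("U1", 1.0, lon=0.0, lat=45.0)
    s = site("S1", 1.0, lon=0.0, lat=45.0 + 1.0 / 111.1949)  # ~1 km north
    minutes = euclidean_ttm([u], [s], 60.0).minutes("U1", "S1")
    km = haversine_km(u.lon, u.lat, s.lon, s.lat)
    assert minutes == pytest.approx(km)  # at 60 km/h, minutes == km
    assert minutes == pytest.approx(1.0, abs=1e-3)


def test_symmetric_inputs_give_symmetric_matrix():
    pts = [(0.0, 45.0), (0.5, 45.2), (0.3, 44.9)]
    units = [unit(f"P{i}", 1.0, lon=lo, lat=la) for i, (lo, la) in enumerate(pts)]
    sites = [site(f"P{i}", 1.0, lon=lo, lat=la) for i, (lo, la) in enumerate(pts)]
    m = euclidean_ttm(units, sites, 50.0).frame.to_numpy()
    np.testing.assert_allclose(m, m.T, atol=1e-12)
    with pytest.raises(ValueError, match="speed"):
        euclidean_ttm(units, sites, 0.0)
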
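"""Synthetic landscape generator: spacing, gradients, generative consistency."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import siteuse
from siteuse import (GradientParams, SyntheticTruth, build_detection_history,
                     evaluate_recovery, filter_independent, simulate_covariates,
                     simulate_detection_data, simulate_stations)
from siteuse.synthetic import AREA_LAYOUT


def test_default_design_dimensions_and_spacing():
    stations = simulate_stations(seed=4)
    assert len(stations) == 127
    areas = {}
    for s in stations:
        areas.setdefault(s.area, []).append(s)
    assert len(areas) == 11
    zones = {z: sum(1 for s in stations if s.zone == z) for z in
             ("national_park", "wma", "village_land")}
    assert zones == {"national_park": 77, "wma": 16, "village_land": 34}
    # all-pairs spacing scan within areas
    for members in areas.values():
        xy = np.array([(s.x, s.y) for s in members])
        if len(xy) > 1:
            d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 1500.0
    cent = {a: np.mean([(s.x, s.y) for s in m], axis=0) for a, m in areas.items()}
    cs = np.array(list(cent.values()))
    dc = np.sqrt(((cs[:, None] - cs[None]) ** 2).sum(-1))
    np.fill_diagonal(dc, np.inf)
    assert dc.min() >= 10_000.0  # centroids placed >= 15 km, means drift a little


def test_single_station_single_area():
    stations = simulate_stations(n_areas=1, stations_per_area=1, seed=0)
    assert len(stations) == 1


def test_infeasible_packing_raises():
    # spacing larger than the (fixed) area extent cannot pack 10 stations
    with pytest.raises(RuntimeError, match="pack"):
        simulate_stations(n_areas=1, stations_per_area=10,
                          min_spacing=30_000.0, area_half_width=5_000.0,
                          seed=0, max_tries=200)
    with pytest.raises(RuntimeError, match="place"):
        simulate_stations(area_spacing=1e7, seed=0, max_tries=50)


def test_covariates_deterministic_given_seed():
    stations = simulate_stations(seed=4)
    c1 = simulate_covariates(stations, seed=9)
    c2 = simulate_covariates(stations, seed=9)
    assert c1.data.equals(c2.data)


def test_default_gradients_follow_the_landscape():
    stations = simulate_stations(seed=4)
    cov = simulate_covariates(stations, seed=9).data
    zone = {s.station_id: s.zone for s in stations}
    by_zone = cov.groupby(cov.index.map(zone))
    means = by_zone.mean()
    assert means.loc["village_land", "livestock"] > means.loc["national_park", "livestock"]
    assert means.loc["national_park", "cpue"] > means.loc["village_land", "cpue"]
    assert means.loc["national_park", "dist_household"] > means.loc["village_land", "dist_household"]


def test_null_gradient_is_exchangeable_across_zones():
    stations = simulate_stations(seed=4)
    cov = simulate_covariates(stations, GradientParams(strength=0.0), seed=10).data
    zone = {s.station_id: s.zone for s in stations}
    park = cov[cov.index.map(zone) == "national_park"]
    village = cov[cov.index.map(zone) == "village_land"]
    for col in cov.columns:
        assert ks_2samp(park[col], village[col]).pvalue > 0.01


MIXED_LAYOUT = [("ParkA", "national_park", 5), ("VillageA", "village_land", 5)]


def test_detection_data_extremes():
    stations = simulate_stations(layout=MIXED_LAYOUT, seed=1)
    cov = simulate_covariates(stations, seed=2)
    sure = SyntheticTruth(mu=30.0, tau=0.0, alpha=(0, 0, 0, 0), beta0=30.0)
    hist, recs, stations, _ = simulate_detection_data(stations, cov, sure, seed=3)
    assert np.all(hist.y[hist.effort_days > 0] == 1.0)
    never = SyntheticTruth(mu=-30.0, tau=0.0, alpha=(0, 0, 0, 0), beta0=0.0)
    hist2, recs2, _, _ = simulate_detection_data(stations, cov, never, seed=3,
                                                 effort_pattern=None)
    assert np.nansum(hist2.y) == 0 and recs2 == []


def test_truth_dimension_mismatch_raises():
    stations = simulate_stations(n_areas=1, stations_per_area=3, seed=1)
    cov = simulate_covariates(stations, seed=2)
    with pytest.raises(ValueError, match="slopes"):
        simulate_detection_data(stations, cov, SyntheticTruth(alpha=(1.0,)), seed=0)


def test_detection_frequency_matches_closed_form():
    stations = simulate_stations(layout=MIXED_LAYOUT + [("WmaA", "wma", 6)], seed=5)
    cov = simulate_covariates(stations, seed=6)
    base = SyntheticTruth(mu=0.0, tau=0.5, alpha=(0.0, 0.0, 1.0, 0.0), beta0=-1.0)
    # fix windows and area effects once, then replicate only use/detection
    hist0, _, stations, truth = simulate_detection_data(stations, cov, base, seed=7)
    zcov = siteuse.zscore_standardize(cov)
    X = zcov.data.reindex([s.station_id for s in stations]).to_numpy()
    eta = (np.array([truth.area_effects[s.area] for s in stations])
           + X @ np.asarray(truth.alpha))
    psi = 1 / (1 + np.exp(-eta))
    p = 1 / (1 + np.exp(-truth.beta0))  # beta_k = 0
    m = (hist0.effort_days > 0).sum(axis=1)
    expected = float(np.sum(m * psi * p) / m.sum())
    reps = []
    for k in range(100):
        h, _, _, _ = simulate_detection_data(stations, cov, truth, seed=100 + k,
                                             effort_pattern=None)
        reps.append(np.nansum(h.y) / (h.effort_days > 0).sum())
    reps = np.asarray(reps)
    mc_se = reps.std(ddof=1) / np.sqrt(len(reps))
    assert abs(reps.mean() - expected) <= 3 * mc_se + 1e-12


def test_records_roundtrip_through_ingest():
    stations = simulate_stations(seed=4)
    cov = simulate_covariates(stations, seed=9)
    hist, records, stations, _ = simulate_detection_data(stations, cov, seed=14)
    # the independence filter is a no-op on synthetic timestamps
    events = filter_independent(records)
    assert events == sorted(records)
    rebuilt = build_detection_history(events, stations, hist.grid, species="leopard")
    np.testing.assert_array_equal(rebuilt.effort_days, hist.effort_days)
    np.testing.assert_array_equal(np.nan_to_num(rebuilt.y, nan=-1),
                                  np.nan_to_num(hist.y, nan=-1))


def test_simulation_deterministic_given_seed():
    for seed in (0, 7):
        out = []
        for _ in range(2):
            st = simulate_stations(seed=seed)
            cov = simulate_covariates(st, seed=seed)
            h, r, _, t = simulate_detection_data(st, cov, seed=seed)
            out.append((h, r, t))
        (h1, r1, t1), (h2, r2, t2) = out
        np.testing.assert_array_equal(np.nan_to_num(h1.y), np.nan_to_num(h2.y))
        assert r1 == r2 and t1.area_effects == t2.area_effects


def test_evaluate_recovery_exact_copies():
    truth = SyntheticTruth(seed=0)
    stations = simulate_stations(layout=MIXED_LAYOUT, seed=1)
    cov = simulate_covariates(stations, seed=2)
    _, _, stations, truth = simulate_detection_data(stations, cov, truth, seed=3)

    # hand-built draws that sit exactly on the truth with tiny spread
    from siteuse.model import PosteriorDraws, ModelConfig, McmcSettings

    names = (["mu", "tau", "beta0"]
             + [f"alpha[{c}]" for c in cov.columns] + [f"w[{c}]" for c in cov.columns])
    vals = ([truth.mu, truth.tau, truth.beta0] + list(truth.alpha) + [1.0] * 4)
    rng = np.random.default_rng(0)
    arr = np.stack([np.array(vals) + rng.normal(0, 1e-6, size=(50, len(vals)))] * 2)
    draws = PosteriorDraws(arr, list(names), [s.station_id for s in stations],
                           list(cov.columns), ["a"], [], np.zeros(len(stations)),
                           np.zeros(len(stations)), ModelConfig(),
                           McmcSettings.reduced())
    rep = evaluate_recovery([draws], [truth])
    assert abs(rep.loc["mu", "bias"]) < 1e-4
    assert rep["coverage"].drop("beta[NT]", errors="ignore").eq(1.0).all()
    with pytest.raises(ValueError):
        evaluate_recovery([draws], [])


def test_area_layout_totals():
    assert sum(n for _, _, n, _ in AREA_LAYOUT) == 127
    assert len(AREA_LAYOUT) == 11
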
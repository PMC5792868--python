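"""Texture densities, spread, NN trajectories, power laws, MAD estimation."""

import numpy as np
import pytest

from barkspat import geometry as geo
from barkspat import inference as inf
from barkspat import metrics as met
from barkspat.ssi import SSIConfig, ssi_generate
from conftest import grid_points, make_pattern

# ---------------------------------------------------------------------------
# Texture partition and densities
# ---------------------------------------------------------------------------


def test_texture_partition_areas_sum_to_window():
    w = geo.Window.rectangle(100, 100)
    part = met.texture_partition_from_discs(w, [[30.0, 30.0, 8.0], [70.0, 70.0, 5.0]])
    assert part.area_rough_dm2 + part.area_smooth_dm2 == pytest.approx(
        w.area_dm2, rel=1e-6
    )
    assert part.area_rough_dm2 == pytest.approx(np.pi * (64 + 25) / 100, rel=1e-3)


def test_texture_densities_counts_and_exact_ratios():
    w = geo.Window.rectangle(100, 100)
    part = met.texture_partition_from_discs(w, [[30.0, 30.0, 10.0]])
    pts = np.array([[30.0, 30.0], [32.0, 31.0], [80.0, 80.0]])
    pat = make_pattern(pts, w, days=[1.0, 2.0, 2.0])
    table, slope, intercept = met.texture_densities(pat, part, [1.0, 2.0])
    assert list(table.n_rough) == [1, 2]
    assert list(table.n_smooth) == [0, 1]
    assert table.lambda_rough_dm2.iloc[1] == pytest.approx(2 / part.area_rough_dm2)
    assert table.lambda_smooth_dm2.iloc[1] == pytest.approx(1 / part.area_smooth_dm2)


def test_texture_all_points_rough_gives_zero_smooth_density():
    w = geo.Window.rectangle(100, 100)
    part = met.texture_partition_from_discs(w, [[50.0, 50.0, 15.0]])
    pts = np.array([[50.0, 50.0], [55.0, 50.0], [50.0, 55.0]])
    table, slope, _ = met.texture_densities(
        make_pattern(pts, w, days=[1.0, 1.0, 2.0]), part, [1.0, 2.0]
    )
    assert (table.lambda_smooth_dm2 == 0).all()


def test_texture_proportional_series_slope_equals_density_ratio():
    # counts kept proportional across censuses: the regression slope must
    # equal the per-census density ratio exactly
    w = geo.Window.rectangle(100, 100)
    part = met.texture_partition_from_discs(w, [[50.0, 50.0, 20.0]])
    rough = np.array([[50.0 + dx, 50.0] for dx in np.linspace(-15, 15, 12)])
    smooth = np.array([[5.0 + 10 * k, 5.0] for k in range(6)])
    pts = np.vstack([rough, smooth])
    days = np.concatenate([np.repeat([1.0, 2.0, 3.0], 4), np.repeat([1.0, 2.0, 3.0], 2)])
    table, slope, intercept = met.texture_densities(
        make_pattern(pts, w, days=days), part, [1.0, 2.0, 3.0]
    )
    ratio = table.ratio.iloc[0]
    assert np.allclose(table.ratio, ratio)
    assert slope == pytest.approx(ratio, rel=1e-9)
    assert intercept == pytest.approx(0.0, abs=1e-12)


def test_texture_requires_both_textures_present():
    w = geo.Window.rectangle(10, 10)
    with pytest.raises(ValueError):
        met.texture_partition_from_discs(w, np.empty((0, 3)))


# ---------------------------------------------------------------------------
# Spread
# ---------------------------------------------------------------------------


def test_spread_simple_range():
    w = geo.Window.rectangle(500, 50)
    pat = make_pattern([[0.0, 25.0], [500.0, 30.0]], w, days=[1.0, 1.0])
    out = met.spread_metrics(pat, [1.0], segment_length=500.0)
    assert out["table"].spread_cm.iloc[0] == 500.0
    assert out["ratio_end_to_length"] == 1.0


def test_spread_monotone_and_bounded(rng):
    w = geo.Window.rectangle(400, 80)
    pts = w.sample_uniform(60, rng)
    pat = make_pattern(pts, w, days=rng.integers(1, 11, 60).astype(float))
    out = met.spread_metrics(pat, np.arange(1.0, 11.0), segment_length=400.0)
    spreads = out["table"].spread_cm.dropna().to_numpy()
    assert np.all(np.diff(spreads) >= 0)
    assert out["ratio_end_to_length"] <= 1.0


def test_spread_drift_null_for_time_homogeneous_attacks(rng):
    # uniform x at all days: centre-of-gravity drift is statistically zero
    w = geo.Window.rectangle(400, 80)
    slopes, ses = [], []
    for _ in range(10):
        pts = w.sample_uniform(200, rng)
        pat = make_pattern(pts, w, days=rng.integers(1, 21, 200).astype(float))
        out = met.spread_metrics(pat, np.arange(1.0, 21.0), 400.0)
        slopes.append(out["drift_slope"])
        ses.append(out["drift_slope_se"])
    z = np.asarray(slopes) / np.asarray(ses)
    assert np.mean(np.abs(z) < 3) >= 0.9


# ---------------------------------------------------------------------------
# Power laws and NN trajectories
# ---------------------------------------------------------------------------


def test_power_law_fit_exact_data():
    lam = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    fit = met._power_law_fit(lam, 6.0 * lam**-0.5)
    assert fit.gamma == pytest.approx(6.0, rel=1e-12)
    assert fit.exponent == pytest.approx(-0.5, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_nn_trajectory_on_growing_csr_sequence(rng):
    # time-ordered CSR accumulation: mean NN ~ 5 lambda^-1/2 (cm, holes/dm^2)
    w = geo.Window.rectangle(400, 400)
    pts = w.sample_uniform(1600, rng)
    days = np.arange(1.0, 1601.0)
    pat = make_pattern(pts, w, days=days)
    census = np.array([100.0, 200.0, 400.0, 800.0, 1600.0])
    table, fit_mean, fit_min = met.nn_density_trajectory(pat, census, final_hull=w)
    assert fit_mean.exponent == pytest.approx(-0.5, abs=0.06)
    assert fit_mean.gamma == pytest.approx(5.0, rel=0.06)
    assert np.all(np.diff(table.min_nn_cm) <= 1e-12)  # min NN non-increasing


def test_nn_trajectory_ssi_prefactor_exceeds_csr(rng):
    w = geo.Window.rectangle(300, 80)
    res = ssi_generate(SSIConfig(window=w, r_inhib=2.5, n_target=240), rng=rng)
    census = np.array([30.0, 60.0, 120.0, 240.0])
    table, fit_mean, fit_min = met.nn_density_trajectory(res.pattern, census, final_hull=w)
    assert fit_mean.gamma > 5.0  # inhibition lifts mean NN above CSR
    assert (table.min_nn_cm >= 2.5).all()  # exact: generator truth bound


def test_nn_trajectory_needs_three_censuses(rng):
    w = geo.Window.rectangle(100, 100)
    pat = make_pattern(w.sample_uniform(20, rng), w, days=np.full(20, 1.0))
    with pytest.raises(geo.InsufficientPointsError):
        met.nn_density_trajectory(pat, [1.0, 2.0], final_hull=w)


# ---------------------------------------------------------------------------
# New-attack NN distances
# ---------------------------------------------------------------------------


def test_new_attack_nn_simple_pair():
    w = geo.Window.rectangle(20, 20)
    pat = make_pattern([[0.0, 0.0], [3.0, 4.0]], w, days=[1.0, 2.0])
    table = met.new_attack_nn(pat, [1.0, 2.0])
    assert np.isnan(table.new_nn_cm.iloc[0])  # nothing pre-existing at day 1
    assert table.new_nn_cm.iloc[1] == pytest.approx(5.0)


def test_new_attack_nn_censuses_without_new_points_flagged():
    w = geo.Window.rectangle(20, 20)
    pat = make_pattern([[1.0, 1.0], [5.0, 5.0]], w, days=[1.0, 1.0])
    table = met.new_attack_nn(pat, [1.0, 2.0, 3.0])
    assert table.n_new.tolist() == [2, 0, 0]
    assert np.isnan(table.new_nn_cm.iloc[1]) and np.isnan(table.new_nn_cm.iloc[2])


def test_new_attack_nn_matches_exhaustive_scan(rng):
    w = geo.Window.rectangle(100, 100)
    pts = w.sample_uniform(50, rng)
    days = rng.integers(1, 6, 50).astype(float)
    pat = make_pattern(pts, w, days=days)
    census = np.arange(1.0, 6.0)
    table = met.new_attack_nn(pat, census)
    for i, t in enumerate(census[1:], start=1):
        old = pts[days <= census[i - 1]]
        new = pts[(days > census[i - 1]) & (days <= t)]
        if len(new) == 0 or len(old) == 0:
            assert np.isnan(table.new_nn_cm.iloc[i])
            continue
        want = np.mean(
            [np.min(np.hypot(old[:, 0] - p[0], old[:, 1] - p[1])) for p in new]
        )
        assert table.new_nn_cm.iloc[i] == pytest.approx(want)


# ---------------------------------------------------------------------------
# MAD estimation
# ---------------------------------------------------------------------------


def test_mad_on_grid_min_nn_exact(rng):
    pts = grid_points(8, 8, 5.0)
    hull = geo.convex_hull(pts)
    pat = make_pattern(pts, hull)
    env = inf.pointwise_envelope(pat, "Gprime", nsim=49, rng=rng)
    mad = met.mad_estimate(pat, env)
    assert mad.min_nn_final_cm == pytest.approx(5.0)
    assert mad.first_crossing_cm is not None
    assert mad.first_crossing_cm < 5.0


def test_mad_ssi_min_nn_brackets_inhibition_distance(rng):
    # at ~1 hole/dm^2 the final min NN sits just above the true r = 2.5 cm
    w = geo.Window.rectangle(300, 80)
    finals = []
    for s in range(7):
        res = ssi_generate(SSIConfig(window=w, r_inhib=2.5, n_target=240, seed=600 + s))
        env = inf.pointwise_envelope(res.pattern, "Gprime", nsim=49, rng=rng)
        mad = met.mad_estimate(res.pattern, env, census_times=[60.0, 120.0, 240.0])
        assert mad.min_nn_final_cm >= 2.5
        assert np.all(np.diff(mad.min_nn_trajectory.min_nn_cm) <= 1e-12)
        finals.append(mad.min_nn_final_cm)
    assert 2.5 <= np.median(finals) <= 3.5


def test_mad_crossing_mostly_undefined_for_csr(rng):
    w = geo.Window.rectangle(300, 80)
    undefined = 0
    for _ in range(10):
        pts = inf.csr_sample(w, 100, "fixed_n", rng)
        pat = make_pattern(pts, w)
        env = inf.pointwise_envelope(pat, "Gprime", nsim=99, rng=rng)
        undefined += met.mad_estimate(pat, env).first_crossing_cm is None
    assert undefined >= 8
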
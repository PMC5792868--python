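"""CSR simulation, envelopes, dclf test, classification, allocation null."""

import warnings

import numpy as np
import pytest
from scipy import stats

from barkspat import geometry as geo
from barkspat import inference as inf
from barkspat import ssi
from conftest import grid_points, make_pattern

# ---------------------------------------------------------------------------
# CSR sampling
# ---------------------------------------------------------------------------


def test_csr_fixed_n_count_and_containment(rng):
    w = geo.Window.rectangle(120, 40)
    pts = inf.csr_sample(w, 50, "fixed_n", rng)
    assert len(pts) == 50
    assert w.contains(pts).all()


def test_csr_poisson_mean_count(rng):
    w = geo.Window.rectangle(100, 100)
    lam = 0.01  # mean count 100
    counts = [len(inf.csr_sample(w, lam, "poisson", rng)) for _ in range(1000)]
    m = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(1000)
    assert abs(m - 100.0) < 3 * se


def test_csr_marginals_are_uniform(rng):
    # 100 draws x 2 axes = 200 KS tests at alpha = 0.05: >= 93% non-significant
    w = geo.Window.rectangle(200, 50)
    ok = 0
    for _ in range(100):
        pts = inf.csr_sample(w, 80, "fixed_n", rng)
        ok += stats.kstest(pts[:, 0] / 200.0, "uniform").pvalue > 0.05
        ok += stats.kstest(pts[:, 1] / 50.0, "uniform").pvalue > 0.05
    assert ok >= 186


def test_csr_poisson_requires_positive_intensity(rng):
    with pytest.raises(ValueError):
        inf.csr_sample(geo.Window.rectangle(10, 10), 0.0, "poisson", rng)


# ---------------------------------------------------------------------------
# Envelopes
# ---------------------------------------------------------------------------


def test_envelope_single_simulation_degenerates(rng):
    w = geo.Window.rectangle(100, 100)
    pat = make_pattern(w.sample_uniform(40, rng), w)
    env = inf.pointwise_envelope(pat, "Gprime", nsim=1, rng=rng)
    np.testing.assert_allclose(env.lo, env.hi)
    np.testing.assert_allclose(env.lo, env.null_mean)


def test_envelope_widens_with_nsim_on_fixed_stream():
    w = geo.Window.rectangle(100, 100)
    pat = make_pattern(w.sample_uniform(40, np.random.default_rng(5)), w)
    env_small = inf.pointwise_envelope(pat, "L", nsim=10, rng=np.random.default_rng(77))
    env_big = inf.pointwise_envelope(pat, "L", nsim=30, rng=np.random.default_rng(77))
    assert np.all(env_big.lo <= env_small.lo + 1e-12)
    assert np.all(env_big.hi >= env_small.hi - 1e-12)


def test_fresh_csr_draw_exceeds_envelope_at_rank_rate(rng):
    # a fresh draw falls outside the pointwise [lo, hi] of nsim = 19 null
    # curves with probability exactly 2/20 at any fixed r (exchangeability)
    w = geo.Window.rectangle(100, 100)
    r = np.array([0.0, 6.0])
    nsim, reps = 19, 2000
    hits = 0
    for _ in range(reps):
        curves = np.empty(nsim + 1)
        for i in range(nsim + 1):
            pts = inf.csr_sample(w, 30, "fixed_n", rng)
            curves[i] = inf._curve("L", pts, w, r)[1]
        fresh, nulls = curves[0], curves[1:]
        hits += fresh > nulls.max() or fresh < nulls.min()
    p_hat = hits / reps
    se = np.sqrt(0.1 * 0.9 / reps)
    assert abs(p_hat - 0.1) < 3 * se


def test_grid_gprime_breaks_lower_envelope_below_spacing(rng):
    pts = grid_points(7, 7, 5.0)
    hull = geo.convex_hull(pts)
    pat = make_pattern(pts, hull)
    env = inf.pointwise_envelope(pat, "Gprime", nsim=99, rng=rng)
    below = (env.observed < env.lo) & (env.r_grid < 5.0) & (env.r_grid > 0)
    assert below.any()


# ---------------------------------------------------------------------------
# dclf deviation test
# ---------------------------------------------------------------------------


def test_deviation_rank_matches_exhaustive_counting():
    u_null = np.array([0.5, 1.0, 2.0, 2.0, 3.0, 0.1, 4.0, 2.5, 0.9])  # nsim = 9
    for u_obs in (0.05, 0.5, 2.0, 5.0):
        want_rank = 1 + sum(1 for u in u_null if u >= u_obs)
        rank, p = inf.deviation_rank(u_obs, u_null)
        assert rank == want_rank
        assert p == pytest.approx(want_rank / 10)


def test_deviation_rank_all_ties_gives_p_one():
    rank, p = inf.deviation_rank(0.7, np.full(9, 0.7))
    assert rank == 10 and p == 1.0


def test_dclf_p_is_multiple_of_rank_unit(rng):
    w = geo.Window.rectangle(150, 80)
    pat = make_pattern(w.sample_uniform(60, rng), w)
    res = inf.dclf_test(pat, "Gprime", r_max=15, nsim=19, rng=rng, n_grid=128)
    assert res.p in [k / 20 for k in range(1, 21)]
    assert res.u_obs >= 0
    assert 1 <= res.rank <= 20


def test_dclf_p_uniform_under_csr(rng):
    # under a true CSR null, p is uniform on {1/20, ..., 1}
    w = geo.Window.rectangle(150, 100)
    nsim, runs = 19, 500
    ps = np.empty(runs)
    for i in range(runs):
        pat = make_pattern(inf.csr_sample(w, 100, "fixed_n", rng), w)
        ps[i] = inf.dclf_test(pat, "Gprime", r_max=15, nsim=nsim, rng=rng, n_grid=64).p
    counts = np.array([(np.abs(ps - k / 20) < 1e-12).sum() for k in range(1, 21)])
    chi2 = ((counts - runs / 20) ** 2 / (runs / 20)).sum()
    assert chi2 < stats.chi2.ppf(0.99, df=19)


def test_dclf_rejects_r_max_beyond_window():
    w = geo.Window.rectangle(10, 10)
    pat = make_pattern(w.sample_uniform(20, np.random.default_rng(0)), w)
    with pytest.raises(ValueError, match="diameter"):
        inf.dclf_test(pat, "Gprime", r_max=30, nsim=9)


def test_dclf_nsim_granularity_does_not_change_u_obs():
    w = geo.Window.rectangle(100, 100)
    pat = make_pattern(w.sample_uniform(50, np.random.default_rng(3)), w)
    res1 = inf.dclf_test(pat, "L", r_max=15, nsim=19, rng=np.random.default_rng(9))
    res2 = inf.dclf_test(pat, "L", r_max=15, nsim=39, rng=np.random.default_rng(9))
    # U_obs depends on the null mean, so it shifts only slightly with nsim,
    # while p granularity changes from 1/20 to 1/40
    assert res1.p * 20 == round(res1.p * 20)
    assert res2.p * 40 == round(res2.p * 40)
    assert res1.u_obs == pytest.approx(res2.u_obs, rel=0.5)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def test_grid_classifies_regular(rng):
    pts = grid_points(10, 10, 5.0)
    hull = geo.convex_hull(pts)
    cls = inf.classify_pattern(make_pattern(pts, hull), nsim=99, rng=rng)
    assert cls.label == "regular"
    assert cls.directions == ("below", "below")


def test_parent_offspring_clusters_classify_clustered(rng):
    w = geo.Window.rectangle(300, 80)
    parents = w.sample_uniform(10, rng)
    pts = []
    for p in parents:
        for _ in range(10):
            while True:
                q = p + rng.normal(0, 2.0, 2)
                if w.contains(q[None])[0]:
                    pts.append(q)
                    break
    cls = inf.classify_pattern(make_pattern(np.array(pts), w), nsim=99, rng=rng)
    assert cls.label == "clustered"
    assert cls.directions == ("above", "above")


def test_too_few_points_forces_random_label(rng):
    w = geo.Window.rectangle(50, 50)
    pat = make_pattern(w.sample_uniform(5, rng), w)
    with pytest.warns(UserWarning, match="too few"):
        cls = inf.classify_pattern(pat, nsim=9, rng=rng)
    assert cls.label == "random" and cls.forced


# ---------------------------------------------------------------------------
# Detection density
# ---------------------------------------------------------------------------


def test_detection_density_on_ssi_sequence(rng):
    w = geo.Window.rectangle(300, 80)
    res = ssi.ssi_generate(ssi.SSIConfig(window=w, r_inhib=2.5, n_target=240), rng=rng)
    census = np.array([60.0, 120.0, 180.0, 240.0])
    det = inf.detection_density(res.pattern, census, nsim=49, rng=rng)
    assert det.lambda_detection is not None
    final = det.trajectory.density_dm2.iloc[-1]
    assert det.lambda_detection < final
    # definitional: the reported density is the hull density at detection day
    row = det.trajectory[det.trajectory.day == det.detection_day].iloc[0]
    assert det.lambda_detection == pytest.approx(row.density_dm2)
    assert (det.trajectory[det.trajectory.day < det.detection_day].label != "regular").all()


def test_detection_density_undefined_for_csr(rng):
    w = geo.Window.rectangle(300, 80)
    pts = inf.csr_sample(w, 120, "fixed_n", rng)
    pat = make_pattern(pts, w, days=np.arange(1, 121, dtype=float))
    det = inf.detection_density(
        pat, np.array([40.0, 80.0, 120.0]), nsim=49, rng=rng
    )
    if det.lambda_detection is not None:  # rare false positive; label must be late
        assert det.detection_day >= 40.0
    assert len(det.trajectory) == 3


# ---------------------------------------------------------------------------
# Allocation null
# ---------------------------------------------------------------------------


def test_allocation_ks_statistic_matches_ecdf_oracle():
    a = np.array([0.3, 0.7, 0.9, 1.4])
    b = np.array([0.1, 0.6, 0.8, 1.0, 1.2])
    got = stats.ks_2samp(a, b).statistic
    xs = np.concatenate([a, b])
    want = max(
        abs(np.mean(a <= x) - np.mean(b <= x)) for x in xs
    )
    assert got == pytest.approx(want)


def test_allocation_null_calibration(rng):
    # observed densities drawn from the multinomial null itself: p uniform
    areas = np.full(13, 240.0)
    ok = 0
    for _ in range(30):
        obs_counts = rng.multinomial(1614, np.ones(13) / 13)
        _, p = inf.allocation_ks_test(areas, 1614, obs_counts / areas, nsim=2000, rng=rng)
        ok += p > 0.05
    assert ok >= 25


def test_allocation_requires_multiple_compartments(rng):
    with pytest.raises(ValueError):
        inf.allocation_ks_test([240.0], 100, [0.4], rng=rng)
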
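"""Monte-Carlo inference against complete spatial randomness (CSR).

The null model throughout is the homogeneous Poisson process simulated in
the pattern's own window (typically the convex hull of the final attack
pattern) at the intensity estimated from the data.  Departures are assessed
with pointwise envelopes and with the Diggle-Cressie-Loosmore-Ford (dclf)
deviation test on an integrated squared deviation

    U = integral_0^rmax (T(r) - Tbar(r))^2 dr,

where T is a summary function (variance-stabilised G' or Besag's L) and
Tbar the mean of the null curves.  A pattern is called regular only when
both the G'- and the L-based tests reject with the observed curve below the
null mean; clustered when both reject above; random otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AttackPattern, Window, convex_hull, density
from .summaries import (
    default_r_grid,
    g_estimate,
    kl_estimate,
    pooled_g,
    variance_stabilize,
)

__all__ = [
    "EnvelopeResult",
    "DCLFResult",
    "PatternClass",
    "DetectionResult",
    "csr_sample",
    "pattern_from_points",
    "pointwise_envelope",
    "deviation_rank",
    "dclf_test",
    "classify_pattern",
    "detection_density",
    "allocation_ks_test",
]

MIN_POINTS_FOR_CLASSIFICATION = 10


@dataclass(frozen=True)
class EnvelopeResult:
    """Pointwise extremes of null summary curves around an observed curve."""

    statistic_kind: str
    r_grid: np.ndarray
    observed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    null_mean: np.ndarray
    nsim: int


@dataclass(frozen=True)
class DCLFResult:
    statistic_kind: str
    u_obs: float
    rank: int
    p: float
    r_max: float
    nsim: int
    direction: str  # "below", "above" or "none"
    u_null: np.ndarray | None = None


@dataclass(frozen=True)
class PatternClass:
    label: str  # "regular", "random" or "clustered"
    p_gprime: float | None
    p_l: float | None
    directions: tuple[str, str] | None
    forced: bool = False  # too few points to test; label forced to random


@dataclass(frozen=True)
class DetectionResult:
    """Hull density at which a colonization sequence first reads as regular."""

    lambda_detection: float | None
    detection_day: float | None
    trajectory: pd.DataFrame  # day, n, density, p_gprime, p_l, label


# ---------------------------------------------------------------------------
# CSR simulation
# ---------------------------------------------------------------------------


def csr_sample(
    window: Window,
    intensity_or_n: float,
    mode: str = "poisson",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform independent points in a window.

    ``mode='poisson'`` draws the count from Poisson(intensity * area) with
    ``intensity_or_n`` an intensity per cm**2; ``mode='fixed_n'`` places
    exactly that many points (binomial process).
    """
    rng = np.random.default_rng() if rng is None else rng
    if mode == "poisson":
        if intensity_or_n <= 0:
            raise ValueError("intensity must be positive in poisson mode")
        n = int(rng.poisson(intensity_or_n * window.area_cm2))
    elif mode == "fixed_n":
        n = int(intensity_or_n)
        if n < 0:
            raise ValueError("n must be non-negative in fixed_n mode")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return window.sample_uniform(n, rng)


def pattern_from_points(
    points: np.ndarray, window: Window, segment_id: str = "sim"
) -> AttackPattern:
    n = len(points)
    return AttackPattern(
        segment_id=segment_id,
        points=np.asarray(points, dtype=float),
        days=np.zeros(n),
        texture=np.array(["unknown"] * n, dtype=object),
        window=window,
        day_range=None,
    )


# ---------------------------------------------------------------------------
# Summary-curve evaluation
# ---------------------------------------------------------------------------


def _curve(kind: str, points: np.ndarray, window: Window, r_grid: np.ndarray) -> np.ndarray:
    """Summary curve of a point set; all-zero when fewer than 2 points."""
    if len(points) < 2:
        return np.zeros_like(r_grid)
    pat = pattern_from_points(points, window)
    if kind in ("G", "Gprime"):
        g = g_estimate(pat, r_grid).values
        return variance_stabilize(g) if kind == "Gprime" else g
    if kind in ("K", "L"):
        k, l = kl_estimate(pat, r_grid)
        return l.values if kind == "L" else k.values
    raise ValueError(f"unknown statistic kind {kind!r}")


def _null_curves(
    pattern: AttackPattern,
    kind: str,
    nsim: int,
    rng: np.random.Generator,
    r_grid: np.ndarray,
    mode: str = "poisson",
) -> np.ndarray:
    arg = pattern.n / pattern.window.area_cm2 if mode == "poisson" else pattern.n
    out = np.empty((nsim, len(r_grid)))
    for i in range(nsim):
        pts = csr_sample(pattern.window, arg, mode=mode, rng=rng)
        out[i] = _curve(kind, pts, pattern.window, r_grid)
    return out


def pointwise_envelope(
    pattern: AttackPattern,
    statistic_kind: str = "Gprime",
    nsim: int = 999,
    rng: np.random.Generator | None = None,
    r_grid: np.ndarray | None = None,
) -> EnvelopeResult:
    """Pointwise min/max envelope of nsim CSR simulations in the pattern's window."""
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    r = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    observed = _curve(statistic_kind, pattern.points, pattern.window, r)
    nulls = _null_curves(pattern, statistic_kind, nsim, rng, r)
    return EnvelopeResult(
        statistic_kind=statistic_kind,
        r_grid=r,
        observed=observed,
        lo=nulls.min(axis=0),
        hi=nulls.max(axis=0),
        null_mean=nulls.mean(axis=0),
        nsim=nsim,
    )


# ---------------------------------------------------------------------------
# dclf deviation test
# ---------------------------------------------------------------------------


def deviation_rank(u_obs: float, u_null: np.ndarray) -> tuple[int, float]:
    """Monte-Carlo rank and p of an observed deviation among null deviations.

    Ties are counted as at-least-as-extreme, so they push the rank (and p)
    up — the conservative convention.
    """
    u_null = np.asarray(u_null, dtype=float)
    rank = 1 + int(np.sum(u_null >= u_obs))
    return rank, rank / (len(u_null) + 1)


def dclf_test(
    pattern_or_replicates,
    statistic_kind: str = "Gprime",
    r_max: float = 20.0,
    nsim: int = 999,
    rng: np.random.Generator | None = None,
    n_grid: int = 512,
) -> DCLFResult:
    """Monte-Carlo goodness-of-fit test of CSR on an integrated squared deviation.

    For a single pattern, T is the chosen summary function; for a list of
    replicate patterns, T is the erosion-weighted pooled G — variance
    stabilised by arcsin(sqrt(.)) when ``statistic_kind='Gprime'`` (the
    default, which equalises the sampling variance across distances) — and
    every null round re-simulates all replicates in their own windows.

    Null patterns condition on the observed counts (binomial processes):
    the count carries no information about spatial arrangement under CSR,
    and conditioning — together with comparing every curve to the mean of
    the other nsim curves — makes the nsim + 1 deviations exactly
    exchangeable, so p is exactly uniform under the null.  Tied deviations
    are ranked against significance.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    replicated = isinstance(pattern_or_replicates, (list, tuple))
    if replicated:
        patterns = list(pattern_or_replicates)
        diam = min(p.window.diameter_cm for p in patterns)
    else:
        patterns = [pattern_or_replicates]
        diam = patterns[0].window.diameter_cm
    if r_max > diam + 1e-9:
        raise ValueError(f"r_max = {r_max} exceeds window diameter {diam:.3g}")
    r = default_r_grid(r_max, n_grid)

    if replicated:
        if statistic_kind not in ("G", "Gprime"):
            raise ValueError("replicated dclf uses the pooled G ('G' or 'Gprime')")
        stabilise = statistic_kind == "Gprime"

        def pooled_stat(pats):
            v = pooled_g(pats, r).values
            return variance_stabilize(v) if stabilise else v

        t_obs = pooled_stat(patterns)
        t_null = np.empty((nsim, len(r)))
        for i in range(nsim):
            sims = [
                pattern_from_points(
                    csr_sample(p.window, p.n, mode="fixed_n", rng=rng), p.window
                )
                for p in patterns
            ]
            t_null[i] = pooled_stat(sims)
    else:
        t_obs = _curve(statistic_kind, patterns[0].points, patterns[0].window, r)
        t_null = _null_curves(patterns[0], statistic_kind, nsim, rng, r, mode="fixed_n")

    # exact exchangeable construction: every curve (observed or null) is
    # compared with the mean of the OTHER nsim curves, so under the null the
    # nsim + 1 deviations are exchangeable and p is exactly uniform
    mean_all = t_null.mean(axis=0)
    u_obs = float(np.trapezoid((t_obs - mean_all) ** 2, r))
    loo_mean = (t_null.sum(axis=0)[None, :] + t_obs[None, :] - t_null) / nsim
    u_null = np.trapezoid((t_null - loo_mean) ** 2, r, axis=1)
    rank, p = deviation_rank(u_obs, u_null)
    raw = float(np.trapezoid(t_obs - mean_all, r))
    direction = "below" if raw < 0 else ("above" if raw > 0 else "none")
    return DCLFResult(
        statistic_kind=statistic_kind,
        u_obs=u_obs,
        rank=rank,
        p=p,
        r_max=float(r_max),
        nsim=nsim,
        direction=direction,
        u_null=u_null,
    )


def classify_pattern(
    pattern: AttackPattern,
    alpha: float = 0.05,
    nsim: int = 999,
    rng: np.random.Generator | None = None,
    r_max: float = 20.0,
    n_grid: int = 512,
) -> PatternClass:
    """Regular / random / clustered label requiring agreement of G' and L tests."""
    rng = np.random.default_rng() if rng is None else rng
    if pattern.n < MIN_POINTS_FOR_CLASSIFICATION:
        warnings.warn(
            f"only {pattern.n} points: too few to test, labelling 'random'",
            stacklevel=2,
        )
        return PatternClass("random", None, None, None, forced=True)
    r_max = min(r_max, pattern.window.diameter_cm)
    res_g = dclf_test(pattern, "Gprime", r_max=r_max, nsim=nsim, rng=rng, n_grid=n_grid)
    res_l = dclf_test(pattern, "L", r_max=r_max, nsim=nsim, rng=rng, n_grid=n_grid)
    both_sig = res_g.p <= alpha and res_l.p <= alpha
    dirs = (res_g.direction, res_l.direction)
    if both_sig and dirs == ("below", "below"):
        label = "regular"
    elif both_sig and dirs == ("above", "above"):
        label = "clustered"
    else:
        label = "random"
    return PatternClass(label, res_g.p, res_l.p, dirs)


def detection_density(
    pattern: AttackPattern,
    census_times,
    alpha: float = 0.05,
    nsim: int = 999,
    rng: np.random.Generator | None = None,
    final_hull: Window | None = None,
    r_max: float = 20.0,
    n_grid: int = 512,
) -> DetectionResult:
    """Hull density at which the growing pattern first classifies as regular.

    The convex hull of the *final* pattern serves as the analysis window for
    every census.  Never reaching a regular label is a valid outcome
    (``lambda_detection`` is None); the per-census p-value trajectories are
    always returned so persistence rules can be applied downstream.
    """
    rng = np.random.default_rng() if rng is None else rng
    census_times = np.asarray(census_times, dtype=float)
    if len(census_times) < 2:
        raise ValueError("detection needs at least 2 census times")
    hull = convex_hull(pattern.points) if final_hull is None else final_hull
    rows = []
    lam_det, day_det = None, None
    for t in census_times:
        sub = pattern.up_to_day(t)
        lam = density(sub.n, hull.area_dm2, basis="hull", at_day=t).value
        if sub.n >= 2:
            sub_h = AttackPattern(
                segment_id=sub.segment_id,
                points=sub.points,
                days=sub.days,
                texture=sub.texture,
                window=hull,
                day_range=None,
            )
        else:
            sub_h = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cls = (
                classify_pattern(sub_h, alpha, nsim, rng, r_max=r_max, n_grid=n_grid)
                if sub_h is not None
                else PatternClass("random", None, None, None, forced=True)
            )
        rows.append(
            dict(
                day=t,
                n=sub.n,
                density_dm2=lam,
                p_gprime=cls.p_gprime,
                p_l=cls.p_l,
                label=cls.label,
            )
        )
        if lam_det is None and cls.label == "regular":
            lam_det, day_det = lam, t
    return DetectionResult(
        lambda_detection=lam_det,
        detection_day=day_det,
        trajectory=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Allocation null for between-segment variability
# ---------------------------------------------------------------------------


def allocation_ks_test(
    areas_dm2,
    total_holes: int,
    observed_densities,
    nsim: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Test whether holes split among segments in proportion to their areas.

    The null allocates the grand total of holes to the segments by a
    multinomial draw with probabilities proportional to area (the
    zero-inhibition limit of sequential placement) and compares the observed
    per-segment densities with the pooled simulated densities by a two-sample
    Kolmogorov-Smirnov test (asymptotic p).
    """
    rng = np.random.default_rng() if rng is None else rng
    areas = np.asarray(areas_dm2, dtype=float)
    obs = np.asarray(observed_densities, dtype=float)
    if len(areas) < 2:
        raise ValueError("allocation test needs at least 2 compartments")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    if total_holes < 1:
        raise ValueError("total_holes must be >= 1")
    probs = areas / areas.sum()
    counts = rng.multinomial(int(total_holes), probs, size=nsim)
    sim_densities = (counts / areas[None, :]).ravel()
    res = stats.ks_2samp(obs, sim_densities, mode="asymp")
    return float(res.statistic), float(res.pvalue)
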
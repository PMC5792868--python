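"""Spatial summary functions: G, variance-stabilised G', Ripley K, Besag L.

The nearest-neighbour distribution function G(r) is estimated with the
reduced-sample (border) estimator,

    Ghat(r) = sum_i 1{d_i <= r, b_i > r} / sum_i 1{b_i > r},

where d_i is the nearest-neighbour distance of point i and b_i its distance
to the window boundary.  K uses the translation edge correction, exact for
rectangles and evaluated through the window's set covariance (FFT of the
window mask) for convex polygonal windows; L(r) = sqrt(K(r)/pi) linearises K
so that L(r) = r under complete spatial randomness.

Replicated patterns are pooled by erosion weighting: the pooled G at lag r is
the weighted mean of the per-replicate estimates with weights n_{i,r}, the
number of points of replicate i further than r from its boundary — which
reduces to summing numerators and denominators of the border estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AttackPattern, InsufficientPointsError, Window, nn_distances

__all__ = [
    "SummaryFunction",
    "PooledG",
    "default_r_grid",
    "g_estimate",
    "variance_stabilize",
    "kl_estimate",
    "pooled_g",
]

#: distances are analysed up to 20 cm by default (pooled-test upper bound)
DEFAULT_R_MAX = 20.0
DEFAULT_GRID_SIZE = 512


def default_r_grid(r_max: float = DEFAULT_R_MAX, n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    return np.linspace(0.0, float(r_max), n)


@dataclass(frozen=True)
class SummaryFunction:
    """An estimated summary function on a distance grid, with metadata."""

    kind: str  # "G", "Gprime", "K" or "L"
    r_grid: np.ndarray
    values: np.ndarray
    correction: str  # "border", "translation" or "none"
    n_points: int
    window_area_cm2: float
    denominators: np.ndarray | None = None  # border-estimator denominators
    undefined: np.ndarray | None = None  # mask of grid points with no estimate

    def to_csv(self, path) -> None:
        denom = (
            self.denominators
            if self.denominators is not None
            else np.full_like(self.values, np.nan)
        )
        pd.DataFrame(
            {"r_cm": self.r_grid, "value": self.values, "denominator": denom}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class PooledG:
    """Erosion-weighted pooled nearest-neighbour function over replicates."""

    r_grid: np.ndarray
    values: np.ndarray
    per_replicate_counts: np.ndarray  # n_{i,r}, shape (n_rep, len(r_grid))
    totals: np.ndarray  # n_r = sum_i n_{i,r}
    undefined: np.ndarray  # mask where n_r == 0


def _validate_grid(r_grid: np.ndarray) -> np.ndarray:
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or len(r) < 2 or r[0] != 0.0 or np.any(np.diff(r) <= 0):
        raise ValueError("r_grid must be strictly increasing from 0")
    return r


def _g_counts(
    points: np.ndarray, window: Window, r_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Border-estimator numerator and denominator counts on the grid."""
    d = nn_distances(points)
    b = window.boundary_distance(points)
    sd = np.sort(d)
    sm = np.sort(np.maximum(d, b))
    sb = np.sort(b)
    n = len(points)
    # numerator(r) = #{d_i <= r} - #{max(d_i, b_i) <= r}  (= #{d_i <= r < b_i})
    numer = np.searchsorted(sd, r_grid, side="right") - np.searchsorted(
        sm, r_grid, side="right"
    )
    denom = n - np.searchsorted(sb, r_grid, side="right")
    return numer.astype(float), denom.astype(float)


def _forward_fill(values: np.ndarray, undefined: np.ndarray) -> np.ndarray:
    """Carry the last defined estimate forward across fully-eroded distances.

    The border estimator loses its denominator once the erosion margin
    swallows every point; the empirical G has saturated by then, so holding
    the last defined value avoids spurious jumps to zero in deviation
    integrals.  The ``undefined`` mask still records where this happened.
    """
    if not np.any(undefined):
        return values
    idx = np.where(~undefined, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    out = values.copy()
    ok = idx >= 0
    out[ok] = values[idx[ok]]
    return out


def g_estimate(pattern: AttackPattern, r_grid: np.ndarray | None = None) -> SummaryFunction:
    """Reduced-sample (border) estimate of the nearest-neighbour function G."""
    if pattern.n < 2:
        raise InsufficientPointsError("G estimation needs >= 2 points")
    r = default_r_grid() if r_grid is None else _validate_grid(r_grid)
    numer, denom = _g_counts(pattern.points, pattern.window, r)
    undefined = denom == 0
    values = np.zeros_like(r)
    np.divide(numer, denom, out=values, where=~undefined)
    values = _forward_fill(values, undefined)
    return SummaryFunction(
        kind="G",
        r_grid=r,
        values=values,
        correction="border",
        n_points=pattern.n,
        window_area_cm2=pattern.window.area_cm2,
        denominators=denom,
        undefined=undefined,
    )


def variance_stabilize(g_values: np.ndarray) -> np.ndarray:
    """Fisher's variance-stabilising transform G' = arcsin(sqrt(G))."""
    v = np.asarray(g_values, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("G values must lie in [0, 1]")
    return np.arcsin(np.sqrt(v))


# ---------------------------------------------------------------------------
# Translation-corrected K and L
# ---------------------------------------------------------------------------

_COV_CACHE: dict[tuple, tuple] = {}
_COV_NPIX = 256  # base rasterisation per axis; mask supersampled 2x


def _set_covariance_grid(window: Window):
    """Rasterised set covariance C(t) = area(W intersect (W + t)) of a window.

    One FFT per window; results are cached on the window's vertex tuple.
    """
    key = (window.vertices,)
    hit = _COV_CACHE.get(key)
    if hit is not None:
        return hit
    xmin, ymin, xmax, ymax = window.bounds
    wx, wy = xmax - xmin, ymax - ymin
    px = max(wx, wy) / (_COV_NPIX * 2)  # supersampled pixel size
    nx = max(int(np.ceil(wx / px)), 2)
    ny = max(int(np.ceil(wy / px)), 2)
    xs = xmin + (np.arange(nx) + 0.5) * px
    ys = ymin + (np.arange(ny) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    fine = window.contains(pts).reshape(ny, nx).astype(float)
    # downsample 2x to a fractional-coverage mask
    ny2, nx2 = ny // 2, nx // 2
    mask = fine[: ny2 * 2, : nx2 * 2].reshape(ny2, 2, nx2, 2).mean(axis=(1, 3))
    px2 = px * 2
    F = np.fft.rfft2(mask, s=(2 * ny2, 2 * nx2))
    cov = np.fft.irfft2(F * np.conj(F), s=(2 * ny2, 2 * nx2)) * px2 * px2
    cov = np.fft.fftshift(cov)  # zero lag at (ny2, nx2)
    entry = (cov, px2, ny2, nx2)
    if len(_COV_CACHE) > 32:
        _COV_CACHE.clear()
    _COV_CACHE[key] = entry
    return entry


def _translation_weights(window: Window, dxy: np.ndarray) -> np.ndarray:
    """Edge-correction weights e = |W| / |W intersect (W + t)| per lag t."""
    if window.kind == "rectangle":
        xmin, ymin, xmax, ymax = window.bounds
        a, b = xmax - xmin, ymax - ymin
        denom = (a - np.abs(dxy[:, 0])) * (b - np.abs(dxy[:, 1]))
        return (a * b) / np.maximum(denom, 1e-12)
    cov, px, ny, nx = _set_covariance_grid(window)
    ix = dxy[:, 0] / px + nx
    iy = dxy[:, 1] / px + ny
    i0 = np.clip(np.floor(iy).astype(int), 0, cov.shape[0] - 2)
    j0 = np.clip(np.floor(ix).astype(int), 0, cov.shape[1] - 2)
    fy = np.clip(iy - i0, 0.0, 1.0)
    fx = np.clip(ix - j0, 0.0, 1.0)
    c = (
        cov[i0, j0] * (1 - fy) * (1 - fx)
        + cov[i0 + 1, j0] * fy * (1 - fx)
        + cov[i0, j0 + 1] * (1 - fy) * fx
        + cov[i0 + 1, j0 + 1] * fy * fx
    )
    # normalise by the rasterised zero-lag value so that e(0) = 1 exactly
    c0 = cov[ny, nx]
    return c0 / np.maximum(c, 1e-9 * c0)


def kl_estimate(
    pattern: AttackPattern, r_grid: np.ndarray | None = None
) -> tuple[SummaryFunction, SummaryFunction]:
    """Translation-corrected Ripley K and its Besag transform L = sqrt(K/pi)."""
    if pattern.n < 2:
        raise InsufficientPointsError("K estimation needs >= 2 points")
    r = default_r_grid() if r_grid is None else _validate_grid(r_grid)
    pts = pattern.points
    n = len(pts)
    iu, ju = np.triu_indices(n, k=1)
    diff = pts[ju] - pts[iu]
    dist = np.hypot(diff[:, 0], diff[:, 1])
    keep = dist <= r[-1]
    dist = dist[keep]
    weights = _translation_weights(pattern.window, diff[keep]) * 2.0  # i!=j pairs
    order = np.argsort(dist, kind="stable")
    dist, weights = dist[order], weights[order]
    csum = np.concatenate([[0.0], np.cumsum(weights)])
    idx = np.searchsorted(dist, r, side="right")
    area = pattern.window.area_cm2
    k_values = (area / n**2) * csum[idx]
    l_values = np.sqrt(k_values / np.pi)
    meta = dict(
        correction="translation", n_points=n, window_area_cm2=area
    )
    return (
        SummaryFunction(kind="K", r_grid=r, values=k_values, **meta),
        SummaryFunction(kind="L", r_grid=r, values=l_values, **meta),
    )


# ---------------------------------------------------------------------------
# Pooling over replicates
# ---------------------------------------------------------------------------


def pooled_g(
    patterns: list[AttackPattern], r_grid: np.ndarray | None = None
) -> PooledG:
    """Erosion-weighted pooled G over replicate patterns.

    Weights n_{i,r} count the points of replicate i in the window eroded by a
    margin of width r; pooling the border estimators with these weights is
    the same as summing their numerators and denominators.  Replicates with
    fewer than two points carry zero weight.
    """
    if not patterns:
        raise ValueError("pooled_g needs at least one replicate")
    r = default_r_grid() if r_grid is None else _validate_grid(r_grid)
    numers = np.zeros((len(patterns), len(r)))
    denoms = np.zeros((len(patterns), len(r)))
    for i, pat in enumerate(patterns):
        if pat.n < 2:
            continue
        numers[i], denoms[i] = _g_counts(pat.points, pat.window, r)
    totals = denoms.sum(axis=0)
    undefined = totals == 0
    values = np.zeros_like(r)
    np.divide(numers.sum(axis=0), totals, out=values, where=~undefined)
    values = _forward_fill(values, undefined)
    return PooledG(
        r_grid=r,
        values=values,
        per_replicate_counts=denoms,
        totals=totals,
        undefined=undefined,
    )
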
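"""Texture-partitioned densities, spatial spread, nearest-neighbour
trajectories, power-law fits and inhibition-distance (MAD) estimation.

During colonization the mean nearest-neighbour distance falls with hull
density lambda along a power law NN = gamma * lambda**a; for complete
spatial randomness the expectation is E(NN) = 1 / (2 sqrt(intensity)),
i.e. gamma = 5.0 cm and a = -1/2 with distances in cm and densities in
holes per dm**2.  The minimum allowed distance (MAD) between attacks is
read off either as the first distance at which the observed G' drops below
the lower CSR envelope or as the limiting minimum nearest-neighbour
distance at the end of colonization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point as _ShapelyPoint
from shapely.ops import unary_union

from .geometry import (
    AttackPattern,
    InsufficientPointsError,
    Window,
    convex_hull,
    nn_distances,
)
from .inference import EnvelopeResult

__all__ = [
    "TexturePartition",
    "PowerLawFit",
    "MADEstimate",
    "texture_partition_from_discs",
    "texture_densities",
    "spread_metrics",
    "nn_density_trajectory",
    "new_attack_nn",
    "mad_estimate",
]


@dataclass(frozen=True)
class TexturePartition:
    """Rough-bark disc patches inside a window, with derived areas (dm**2)."""

    window: Window
    patches: np.ndarray  # (n, 3): cx, cy, radius in cm
    area_rough_dm2: float
    area_smooth_dm2: float

    def is_rough(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        if len(self.patches) == 0:
            return np.zeros(len(pts), dtype=bool)
        d2 = (pts[:, None, 0] - self.patches[None, :, 0]) ** 2 + (
            pts[:, None, 1] - self.patches[None, :, 1]
        ) ** 2
        return np.any(d2 <= self.patches[None, :, 2] ** 2, axis=1)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) on log10(x): y = gamma * x**exponent."""

    gamma: float
    exponent: float
    r_squared: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.gamma * np.asarray(x, dtype=float) ** self.exponent


@dataclass(frozen=True)
class MADEstimate:
    first_crossing_cm: float | None  # G' first drops below the lower envelope
    min_nn_final_cm: float
    density_at_final_dm2: float
    min_nn_trajectory: pd.DataFrame  # day, n, density, min_nn


def texture_partition_from_discs(
    window: Window, patches: np.ndarray
) -> TexturePartition:
    """Partition of a window into rough discs (clipped, unioned) and smooth rest."""
    patches = np.asarray(patches, dtype=float).reshape(-1, 3)
    if len(patches) == 0:
        rough = 0.0
    else:
        discs = unary_union(
            [_ShapelyPoint(cx, cy).buffer(r, quad_segs=64) for cx, cy, r in patches]
        )
        rough = discs.intersection(window.as_shapely()).area / 100.0
    smooth = window.area_dm2 - rough
    if rough <= 0 or smooth <= 0:
        raise ValueError("both textures must have positive area")
    return TexturePartition(
        window=window,
        patches=patches,
        area_rough_dm2=rough,
        area_smooth_dm2=smooth,
    )


def texture_densities(
    pattern: AttackPattern,
    partition: TexturePartition,
    census_times,
) -> tuple[pd.DataFrame, float, float]:
    """Per-census rough and smooth densities, with the cross-texture regression.

    Returns (table, slope, intercept) where slope is the ordinary
    least-squares coefficient of Lambda_rough on Lambda_smooth across the
    censuses — a direct estimate of the rough-bark preference weight.
    """
    census_times = np.asarray(census_times, dtype=float)
    rough_mask = partition.is_rough(pattern.points)
    rows = []
    for t in census_times:
        present = pattern.days <= t + 1e-9
        n_rough = int(np.sum(present & rough_mask))
        n_smooth = int(np.sum(present & ~rough_mask))
        lam_r = n_rough / partition.area_rough_dm2
        lam_s = n_smooth / partition.area_smooth_dm2
        rows.append(
            dict(
                day=t,
                n_rough=n_rough,
                n_smooth=n_smooth,
                lambda_rough_dm2=lam_r,
                lambda_smooth_dm2=lam_s,
                ratio=lam_r / lam_s if lam_s > 0 else np.nan,
            )
        )
    table = pd.DataFrame(rows)
    x = table.lambda_smooth_dm2.to_numpy()
    y = table.lambda_rough_dm2.to_numpy()
    if np.ptp(x) == 0:
        slope, intercept = np.nan, np.nan
    else:
        slope, intercept = np.polyfit(x, y, 1)
    return table, float(slope), float(intercept)


def spread_metrics(
    pattern: AttackPattern,
    census_times,
    segment_length: float,
) -> dict:
    """Along-bole spread of the attacked patch and its drift over time.

    spread(t) is the x-range of all attacks present at census t.  Drift is
    the regression slope of the mean x-coordinate of *new* attacks on census
    day — near zero when colonization is spatially time-homogeneous.
    """
    census_times = np.asarray(census_times, dtype=float)
    x = pattern.points[:, 0]
    rows = []
    prev_t = -np.inf
    days = pattern.days
    for t in census_times:
        present = days <= t + 1e-9
        n = int(present.sum())
        if n == 0:
            rows.append(dict(day=t, n=0, spread_cm=np.nan, new_mean_x=np.nan))
            prev_t = t
            continue
        xs = x[present]
        spread = float(xs.max() - xs.min()) if n >= 2 else 0.0
        new = present & (days > prev_t + 1e-9)
        new_mean_x = float(x[new].mean()) if np.any(new) else np.nan
        rows.append(dict(day=t, n=n, spread_cm=spread, new_mean_x=new_mean_x))
        prev_t = t
    table = pd.DataFrame(rows)
    spreads = table.spread_cm.dropna()
    spread_1 = float(spreads.iloc[0]) if len(spreads) else np.nan
    spread_end = float(spreads.iloc[-1]) if len(spreads) else np.nan
    ok = table.dropna(subset=["new_mean_x"])
    if len(ok) >= 3 and np.ptp(ok.day.to_numpy()) > 0:
        coef, cov = np.polyfit(ok.day, ok.new_mean_x, 1, cov=True)
        slope = float(coef[0])
        slope_se = float(np.sqrt(cov[0, 0]))
        pred = np.polyval(coef, ok.day)
        ss_tot = float(np.sum((ok.new_mean_x - ok.new_mean_x.mean()) ** 2))
        r2 = 1.0 - float(np.sum((ok.new_mean_x - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        slope, slope_se, r2 = np.nan, np.nan, np.nan
    return dict(
        table=table,
        spread_1=spread_1,
        spread_end=spread_end,
        ratio_first_to_end=spread_1 / spread_end if spread_end else np.nan,
        ratio_end_to_length=spread_end / segment_length,
        drift_slope=slope,
        drift_slope_se=slope_se,
        drift_r_squared=r2,
    )


def _power_law_fit(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    keep = (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientPointsError("power-law fit needs >= 3 positive points")
    lx, ly = np.log10(x), np.log10(y)
    coef = np.polyfit(lx, ly, 1)
    pred = np.polyval(coef, lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum((ly - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        gamma=float(10 ** coef[1]), exponent=float(coef[0]), r_squared=r2, n=len(x)
    )


def nn_density_trajectory(
    pattern: AttackPattern,
    census_times,
    final_hull: Window | None = None,
) -> tuple[pd.DataFrame, PowerLawFit, PowerLawFit]:
    """Mean and minimum NN distance per census against hull density.

    The hull of the final pattern fixes the density denominator throughout.
    Returns the trajectory table and the power-law fits of mean NN and of
    min NN against hull density (holes per dm**2).
    """
    census_times = np.asarray(census_times, dtype=float)
    hull = convex_hull(pattern.points) if final_hull is None else final_hull
    rows = []
    for t in census_times:
        sub = pattern.points[pattern.days <= t + 1e-9]
        if len(sub) < 2:
            continue
        d = nn_distances(sub)
        rows.append(
            dict(
                day=t,
                n=len(sub),
                lambda_hull_dm2=len(sub) / hull.area_dm2,
                mean_nn_cm=float(d.mean()),
                min_nn_cm=float(d.min()),
            )
        )
    if len(rows) < 3:
        raise InsufficientPointsError("need >= 3 censuses with >= 2 points")
    table = pd.DataFrame(rows)
    lam = table.lambda_hull_dm2.to_numpy()
    fit_mean = _power_law_fit(lam, table.mean_nn_cm.to_numpy())
    fit_min = _power_law_fit(lam, table.min_nn_cm.to_numpy())
    return table, fit_mean, fit_min


def new_attack_nn(pattern: AttackPattern, census_times) -> pd.DataFrame:
    """Mean distance from each census's new attacks to the pre-existing ones.

    Censuses with no new points, or nothing pre-existing, get NaN entries.
    The rate of new points is (new attacks) / (days since previous census).
    """
    census_times = np.asarray(census_times, dtype=float)
    rows = []
    prev_t = None
    for t in census_times:
        old = pattern.points[pattern.days <= (prev_t if prev_t is not None else -np.inf) + 1e-9]
        here = (pattern.days <= t + 1e-9) & (
            pattern.days > (prev_t if prev_t is not None else -np.inf) + 1e-9
        )
        new = pattern.points[here]
        dt = t - prev_t if prev_t is not None else np.nan
        if len(new) and len(old):
            d2 = (new[:, None, 0] - old[None, :, 0]) ** 2 + (
                new[:, None, 1] - old[None, :, 1]
            ) ** 2
            mean_nn = float(np.sqrt(d2.min(axis=1)).mean())
        else:
            mean_nn = np.nan
        rows.append(
            dict(
                day=t,
                n_new=int(len(new)),
                rate_new_per_day=len(new) / dt if dt and dt > 0 else np.nan,
                new_nn_cm=mean_nn,
            )
        )
        prev_t = t
    return pd.DataFrame(rows)


def mad_estimate(
    pattern: AttackPattern,
    envelope: EnvelopeResult,
    census_times=None,
) -> MADEstimate:
    """Minimum-allowed-distance estimates from a final pattern.

    ``envelope`` must be a G'-type envelope of the final pattern; the first
    distance where the observed curve falls strictly below the lower
    envelope approximates the inhibition distance from above, while the
    final minimum nearest-neighbour distance bounds it from above ever more
    tightly as density grows.
    """
    below = envelope.observed < envelope.lo
    first = float(envelope.r_grid[np.argmax(below)]) if np.any(below) else None
    d = nn_distances(pattern.points)
    hull = convex_hull(pattern.points)
    rows = []
    if census_times is not None:
        for t in np.asarray(census_times, dtype=float):
            sub = pattern.points[pattern.days <= t + 1e-9]
            if len(sub) < 2:
                continue
            rows.append(
                dict(
                    day=t,
                    n=len(sub),
                    lambda_hull_dm2=len(sub) / hull.area_dm2,
                    min_nn_cm=float(nn_distances(sub).min()),
                )
            )
    return MADEstimate(
        first_crossing_cm=first,
        min_nn_final_cm=float(d.min()),
        density_at_final_dm2=pattern.n / hull.area_dm2,
        min_nn_trajectory=pd.DataFrame(rows),
    )
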
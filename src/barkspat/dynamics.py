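"""Temporal colonization models: saturation fit, stage split, landings,
susceptibility ratios.

The cumulative number of entrance holes on a segment follows a saturating
exponential

    H(t) = H_END * (1 - exp(-beta * t)),

with H_END the plateau and beta (per day, stored positive) the steepness.
Colonization proceeds in two stages split at day 11/12.  Under a shared
ambient flux Phi(t), segment densities are proportional within a stage,
Lambda_i(t) = (alpha_i / alpha_j) * Lambda_j(t), so per-segment
susceptibilities alpha are estimated as through-origin regression slopes
against a reference segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import CensusSeries

__all__ = [
    "DynamicsFit",
    "StageSplit",
    "SusceptibilityFit",
    "fit_saturation",
    "split_stages",
    "landing_series",
    "landing_attack_correlation",
    "susceptibility_fit",
]


class InsufficientDataError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class DynamicsFit:
    h_end: float
    beta: float  # positive decay rate, per day
    r_squared: float
    residuals: np.ndarray
    times: np.ndarray

    def predict(self, t) -> np.ndarray:
        return self.h_end * (1.0 - np.exp(-self.beta * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class StageSplit:
    boundary_day: float
    h_first: float
    h_second: float

    @property
    def ratio(self) -> float:
        return self.h_second / self.h_first if self.h_first > 0 else np.inf


@dataclass(frozen=True)
class SusceptibilityFit:
    reference_id: str
    table: pd.DataFrame  # segment_id, stage, alpha, alpha_se, r_squared, n_censuses

    def alpha(self, segment_id: str, stage: str) -> float:
        sel = self.table[
            (self.table.segment_id == segment_id) & (self.table.stage == stage)
        ]
        return float(sel.alpha.iloc[0])


def _as_series(census) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(census, CensusSeries):
        return census.times, census.counts
    t, h = census
    return np.asarray(t, dtype=float), np.asarray(h, dtype=float)


def fit_saturation(census) -> DynamicsFit:
    """Nonlinear least-squares fit of H(t) = H_END (1 - exp(-beta t)).

    Initialised at H_END = 1.1 max(H) with beta from a log-linearised fit of
    the pre-plateau counts; accepts a :class:`CensusSeries` or a
    (times, counts) pair.
    """
    t, h = _as_series(census)
    if len(t) < 4:
        raise InsufficientDataError("saturation fit needs >= 4 census points")
    if len(np.unique(h[h > 0])) < 2:
        raise InsufficientDataError("saturation fit needs >= 2 distinct nonzero counts")
    h0 = 1.1 * float(h.max())
    # log-linearisation: -log(1 - H/H0) = beta * t, through the origin
    frac = np.clip(h / h0, 0.0, 1.0 - 1e-9)
    y = -np.log1p(-frac)
    denom = float(np.dot(t, t))
    b0 = max(float(np.dot(t, y)) / denom, 1e-6) if denom > 0 else 0.1

    def model(tt, h_end, beta):
        return h_end * (1.0 - np.exp(-beta * tt))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            h,
            p0=(h0, b0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            xtol=1e-10,
            ftol=1e-10,
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"saturation fit did not converge: {exc}") from exc
    h_end, beta = float(popt[0]), float(popt[1])
    resid = h - model(t, h_end, beta)
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DynamicsFit(h_end=h_end, beta=beta, r_squared=r2, residuals=resid, times=t)


def split_stages(census, boundary_day: float = 11.0, end_day: float = 45.0) -> StageSplit:
    """First-stage / second-stage partition of the final hole count.

    H_FIRST is the count at the last census on or before the boundary day;
    H_SECOND is the remainder, so the two always sum to the final count.
    """
    t, h = _as_series(census)
    before = t <= boundary_day + 1e-9
    if not np.any(before):
        raise ValueError(f"no census on or before day {boundary_day}")
    h_first = float(h[before][-1])
    h_second = float(h[-1]) - h_first
    return StageSplit(boundary_day=boundary_day, h_first=h_first, h_second=h_second)


def landing_series(traps: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Daily male landing intensity and the weighted mean sex ratio.

    The sex ratio SR = males / sexed is averaged over days with weights equal
    to the number of sexed insects; the male landing intensity on day t is
    n_landed(t) * SR / trap_area (males per dm**2 per day).
    """
    required = {"day", "n_landed", "n_sexed", "n_males", "trap_area_dm2"}
    missing = required - set(traps.columns)
    if missing:
        raise ValueError(f"trap table missing columns {sorted(missing)}")
    if np.any(traps.n_males > traps.n_sexed) or np.any(traps.n_sexed > traps.n_landed):
        raise ValueError("need n_males <= n_sexed <= n_landed on every day")
    total_sexed = float(traps.n_sexed.sum())
    if total_sexed == 0:
        raise ValueError("no sexed insects: sex ratio undefined")
    sr = float(traps.n_males.sum()) / total_sexed
    out = traps.copy()
    out["intensity_land"] = out.n_landed * sr / out.trap_area_dm2
    return out, sr


def landing_attack_correlation(landing_intensity, attack_intensity):
    """Pearson correlation between aligned daily landing and attack series.

    Returns (rho, t, df, p) with t = rho * sqrt(df / (1 - rho**2)) and
    df = n - 2.
    """
    x = np.asarray(landing_intensity, dtype=float)
    y = np.asarray(attack_intensity, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length aligned series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    rho = float(res.statistic)
    df = len(x) - 2
    tval = rho * np.sqrt(df / max(1.0 - rho**2, 1e-15))
    return rho, float(tval), df, float(res.pvalue)


def susceptibility_fit(
    density_table: pd.DataFrame,
    reference_id: str,
    stages: dict[str, tuple[float, float]] | None = None,
) -> SusceptibilityFit:
    """Per-segment susceptibilities from through-origin density regressions.

    ``density_table`` holds one column of segment densities Lambda_i(t) per
    segment, indexed by census day.  Within each stage, Lambda_i is regressed
    through the origin on the reference segment's density; the slope
    estimates alpha_i / alpha_ref (alpha_ref = 1 by construction).
    """
    if stages is None:
        stages = {"first": (0.0, 11.0), "second": (12.0, 45.0)}
    if reference_id not in density_table.columns:
        raise ValueError(f"reference segment {reference_id!r} not in table")
    days = density_table.index.to_numpy(dtype=float)
    ref = density_table[reference_id].to_numpy(dtype=float)
    if np.all(ref == 0):
        raise ValueError("reference density series is identically zero")
    rows = []
    for stage, (lo, hi) in stages.items():
        sel = (days >= lo - 1e-9) & (days <= hi + 1e-9)
        x = ref[sel]
        if len(x) < 3 or np.all(x == 0):
            continue
        sxx = float(np.dot(x, x))
        for seg in density_table.columns:
            y = density_table[seg].to_numpy(dtype=float)[sel]
            slope = float(np.dot(x, y)) / sxx
            resid = y - slope * x
            dof = max(len(x) - 1, 1)
            se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
            ss_tot = float(np.sum(y**2))  # through-origin R^2
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            rows.append(
                dict(
                    segment_id=seg,
                    stage=stage,
                    alpha=slope,
                    alpha_se=se,
                    r_squared=r2,
                    n_censuses=int(len(x)),
                )
            )
    if not rows:
        raise InsufficientDataError("no stage had >= 3 shared censuses")
    return SusceptibilityFit(reference_id=reference_id, table=pd.DataFrame(rows))
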
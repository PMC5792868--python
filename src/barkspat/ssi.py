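"""Simple sequential inhibition (SSI) sampling and colonization simulation.

SSI places points one at a time, uniformly at random in the window, and
rejects any proposal closer than an inhibition distance r to a previously
accepted point.  With a fixed target count the sampler retries until the
count is reached or a run of ``giveup`` consecutive rejections occurs; run
unbounded, the give-up rule estimates the saturation (jamming) density of
the hard-core packing.

``sequential_colonization`` couples the same acceptance rule to a daily
arrival flux: each day, each segment receives Poisson(alpha_j * A_j * Phi(t))
arriving beetles; each arrival proposes one landing site (biased towards
rough bark when texture patches are supplied) and simply leaves if the site
falls within r of an existing attack — arrivals do not retry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import AttackPattern, CensusSeries, Window

__all__ = [
    "SSIConfig",
    "SSIResult",
    "ColonizationResult",
    "ssi_generate",
    "jamming_density",
    "sequential_colonization",
]

_BATCH = 512


@dataclass(frozen=True)
class SSIConfig:
    window: Window
    r_inhib: float
    n_target: int | None = None  # None = unbounded (run to give-up)
    giveup: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.r_inhib < 0:
            raise ValueError("inhibition distance must be >= 0")
        if self.giveup < 1:
            raise ValueError("giveup must be >= 1")
        if self.n_target is not None and self.n_target < 0:
            raise ValueError("n_target must be >= 0")
        if self.n_target is None and self.r_inhib == 0:
            raise ValueError("unbounded SSI with r = 0 never terminates")


@dataclass(frozen=True)
class SSIResult:
    pattern: AttackPattern
    n_accepted: int
    n_proposed: int
    terminated_by: str  # "target_reached" or "giveup"


def ssi_generate(config: SSIConfig, rng: np.random.Generator | None = None) -> SSIResult:
    """Run the SSI sampler; acceptance order is recorded as pseudo-time."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    window, r, giveup = config.window, config.r_inhib, config.giveup
    target = config.n_target
    accepted: list[np.ndarray] = []
    acc_arr = np.empty((0, 2))
    consec = 0
    proposed = 0
    terminated = None
    while terminated is None:
        if target is not None and len(accepted) >= target:
            terminated = "target_reached"
            break
        batch = window.sample_uniform(_BATCH, rng)
        if len(acc_arr) and r > 0:
            dmin, _ = cKDTree(acc_arr).query(batch)
            ok = dmin >= r
        else:
            ok = np.ones(len(batch), dtype=bool)
        cand = np.flatnonzero(ok)
        new: list[np.ndarray] = []
        new_arr = np.empty((len(batch), 2))
        n_new = 0
        prev = -1
        for pos in cand:
            gap = pos - prev - 1  # proposals rejected by pre-batch points
            if consec + gap >= giveup:
                proposed += prev + 1 + (giveup - consec)
                terminated = "giveup"
                break
            consec += gap
            prev = pos
            p = batch[pos]
            if r > 0 and n_new:
                d2 = np.min(
                    (new_arr[:n_new, 0] - p[0]) ** 2 + (new_arr[:n_new, 1] - p[1]) ** 2
                )
                if d2 < r * r:
                    consec += 1
                    continue
            new_arr[n_new] = p
            n_new += 1
            new.append(p)
            consec = 0
            if target is not None and len(accepted) + n_new >= target:
                proposed += pos + 1
                terminated = "target_reached"
                break
        else:
            tail = len(batch) - prev - 1
            if consec + tail >= giveup:
                proposed += prev + 1 + (giveup - consec)
                terminated = "giveup"
            else:
                consec += tail
                proposed += len(batch)
        accepted.extend(new)
        if len(new):
            acc_arr = np.vstack([acc_arr, np.vstack(new)])
    pts = np.asarray(accepted).reshape(-1, 2)
    pattern = AttackPattern(
        segment_id="ssi",
        points=pts,
        days=np.arange(1, len(pts) + 1, dtype=float),
        texture=np.array(["unknown"] * len(pts), dtype=object),
        window=window,
        day_range=None,
    )
    return SSIResult(
        pattern=pattern,
        n_accepted=len(pts),
        n_proposed=proposed,
        terminated_by=terminated,
    )


def jamming_density(
    window: Window,
    r_inhib: float,
    giveup: int = 1000,
    reps: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean saturation density (holes per dm**2) of give-up-terminated SSI runs.

    Returns the Monte-Carlo mean and its standard error over ``reps``
    independent runs.  The saturation count scales as r**-2 away from window
    edges.
    """
    if r_inhib <= 0:
        raise ValueError("jamming density is unbounded at r = 0")
    rng = np.random.default_rng() if rng is None else rng
    dens = np.empty(reps)
    for i in range(reps):
        res = ssi_generate(
            SSIConfig(window=window, r_inhib=r_inhib, n_target=None, giveup=giveup),
            rng=rng,
        )
        dens[i] = res.n_accepted / window.area_dm2
    se = dens.std(ddof=1) / np.sqrt(reps) if reps > 1 else np.nan
    return float(dens.mean()), float(se)


# ---------------------------------------------------------------------------
# Flux-driven multi-segment colonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColonizationResult:
    patterns: list[AttackPattern]
    censuses: dict[str, CensusSeries]
    arrivals: pd.DataFrame  # day, segment_id, n_arrived, n_settled


def _in_patches(point: np.ndarray, patches: np.ndarray) -> bool:
    if patches is None or len(patches) == 0:
        return False
    d2 = (patches[:, 0] - point[0]) ** 2 + (patches[:, 1] - point[1]) ** 2
    return bool(np.any(d2 <= patches[:, 2] ** 2))


def _propose_site(
    window: Window,
    patches: np.ndarray | None,
    w_rough: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """One landing site with proposal density proportional to texture weight.

    Thinning of a uniform proposal: smooth-bark sites are kept with
    probability 1/w_rough (w_rough >= 1), rough sites always.
    """
    if patches is None or len(patches) == 0 or w_rough == 1.0:
        p = window.sample_uniform(1, rng)[0]
        tex = "rough" if patches is not None and _in_patches(p, patches) else (
            "smooth" if patches is not None else "unknown"
        )
        return p, tex
    while True:
        p = window.sample_uniform(1, rng)[0]
        if _in_patches(p, patches):
            return p, "rough"
        if rng.random() < 1.0 / w_rough:
            return p, "smooth"


def sequential_colonization(
    windows: list[Window],
    receptivities,
    flux,
    r_inhib: float,
    census_times,
    rng: np.random.Generator | None = None,
    texture_weights: tuple[float, list[np.ndarray | None]] | None = None,
    segment_ids: list[str] | None = None,
) -> ColonizationResult:
    """Simulate daily colonization of several segments under a shared flux.

    ``flux`` maps a day (float) to the ambient arrival intensity Phi(t) in
    beetles per dm**2 per day; segment j receives
    Poisson(alpha_j * A_j * Phi(t)) arrivals on day t.  ``texture_weights``
    is an optional pair (w_rough, patch list) with one (n, 3) array of disc
    patches (cx, cy, radius in cm) per segment.  Attacks are stamped with
    the first census day >= their arrival day.
    """
    if not windows:
        raise ValueError("at least one segment window is required")
    rng = np.random.default_rng() if rng is None else rng
    alphas = np.asarray(receptivities, dtype=float)
    if len(alphas) != len(windows) or np.any(alphas <= 0):
        raise ValueError("one positive receptivity per window is required")
    census_times = np.sort(np.asarray(census_times, dtype=float))
    if len(census_times) == 0 or np.any(np.diff(census_times) <= 0):
        raise ValueError("census times must be strictly increasing")
    if segment_ids is None:
        segment_ids = [f"seg{j + 1:02d}" for j in range(len(windows))]
    w_rough = 1.0
    patch_list: list[np.ndarray | None] = [None] * len(windows)
    if texture_weights is not None:
        w_rough, patch_list = texture_weights
        if w_rough <= 0:
            raise ValueError("texture weight must be positive")

    n_days = int(np.ceil(census_times[-1]))
    points = [[] for _ in windows]
    cdays = [[] for _ in windows]
    texs = [[] for _ in windows]
    arrival_rows = []
    for d in range(1, n_days + 1):
        phi = float(flux(d - 0.5))  # midpoint of the day's interval
        if phi < 0:
            raise ValueError("flux must be non-negative")
        census = census_times[np.searchsorted(census_times, d, side="left")] if d <= census_times[-1] else None
        for j, window in enumerate(windows):
            n_arr = int(rng.poisson(alphas[j] * window.area_dm2 * phi)) if phi > 0 else 0
            settled = 0
            for _ in range(n_arr):
                site, tex = _propose_site(window, patch_list[j], w_rough, rng)
                if r_inhib > 0 and points[j]:
                    arr = np.asarray(points[j])
                    d2 = (arr[:, 0] - site[0]) ** 2 + (arr[:, 1] - site[1]) ** 2
                    if d2.min() < r_inhib * r_inhib:
                        continue  # the arrival leaves; no retry
                points[j].append(site)
                cdays[j].append(census)
                texs[j].append(tex)
                settled += 1
            arrival_rows.append(
                dict(day=d, segment_id=segment_ids[j], n_arrived=n_arr, n_settled=settled)
            )

    patterns = []
    censuses = {}
    for j, window in enumerate(windows):
        pat = AttackPattern(
            segment_id=segment_ids[j],
            points=np.asarray(points[j]).reshape(-1, 2),
            days=np.asarray(cdays[j], dtype=float),
            texture=np.asarray(texs[j], dtype=object),
            window=window,
            day_range=(0.0, float(census_times[-1])),
        )
        patterns.append(pat)
        censuses[segment_ids[j]] = pat.census_series(census_times)
    return ColonizationResult(
        patterns=patterns,
        censuses=censuses,
        arrivals=pd.DataFrame(arrival_rows),
    )
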
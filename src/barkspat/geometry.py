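"""Windows, marked spatio-temporal point patterns, and table I/O.

The bark surface of a log segment is treated as a planar rectangle obtained
by unrolling the cylinder: x runs along the bole (cm), y around the
circumference (cm) with y = 0 at the upper rim.  Attack (entrance-hole)
patterns live inside such a window, or inside the convex hull of the attacked
patch.  All distances are centimetres; areas are reported in dm**2
(1 dm**2 = 100 cm**2) because attack densities are conventionally quoted in
holes per dm**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Window",
    "AttackPattern",
    "CensusSeries",
    "DensityValue",
    "FormatError",
    "ValidationError",
    "DegenerateHullError",
    "InsufficientPointsError",
    "convex_hull",
    "density",
    "nn_distances",
    "load_attack_table",
    "load_segment_table",
    "load_patch_table",
    "load_trap_table",
]

#: geometric tolerance for boundary-inclusive containment tests (cm)
BOUNDARY_TOL = 1e-9

#: two holes closer than this are considered a duplicate record (cm)
MIN_SEPARATION = 1e-6


class FormatError(ValueError):
    """An input table does not conform to the expected schema."""


class ValidationError(ValueError):
    """Input data violate a structural invariant (e.g. point outside window)."""


class DegenerateHullError(ValueError):
    """Fewer than three non-collinear points: the convex hull has no area."""


class InsufficientPointsError(ValueError):
    """An operation needs more points than the pattern provides."""


# ---------------------------------------------------------------------------
# Window
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """A convex planar observation window.

    Vertices are stored counter-clockwise; ``kind`` distinguishes the
    axis-aligned rectangle of a full segment surface from a general convex
    polygon (typically a convex hull of attack holes).
    """

    vertices: tuple[tuple[float, float], ...]
    kind: str = "convex-polygon"

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValidationError("a window needs at least 3 (x, y) vertices")
        if not np.all(np.isfinite(verts)):
            raise ValidationError("window vertices must be finite")
        area2 = _signed_area2(verts)
        if area2 < 0:  # normalise to counter-clockwise
            verts = verts[::-1]
            object.__setattr__(self, "vertices", tuple(map(tuple, verts)))
            area2 = -area2
        if area2 <= 0:
            raise ValidationError("window area must be positive")
        if not _is_convex_ccw(verts):
            raise ValidationError("window polygon must be simple and convex")

    # -- constructors ------------------------------------------------------

    @classmethod
    def rectangle(cls, length_cm: float, circumference_cm: float) -> "Window":
        """Axis-aligned segment surface: x in [0, length], y in [0, circumference]."""
        if length_cm <= 0 or circumference_cm <= 0:
            raise ValidationError("rectangle sides must be positive")
        verts = ((0.0, 0.0), (length_cm, 0.0), (length_cm, circumference_cm), (0.0, circumference_cm))
        return cls(vertices=verts, kind="rectangle")

    # -- geometry ----------------------------------------------------------

    @property
    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    @property
    def area_cm2(self) -> float:
        return 0.5 * _signed_area2(self.vertex_array)

    @property
    def area_dm2(self) -> float:
        return self.area_cm2 / 100.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        v = self.vertex_array
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    @property
    def diameter_cm(self) -> float:
        v = self.vertex_array
        d = v[:, None, :] - v[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).max())

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def _edge_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Inward unit normals and an anchor vertex per edge (CCW polygon)."""
        v = self.vertex_array
        edges = np.roll(v, -1, axis=0) - v
        lengths = np.hypot(edges[:, 0], edges[:, 1])
        # for CCW orientation the inward normal of edge (dx, dy) is (-dy, dx)
        normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
        return normals, v

    def contains(self, points: np.ndarray, tol: float = BOUNDARY_TOL) -> np.ndarray:
        """Boundary-inclusive containment test, vectorised over points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        normals, anchors = self._edge_normals()
        # signed distance of each point to each edge line; >= 0 means inside
        d = np.einsum("pk,ek->pe", pts, normals) - np.einsum("ek,ek->e", anchors, normals)
        return np.all(d >= -tol, axis=1)

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from interior points to the window boundary.

        For a convex window this is the minimum perpendicular distance to the
        supporting line of any edge (clipped at 0 for boundary points).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        normals, anchors = self._edge_normals()
        d = np.einsum("pk,ek->pe", pts, normals) - np.einsum("ek,ek->e", anchors, normals)
        return np.maximum(d.min(axis=1), 0.0)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n i.i.d. uniform points inside the window (rejection from bbox)."""
        if n == 0:
            return np.empty((0, 2))
        xmin, ymin, xmax, ymax = self.bounds
        out = []
        got = 0
        while got < n:
            m = max(int(1.6 * (n - got)) + 8, 16)
            cand = np.column_stack(
                [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
            )
            keep = cand[self.contains(cand)]
            out.append(keep[: n - got])
            got += len(keep[: n - got])
        return np.vstack(out)


def _signed_area2(verts: np.ndarray) -> float:
    """Twice the signed (shoelace) area of a polygon."""
    x, y = verts[:, 0], verts[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _is_convex_ccw(verts: np.ndarray, tol: float = 1e-12) -> bool:
    e = np.roll(verts, -1, axis=0) - verts
    cross = e[:, 0] * np.roll(e[:, 1], -1) - e[:, 1] * np.roll(e[:, 0], -1)
    scale = max(1.0, float(np.abs(e).max()) ** 2)
    return bool(np.all(cross >= -tol * scale))


# ---------------------------------------------------------------------------
# Patterns and censuses
# ---------------------------------------------------------------------------

TEXTURES = ("smooth", "rough", "unknown")


@dataclass(frozen=True)
class AttackPattern:
    """Marked spatio-temporal point set of entrance holes in a window.

    ``days`` carries the census day of each hole; ``texture`` marks whether
    the hole sits on rough or smooth bark.  ``day_range`` bounds admissible
    census days; pass ``None`` for simulated pseudo-time (acceptance order).
    """

    segment_id: str
    points: np.ndarray
    days: np.ndarray
    texture: np.ndarray
    window: Window
    day_range: tuple[float, float] | None = (0.0, 45.0)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        days = np.asarray(self.days, dtype=float).reshape(-1)
        tex = np.asarray(self.texture, dtype=object).reshape(-1)
        if not (len(pts) == len(days) == len(tex)):
            raise ValidationError("points, days and texture must have equal length")
        if len(pts) and not np.all(np.isfinite(pts)):
            raise ValidationError("coordinates must be finite")
        if len(pts):
            inside = self.window.contains(pts)
            if not np.all(inside):
                rows = np.flatnonzero(~inside).tolist()
                raise ValidationError(
                    f"points outside window for segment {self.segment_id!r} at rows {rows}"
                )
            bad = set(tex) - set(TEXTURES)
            if bad:
                raise ValidationError(f"unknown texture marks: {sorted(bad)}")
            if self.day_range is not None:
                lo, hi = self.day_range
                if days.size and (days.min() < lo or days.max() > hi):
                    raise ValidationError(f"census days outside [{lo}, {hi}]")
            if len(pts) >= 2:
                d, _ = cKDTree(pts).query(pts, k=2)
                if d[:, 1].min() <= MIN_SEPARATION:
                    raise ValidationError(
                        "duplicate coordinates: two holes separated by <= 1e-6 cm"
                    )
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "texture", tex)

    @property
    def n(self) -> int:
        return len(self.points)

    def up_to_day(self, day: float) -> "AttackPattern":
        """Cumulative sub-pattern of holes present at census ``day``."""
        keep = self.days <= day + 1e-9
        return AttackPattern(
            segment_id=self.segment_id,
            points=self.points[keep],
            days=self.days[keep],
            texture=self.texture[keep],
            window=self.window,
            day_range=self.day_range,
        )

    def census_series(self, census_times: np.ndarray) -> "CensusSeries":
        times = np.asarray(census_times, dtype=float)
        counts = np.array([(self.days <= t + 1e-9).sum() for t in times])
        return CensusSeries(times=times, counts=counts)


@dataclass(frozen=True)
class CensusSeries:
    """Cumulative entrance-hole counts H(t) at the census days t."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.counts)
        if len(t) != len(h):
            raise ValidationError("times and counts must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValidationError("census times must be strictly increasing")
        if np.any(h < 0):
            raise ValidationError("counts must be non-negative")
        if len(h) and np.any(np.diff(h.astype(float)) < 0):
            raise ValidationError("cumulative counts must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", np.asarray(h, dtype=float))


@dataclass(frozen=True)
class DensityValue:
    """An attack density in holes per dm**2 on a stated areal basis."""

    value: float
    basis: str  # "segment" or "hull"
    at_day: float | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("segment", "hull"):
            raise ValidationError("basis must be 'segment' or 'hull'")
        if self.value < 0:
            raise ValidationError("density must be non-negative")


def density(count: int, area_dm2: float, basis: str, at_day: float | None = None) -> DensityValue:
    """Attack density count / area, in holes per dm**2."""
    if area_dm2 <= 0:
        raise ValidationError("area must be positive")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return DensityValue(value=count / area_dm2, basis=basis, at_day=at_day)


# ---------------------------------------------------------------------------
# Hulls and nearest neighbours
# ---------------------------------------------------------------------------


def convex_hull(points: np.ndarray) -> Window:
    """Most compact convex polygon encompassing all the points.

    Raises :class:`DegenerateHullError` for fewer than three non-collinear
    points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateHullError("a convex hull needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate (collinear) point set: {exc}") from exc
    verts = pts[hull.vertices]  # scipy returns CCW order in 2-D
    return Window(vertices=tuple(map(tuple, verts)), kind="convex-polygon")


def nn_distances(points: np.ndarray, axis_mode: str = "euclidean") -> np.ndarray:
    """Per-point distance to its nearest other point.

    ``axis_mode`` selects the full planar distance or the projection onto a
    single axis (|dx| or |dy| alone), used to check the isotropy of the
    inhibition zone.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise InsufficientPointsError("nearest-neighbour distances need >= 2 points")
    if axis_mode == "euclidean":
        d, _ = cKDTree(pts).query(pts, k=2)
        return d[:, 1]
    if axis_mode in ("x_only", "y_only"):
        vals = pts[:, 0] if axis_mode == "x_only" else pts[:, 1]
        order = np.argsort(vals, kind="stable")
        s = vals[order]
        gaps = np.diff(s)
        out = np.empty(n)
        out[order[0]] = gaps[0]
        out[order[-1]] = gaps[-1]
        if n > 2:
            out[order[1:-1]] = np.minimum(gaps[:-1], gaps[1:])
        return out
    raise ValueError(f"unknown axis_mode {axis_mode!r}")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

ATTACK_COLUMNS = ["segment_id", "x_cm", "y_cm", "day", "texture"]
SEGMENT_COLUMNS = ["segment_id", "tree_id", "length_cm", "circumference_cm", "area_dm2"]
PATCH_COLUMNS = ["segment_id", "patch_id", "shape", "cx_cm", "cy_cm", "radius_cm"]
TRAP_COLUMNS = ["day", "n_landed", "n_sexed", "n_males", "trap_area_dm2"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def load_attack_table(path, windows: dict[str, Window] | None = None) -> list[AttackPattern]:
    """Read an attacks.csv file into one :class:`AttackPattern` per segment.

    ``windows`` maps segment ids to observation windows; segments without an
    entry get the bounding rectangle of their own points.  Points outside
    their window raise a :class:`ValidationError` naming the offending file
    rows.
    """
    df = _read_csv(path, ATTACK_COLUMNS)
    df = df.reset_index().rename(columns={"index": "_row"})
    patterns: list[AttackPattern] = []
    for seg_id, grp in df.groupby("segment_id", sort=True):
        grp = grp.sort_values(["day", "_row"], kind="stable")
        pts = grp[["x_cm", "y_cm"]].to_numpy(dtype=float)
        if windows is not None and str(seg_id) in windows:
            window = windows[str(seg_id)]
        else:
            xmin, ymin = pts.min(axis=0)
            xmax, ymax = pts.max(axis=0)
            if xmax - xmin <= 0 or ymax - ymin <= 0:
                raise ValidationError(
                    f"segment {seg_id!r}: cannot infer a bounding rectangle from "
                    "degenerate coordinates; supply a window"
                )
            window = Window(
                vertices=((xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)),
                kind="rectangle",
            )
        inside = window.contains(pts)
        if not np.all(inside):
            rows = (grp["_row"].to_numpy()[~inside] + 2).tolist()  # header is line 1
            raise ValidationError(
                f"segment {seg_id!r}: points outside window at file lines {rows}"
            )
        patterns.append(
            AttackPattern(
                segment_id=str(seg_id),
                points=pts,
                days=grp["day"].to_numpy(dtype=float),
                texture=grp["texture"].astype(str).to_numpy(dtype=object),
                window=window,
            )
        )
    return patterns


def load_segment_table(path) -> pd.DataFrame:
    df = _read_csv(path, SEGMENT_COLUMNS)
    return df.astype({"segment_id": str})


def segment_windows(segments: pd.DataFrame) -> dict[str, Window]:
    """Rectangle windows (length x circumference) from a segments table."""
    return {
        str(row.segment_id): Window.rectangle(row.length_cm, row.circumference_cm)
        for row in segments.itertuples()
    }


def load_patch_table(path) -> pd.DataFrame:
    df = _read_csv(path, PATCH_COLUMNS)
    return df.astype({"segment_id": str})


def load_trap_table(path) -> pd.DataFrame:
    return _read_csv(path, TRAP_COLUMNS)
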
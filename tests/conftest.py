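import numpy as np
import pytest

from barkspat import geometry as geo
from barkspat import inference as inf


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def grid_points(nx: int, ny: int, spacing: float, origin=(0.0, 0.0)) -> np.ndarray:
    gx, gy = np.meshgrid(
        origin[0] + np.arange(nx) * spacing, origin[1] + np.arange(ny) * spacing
    )
    return np.column_stack([gx.ravel(), gy.ravel()])


def make_pattern(points, window, days=None, texture=None, segment_id="t"):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return geo.AttackPattern(
        segment_id=segment_id,
        points=points,
        days=np.zeros(n) if days is None else np.asarray(days, dtype=float),
        texture=np.array(["unknown"] * n, dtype=object) if texture is None else texture,
        window=window,
        day_range=None,
    )
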
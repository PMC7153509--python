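import numpy as np
import pytest
from scipy.spatial import ConvexHull


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12, scale: float = 100.0):
    """Convex hull of random points — a generic convex particle outline."""
    pts = rng.normal(0.0, scale, (n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _widths_at(outline: np.ndarray, angles: np.ndarray) -> np.ndarray:
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = np.asarray(outline, dtype=float) @ dirs.T  # (n_vertices, n_angles)
    return proj.max(axis=0) - proj.min(axis=0)


def feret_rotation_scan(outline: np.ndarray, step_deg: float = 0.05):
    """Independent brute-force Feret extents: scan projection directions.

    The Feret diameter along direction theta is the extent of the vertex
    projections onto that direction; Fmax/Fmin are the extremes over a
    half-turn scanned in ``step_deg`` steps.  The width function is kinked
    at its minimum (attained flush with a polygon edge), so the coarse scan
    is followed by a fine re-scan of the bracketing interval to remove the
    first-order discretization error.
    """
    step = np.deg2rad(step_deg)
    angles = np.arange(0.0, np.pi, step)
    widths = _widths_at(outline, angles)
    i_min, i_max = int(np.argmin(widths)), int(np.argmax(widths))
    fine_min = _widths_at(
        outline, np.linspace(angles[i_min] - step, angles[i_min] + step, 401)
    ).min()
    fine_max = _widths_at(
        outline, np.linspace(angles[i_max] - step, angles[i_max] + step, 401)
    ).max()
    return float(fine_min), float(fine_max)


def iterative_trim_oracle(readings, k: float = 5.0):
    """Literal re-implementation of iterative mean + k·sigma baseline trimming.

    Pure-Python loop over explicit inlier lists; returns (mu, sigma,
    threshold, sorted outlier indices).
    """
    import statistics

    values = [float(x) for x in readings]
    inliers = list(range(len(values)))
    while True:
        data = [values[i] for i in inliers]
        mu = statistics.fmean(data)
        sd = statistics.stdev(data) if len(data) > 1 else 0.0
        thr = mu + k * sd
        kept = [i for i in inliers if values[i] <= thr]
        if kept == inliers:
            return mu, sd, thr, sorted(set(range(len(values))) - set(kept))
        inliers = kept
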
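"""Kernel-smoothed interpolated points along a pseudotime axis.

Aligning every cell against every cell would be slow and noisy, so each
trajectory is summarized by ``u`` interpolated points placed evenly over its
pseudotime range. Every point carries a Gaussian-smoothed expression profile
of the surrounding cells. The kernel bandwidth starts from a shared base
``window_size`` and is adjusted per point by local cell density: crowded
points get a narrower window, sparse points a wider one, so that smoothing
tracks the data where it is dense without losing coverage where it is thin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from trajalign.io import TrajectoryData

logger = logging.getLogger("trajalign")


@dataclass
class InterpolatedTrajectory:
    """Interpolated points of one trajectory.

    Attributes
    ----------
    name : str
        Condition label, inherited from the source trajectory.
    point_pseudotime : ndarray of shape (u,)
        Pseudotime of each interpolated point, strictly increasing from
        ``min(p)`` to ``max(p)``.
    base_window : float
        The unadjusted kernel window size.
    point_counts : ndarray of shape (u,)
        Number of cells within ``base_window`` of each point.
    point_windows : ndarray of shape (u,)
        Density-adjusted kernel bandwidth per point, all positive.
    point_expression : ndarray of shape (g, u)
        Smoothed expression per gene and point.
    source : TrajectoryData
        The cell-level data the points were computed from.
    """

    name: str
    point_pseudotime: np.ndarray = field(repr=False)
    base_window: float = field(repr=False, default=0.0)
    point_counts: np.ndarray = field(repr=False, default=None)
    point_windows: np.ndarray = field(repr=False, default=None)
    point_expression: np.ndarray = field(repr=False, default=None)
    source: TrajectoryData = field(repr=False, default=None)

    @property
    def n_points(self) -> int:
        return len(self.point_pseudotime)


def default_window_size(max_pseudotime: float, n_points: int) -> float:
    """Base kernel window: the maximum pseudotime divided by 90% of ``u``.

    Scales the window with the spacing of the interpolated points while
    leaving the windows of neighboring points slightly overlapping.
    """
    if n_points < 2:
        raise ValueError("need at least 2 interpolated points")
    if max_pseudotime <= 0:
        raise ValueError("maximum pseudotime must be positive")
    return max_pseudotime / (0.9 * n_points)


def place_points(p: np.ndarray, n_points: int) -> np.ndarray:
    """Evenly spaced interpolated points over [min(p), max(p)], inclusive."""
    p = np.asarray(p, dtype=float)
    if n_points < 2:
        raise ValueError("need at least 2 interpolated points")
    lo, hi = p.min(), p.max()
    if hi <= lo:
        raise ValueError("pseudotime is constant; cannot place points")
    return np.linspace(lo, hi, n_points)


def adaptive_windows(
    p: np.ndarray, q: np.ndarray, window_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point cell counts and density-adjusted window sizes.

    ``counts[h]`` is the number of cells with ``|p - q[h]| <= window_size``
    (inclusive bounds). The adjusted window is

    ``window_size * (1 - (counts[h] - mean(counts)) / max(counts))``

    so points with above-average density shrink their window and sparse
    points widen it; a point at exactly the mean density keeps the base
    window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dist = np.abs(p[None, :] - q[:, None])
    counts = (dist <= window_size).sum(axis=1)
    if counts.max() == 0:
        raise ValueError("empty trajectory coverage: no cell near any interpolated point")
    windows = window_size * (1.0 - (counts - counts.mean()) / counts.max())
    return counts.astype(int), windows


def smooth_expression(
    X: np.ndarray, p: np.ndarray, q: np.ndarray, point_windows: np.ndarray
) -> np.ndarray:
    """Gaussian-kernel smoothed expression at each interpolated point.

    ``out[k, h]`` is the weighted mean of gene ``k`` over all cells with
    weight ``exp(-(p_l - q_h)^2 / w_h^2)`` where ``w_h`` is that point's
    adjusted window. Weights are normalized per point, so each column is a
    convex combination of cell profiles.
    """
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    w = np.asarray(point_windows, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all point windows must be positive")
    # weights[l, h]
    weights = np.exp(-((p[:, None] - q[None, :]) ** 2) / (w[None, :] ** 2))
    totals = weights.sum(axis=0)
    dead = np.nonzero(totals <= 1e-300)[0]
    if dead.size:
        raise ValueError(
            f"interpolated point {dead[0]} at pseudotime {q[dead[0]]:.4g} has "
            "zero total kernel weight (pseudotime gap?)"
        )
    return (X @ weights) / totals


def check_pseudotime_gaps(p: np.ndarray, window_size: float) -> list[str]:
    """Warn about empty pseudotime intervals longer than twice the window.

    The alignment cannot bridge stretches of the axis with no cells: no
    kernel window covers them and smoothed expression there is extrapolated.
    Returns one warning string per gap; nothing is mutated.
    """
    p = np.sort(np.asarray(p, dtype=float))
    warnings = []
    gaps = np.diff(p)
    for k in np.nonzero(gaps > 2 * window_size)[0]:
        msg = (
            f"pseudotime gap ({p[k]:.4g}, {p[k + 1]:.4g}) longer than twice "
            f"the window size {window_size:.4g}; alignment may be unreliable"
        )
        warnings.append(msg)
        logger.warning(msg)
    return warnings


def interpolate(
    trajectory: TrajectoryData,
    n_points: int,
    window_size: float | None = None,
) -> InterpolatedTrajectory:
    """Compute the interpolated-point summary of a trajectory.

    ``window_size`` defaults to :func:`default_window_size` of the
    trajectory's maximum pseudotime. 10-20 points per cluster in the larger
    dataset is the recommended range for ``n_points``; both trajectories of
    a pair should use the same value.
    """
    p = trajectory.pseudotime
    if window_size is None:
        window_size = default_window_size(p.max(), n_points)
    q = place_points(p, n_points)
    check_pseudotime_gaps(p, window_size)
    counts, windows = adaptive_windows(p, q, window_size)
    smoothed = smooth_expression(trajectory.expression, p, q, windows)
    return InterpolatedTrajectory(
        name=trajectory.name,
        point_pseudotime=q,
        base_window=float(window_size),
        point_counts=counts,
        point_windows=windows,
        point_expression=smoothed,
        source=trajectory,
    )
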
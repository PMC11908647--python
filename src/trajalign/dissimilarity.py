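"""Transcriptomic dissimilarity between interpolated points.

The cost between two smoothed expression profiles is, by default, a Spearman
rank-correlation distance rescaled so that 0 means perfect positive
correlation and 2 perfect anti-correlation; Pearson distance (1 - r) and
Euclidean distance are available as alternatives. For tie-free vectors the
Spearman cost equals the classical ``6 * sum(d_v^2) / (g (g^2 - 1))``
rank-difference form; with ties, average ranks are used, which reduces to the
same value when ties are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from trajalign.interpolation import InterpolatedTrajectory

METRICS = ("spearman", "pearson", "euclidean")


@dataclass
class DissimilarityMatrix:
    """Pairwise costs between the points of two trajectories.

    ``values[i, j]`` is the cost between point ``i`` of the row trajectory
    and point ``j`` of the column trajectory; shape ``(n, m)``.
    """

    values: np.ndarray = field(repr=False)
    metric: str = "spearman"
    row_trajectory: str = "A"
    col_trajectory: str = "B"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        n, m = self.values.shape
        return pd.DataFrame(
            self.values,
            index=[f"{self.row_trajectory}_{i + 1}" for i in range(n)],
            columns=[f"{self.col_trajectory}_{j + 1}" for j in range(m)],
        )


def _check_variance(x: np.ndarray, y: np.ndarray, metric: str) -> None:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"zero-variance expression profile under {metric} metric; "
            "correlation is undefined for a flat interpolated point"
        )


def cost(x: np.ndarray, y: np.ndarray, metric: str = "spearman") -> float:
    """Dissimilarity between two length-g expression profiles.

    spearman
        ``1 - rho`` with average ranks under ties; range [0, 2].
    pearson
        ``1 - r``; range [0, 2].
    euclidean
        plain L2 distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression profiles must be 1-D and equally long")
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if len(x) < 3:
        raise ValueError("correlation metrics need at least 3 genes")
    _check_variance(x, y, metric)
    if metric == "spearman":
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        return float(1.0 - np.corrcoef(rx, ry)[0, 1])
    if metric == "pearson":
        return float(1.0 - np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _rank_matrix(X: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(X, axis=0)


def dissimilarity_matrix(
    a: InterpolatedTrajectory,
    b: InterpolatedTrajectory,
    metric: str = "spearman",
) -> DissimilarityMatrix:
    """All-pairs cost matrix between the points of two trajectories.

    Both trajectories must carry the same genes in the same order (use
    :func:`trajalign.io.harmonize_genes` upstream).
    """
    Xa, Xb = a.point_expression, b.point_expression
    if Xa.shape[0] != Xb.shape[0]:
        raise ValueError("trajectories have different gene counts; harmonize first")
    if metric == "euclidean":
        diff = Xa[:, :, None] - Xb[:, None, :]
        D = np.sqrt((diff**2).sum(axis=0))
    elif metric in ("spearman", "pearson"):
        if Xa.shape[0] < 3:
            raise ValueError("correlation metrics need at least 3 genes")
        for X, which in ((Xa, a.name), (Xb, b.name)):
            flat = np.nonzero(np.ptp(X, axis=0) == 0)[0]
            if flat.size:
                raise ValueError(
                    f"interpolated point {flat[0]} of {which} has zero-variance "
                    "expression; correlation is undefined"
                )
        Za = _rank_matrix(Xa) if metric == "spearman" else Xa
        Zb = _rank_matrix(Xb) if metric == "spearman" else Xb
        Za = (Za - Za.mean(axis=0)) / Za.std(axis=0)
        Zb = (Zb - Zb.mean(axis=0)) / Zb.std(axis=0)
        D = 1.0 - (Za.T @ Zb) / Za.shape[0]
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return DissimilarityMatrix(
        values=np.asarray(D, dtype=float),
        metric=metric,
        row_trajectory=a.name,
        col_trajectory=b.name,
    )
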
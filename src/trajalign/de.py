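"""Windowed cross-condition differential expression on the aligned axis.

The kept matches of the alignment are tiled into ``n_windows`` overlapping
windows (a sliding-window soft clustering: junction matches belong to two
windows). Cells are assigned to their trajectory's interpolated points by a
single round of k-means on the aligned pseudotime axis (nearest point in
squared distance, no centroid update), and each window pools the cells of its
matched points from each condition. Per window and gene, a two-sided
Mann-Whitney U test compares the conditions; the fold change follows the
Seurat V5 convention ``log2(mean(expm1(x)) + 1)`` per group, which assumes
log1p-normalized input. P-values are Bonferroni-adjusted within each window,
and a gene is flagged significant when the adjusted p, the absolute fold
change and the fraction of expressing cells all pass their thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger("trajalign")

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 0.5
DEFAULT_PCT_MIN = 0.1
DEFAULT_MIN_CELLS = 3


@dataclass
class WindowScheme:
    """How kept matches are tiled into overlapping comparison windows."""

    n_windows: int
    overlap: int
    matches_total: int
    total_with_overlap: int
    window_match_counts: list
    window_members: list = field(repr=False)


@dataclass
class DEResult:
    """Per-window, per-gene test results."""

    table: pd.DataFrame = field(repr=False)
    scheme: WindowScheme = None
    alpha: float = DEFAULT_ALPHA
    lfc_min: float = DEFAULT_LFC_MIN
    pct_min: float = DEFAULT_PCT_MIN

    def significant_genes(self) -> list:
        t = self.table
        return sorted(t.loc[t["significant"], "gene"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def window_scheme(matches: list | int, n_windows: int, overlap: int) -> WindowScheme:
    """Tile the match sequence into windows sharing ``overlap`` matches.

    The total number of window slots is
    ``total = matches + overlap * n_windows - overlap``; per-window counts
    come from repeatedly taking ``round(total_remaining / windows_remaining)``
    (rounding half away from zero). Window w+1 starts ``overlap`` matches
    before window w ends, so consecutive windows share exactly ``overlap``
    matches and the counts sum to ``total``.
    """
    if isinstance(matches, int):
        match_list = list(range(matches))
    else:
        match_list = list(matches)
    n_matches = len(match_list)
    if n_windows < 1:
        raise ValueError("need at least one window")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    minimum = overlap * (n_windows - 1) + n_windows
    if n_matches < minimum:
        raise ValueError(
            f"{n_matches} matches cannot fill {n_windows} windows with overlap "
            f"{overlap}; at least {minimum} matches are needed"
        )
    total = (n_matches + overlap * n_windows) - overlap
    counts = []
    remaining, w = total, n_windows
    while w != 0:
        current = _round_half_away(remaining / w)
        counts.append(current)
        remaining -= current
        w -= 1
    members, start = [], 0
    for c in counts:
        members.append(match_list[start : start + c])
        start += c - overlap
    return WindowScheme(
        n_windows=n_windows,
        overlap=overlap,
        matches_total=n_matches,
        total_with_overlap=total,
        window_match_counts=counts,
        window_members=members,
    )


def assign_cells_to_points(p_aligned: np.ndarray, q_aligned: np.ndarray) -> np.ndarray:
    """Nearest interpolated point per cell on the aligned axis.

    One round of k-means with the points as fixed centroids: each cell goes
    to the point minimizing the squared pseudotime distance; ties go to the
    lower point index.
    """
    p = np.asarray(p_aligned, dtype=float)
    q = np.asarray(q_aligned, dtype=float)
    if q.size == 0:
        raise ValueError("no interpolated points to assign cells to")
    return np.argmin((p[:, None] - q[None, :]) ** 2, axis=1)


def _perm_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Works on midranks so ties are handled exactly; only called for small
    pooled samples where the enumeration is cheap.
    """
    import itertools

    n = len(a)
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    obs = ranks[:n].sum()
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(ranks, n)), dtype=float
    )
    eps = 1e-9
    p_lo = np.mean(sums <= obs + eps)
    p_hi = np.mean(sums >= obs - eps)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def _mwu_pvalues(XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per gene (rows).

    Exact for small groups (scipy's U null distribution when tie-free, full
    permutation enumeration when ties are present and the pooled sample is
    tiny); normal approximation with tie correction otherwise.
    """
    nA, nB = XA.shape[1], XB.shape[1]
    small = max(nA, nB) <= 20
    p = np.empty(XA.shape[0])
    for k in range(XA.shape[0]):
        a, b = XA[k], XB[k]
        if np.ptp(np.concatenate([a, b])) == 0:
            p[k] = 1.0
            continue
        ties = len(np.unique(np.concatenate([a, b]))) < nA + nB
        if small and not ties:
            p[k] = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            ).pvalue
        elif ties and nA + nB <= 16:
            p[k] = _perm_exact_p(a, b)
        else:
            p[k] = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
    return p


def window_test(XA: np.ndarray, XB: np.ndarray) -> pd.DataFrame:
    """Per-gene statistics for one window.

    ``XA`` and ``XB`` are gene-by-cell slices of log1p-normalized expression
    for the two conditions. Returns p_value, log2fc (Seurat V5 convention,
    positive when A is higher), and per-condition fractions of expressing
    cells.
    """
    XA = np.atleast_2d(np.asarray(XA, dtype=float))
    XB = np.atleast_2d(np.asarray(XB, dtype=float))
    if XA.shape[1] == 0 or XB.shape[1] == 0:
        raise ValueError("both condition groups must be non-empty")
    p = _mwu_pvalues(XA, XB)
    lfc = np.log2(np.expm1(XA).mean(axis=1) + 1) - np.log2(np.expm1(XB).mean(axis=1) + 1)
    return pd.DataFrame(
        {
            "p_value": p,
            "log2fc": lfc,
            "pct_expressed_a": (XA > 0).mean(axis=1),
            "pct_expressed_b": (XB > 0).mean(axis=1),
            "n_cells_a": XA.shape[1],
            "n_cells_b": XB.shape[1],
        }
    )


def run_de(
    alignment,
    warped_a,
    warped_b,
    n_windows: int = 4,
    overlap: int = 1,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    pct_min: float = DEFAULT_PCT_MIN,
    min_cells: int = DEFAULT_MIN_CELLS,
    genes: list | None = None,
) -> DEResult:
    """Windowed differential expression between two aligned conditions.

    For each window, the cells assigned (on the aligned axis) to that
    window's matched interpolated points are pooled per condition and every
    gene is tested. Cells sitting at pruned points are excluded: only the
    matched process segments are comparable. Windows where either condition
    has fewer than ``min_cells`` cells are skipped with a warning.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    scheme = window_scheme(alignment.kept_matches, n_windows, overlap)
    if warped_a.source is None or warped_b.source is None:
        raise ValueError("warped trajectories must carry cell-level data for DE")

    # genes come from the harmonized source expression
    Xa = warped_a.source.expression
    Xb = warped_b.source.expression
    gene_names = genes if genes is not None else warped_a.source.genes
    if Xa.shape[0] != Xb.shape[0]:
        raise ValueError("conditions have different gene counts; harmonize first")

    assign_a = assign_cells_to_points(
        warped_a.cell_aligned_pseudotime, warped_a.aligned_point_pseudotime
    )
    assign_b = assign_cells_to_points(
        warped_b.cell_aligned_pseudotime, warped_b.aligned_point_pseudotime
    )

    frames = []
    for w, members in enumerate(scheme.window_members, start=1):
        points_a = {i for i, _ in members}
        points_b = {j for _, j in members}
        cells_a = np.nonzero(np.isin(assign_a, list(points_a)))[0]
        cells_b = np.nonzero(np.isin(assign_b, list(points_b)))[0]
        if len(cells_a) < min_cells or len(cells_b) < min_cells:
            logger.warning(
                "window %d skipped: %d vs %d cells (minimum %d per condition)",
                w, len(cells_a), len(cells_b), min_cells,
            )
            continue
        stats = window_test(Xa[:, cells_a], Xb[:, cells_b])
        stats.insert(0, "window_id", w)
        stats.insert(0, "gene", gene_names)
        n_tests = len(stats)
        stats["p_adjusted"] = np.minimum(1.0, stats["p_value"] * n_tests)
        stats["significant"] = (
            (stats["p_adjusted"] < alpha)
            & (stats["log2fc"].abs() > lfc_min)
            & (stats[["pct_expressed_a", "pct_expressed_b"]].max(axis=1) > pct_min)
        )
        frames.append(stats)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=[
                "gene", "window_id", "p_value", "log2fc", "pct_expressed_a",
                "pct_expressed_b", "n_cells_a", "n_cells_b", "p_adjusted",
                "significant",
            ]
        )
    return DEResult(table=table, scheme=scheme, alpha=alpha, lfc_min=lfc_min, pct_min=pct_min)
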
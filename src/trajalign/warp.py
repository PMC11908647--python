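"""Warp pseudotime so matched interpolated points share a common axis.

Matched points of the two trajectories should end up at (numerically) equal
pseudotime. Matches are processed in path order. For a 1:1 match the
trajectory whose matched point sits at the larger pseudotime has that point
and everything after it shifted back so the pair coincides; the shifts of
later matches accumulate. In a multi-match (several consecutive points on
one side matched to a single point on the other) only the first pair is
aligned that way; the remaining members are then evenly re-spaced between the
aligned value of the first pair and the aligned value of the next match
beyond the block. Points in pruned gaps are re-spaced the same way between
the bounding kept matches, which keeps the warped axis monotone. Finally the
aligned point pseudotimes are carried back onto individual cells with the
same Gaussian kernel used for interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from trajalign.alignment import Alignment
from trajalign.interpolation import InterpolatedTrajectory

logger = logging.getLogger("trajalign")


@dataclass
class WarpedTrajectory:
    """One trajectory's pseudotime before and after alignment."""

    name: str
    original_point_pseudotime: np.ndarray = field(repr=False)
    aligned_point_pseudotime: np.ndarray = field(repr=False)
    unmatched_point_mask: np.ndarray = field(repr=False)
    cells: list = field(repr=False, default=None)
    original_cell_pseudotime: np.ndarray = field(repr=False, default=None)
    cell_aligned_pseudotime: np.ndarray = field(repr=False, default=None)
    source: object = field(repr=False, default=None)


def _blocks(matches: list) -> list:
    """Group path-ordered matches into 1:1 blocks and multi-match blocks.

    A block is a maximal run of matches sharing one coordinate while the
    other advances by exactly 1 (i.e. consecutive DTW steps along one row or
    column). Matches separated by a pruned gap never share a block.
    """
    blocks: list[list] = []
    for m in matches:
        if blocks:
            prev = blocks[-1][-1]
            same_i = m[0] == prev[0] and m[1] == prev[1] + 1
            same_j = m[1] == prev[1] and m[0] == prev[0] + 1
            if len(blocks[-1]) == 1 and (same_i or same_j):
                blocks[-1].append(m)
                continue
            if len(blocks[-1]) > 1:
                b = blocks[-1]
                const_i = b[0][0] == b[1][0]
                if (const_i and m[0] == b[0][0] and m[1] == prev[1] + 1) or (
                    not const_i and m[1] == b[0][1] and m[0] == prev[0] + 1
                ):
                    blocks[-1].append(m)
                    continue
        blocks.append([m])
    return blocks


def align_individual_match(
    points_a: np.ndarray, points_b: np.ndarray, match: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Align one 1:1 match: shift the later-running trajectory's suffix.

    The trajectory whose matched point has the larger pseudotime has that
    point and all later points shifted by the (negative) difference, so the
    matched pair coincides. Returns updated copies.
    """
    A = np.asarray(points_a, dtype=float).copy()
    B = np.asarray(points_b, dtype=float).copy()
    i, j = match
    if A[i] > B[j]:
        A[i:] += B[j] - A[i]
    elif B[j] > A[i]:
        B[j:] += A[i] - B[j]
    return A, B


def align_multi_match(
    points: np.ndarray,
    block_indices: list,
    next_index: int | None,
    next_value: float | None = None,
) -> np.ndarray:
    """Re-space the extra members of a multi-match block.

    ``block_indices`` are the consecutive indices (on the multi side) of one
    block whose first member has already been aligned; members after the
    first are evenly spaced between the first member's value and
    ``next_value`` (the aligned value at ``next_index``, the first match
    beyond the block). With no next match the original spacing is already
    preserved by the suffix shift, so the points are returned unchanged.
    """
    q = np.asarray(points, dtype=float).copy()
    first = block_indices[0]
    if next_index is None:
        return q
    if next_value is None:
        next_value = q[next_index]
    gap = next_index - first
    if gap > 1:
        q[first + 1 : next_index] = (
            q[first] + (next_value - q[first]) * np.arange(1, gap) / gap
        )
    return q


def align_point_pseudotime(
    q_a: np.ndarray, q_b: np.ndarray, matches: list
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned point pseudotimes for both trajectories given kept matches.

    ``matches`` are 0-based (index_a, index_b) pairs in path order. Returns
    the two warped point-pseudotime vectors; both are non-decreasing and the
    first pair of every block coincides exactly.
    """
    A = np.asarray(q_a, dtype=float).copy()
    B = np.asarray(q_b, dtype=float).copy()
    if not matches:
        raise ValueError("cannot warp with no kept matches")
    blocks = _blocks(matches)
    anchors = [b[0] for b in blocks]

    # Sequential individual alignment of the block anchors; each shift moves
    # the anchor and everything after it on the later-running trajectory.
    first = anchors[0]
    lead_a = lead_b = 0.0
    for k, (i, j) in enumerate(anchors):
        if A[i] > B[j]:
            delta = B[j] - A[i]
            A[i:] += delta
            if k == 0:
                lead_a = delta
        elif B[j] > A[i]:
            delta = A[i] - B[j]
            B[j:] += delta
            if k == 0:
                lead_b = delta
    # Points before the first anchor follow its shift so the lead-in stays
    # monotone and ends at the anchor.
    A[: first[0]] += lead_a
    B[: first[1]] += lead_b

    # Multi-match members and pruned-gap interiors: evenly spaced between
    # the bounding anchor values. Points after the last anchor keep the
    # spacing produced by the accumulated shifts.
    def respace(q: np.ndarray, idx: list) -> None:
        for a, b in zip(idx[:-1], idx[1:]):
            gap = b - a
            if gap > 1:
                q[a + 1 : b] = q[a] + (q[b] - q[a]) * np.arange(1, gap) / gap

    respace(A, sorted({i for i, _ in anchors}))
    respace(B, sorted({j for _, j in anchors}))
    return A, B


def warp_cells(
    p: np.ndarray,
    q_original: np.ndarray,
    q_aligned: np.ndarray,
    point_windows: np.ndarray,
) -> np.ndarray:
    """Map aligned point pseudotimes back onto individual cells.

    Each cell's aligned pseudotime is the Gaussian-kernel weighted mean of
    the aligned point pseudotimes, with weights taken from the distance
    between the cell's original pseudotime and the points' original
    pseudotimes — the same kernel used to smooth expression onto the points.
    A cell beyond the reach of every kernel keeps its offset from the
    nearest point.
    """
    p = np.asarray(p, dtype=float)
    q_original = np.asarray(q_original, dtype=float)
    q_aligned = np.asarray(q_aligned, dtype=float)
    w = np.asarray(point_windows, dtype=float)
    weights = np.exp(-((p[:, None] - q_original[None, :]) ** 2) / (w[None, :] ** 2))
    totals = weights.sum(axis=1)
    out = np.empty_like(p)
    ok = totals > 1e-300
    out[ok] = (weights[ok] @ q_aligned) / totals[ok]
    if not np.all(ok):
        for l in np.nonzero(~ok)[0]:
            h = int(np.argmin(np.abs(p[l] - q_original)))
            out[l] = q_aligned[h] + (p[l] - q_original[h])
            logger.warning(
                "cell %d at pseudotime %.4g outside all kernel windows; "
                "kept offset from nearest interpolated point", l, p[l],
            )
    return out


def warp_pair(
    alignment: Alignment,
    interp_a: InterpolatedTrajectory,
    interp_b: InterpolatedTrajectory,
) -> tuple[WarpedTrajectory, WarpedTrajectory]:
    """Warp both trajectories of an alignment onto the common axis."""
    q_a = interp_a.point_pseudotime
    q_b = interp_b.point_pseudotime
    aligned_a, aligned_b = align_point_pseudotime(q_a, q_b, alignment.kept_matches)
    mask_a = np.ones(len(q_a), dtype=bool)
    mask_b = np.ones(len(q_b), dtype=bool)
    for i, j in alignment.kept_matches:
        mask_a[i] = False
        mask_b[j] = False

    def build(interp, aligned, mask):
        cells = original = warped = None
        if interp.source is not None:
            cells = interp.source.cells
            original = interp.source.pseudotime
            warped = warp_cells(
                original, interp.point_pseudotime, aligned, interp.point_windows
            )
        return WarpedTrajectory(
            name=interp.name,
            original_point_pseudotime=interp.point_pseudotime.copy(),
            aligned_point_pseudotime=aligned,
            unmatched_point_mask=mask,
            cells=cells,
            original_cell_pseudotime=original,
            cell_aligned_pseudotime=warped,
            source=interp.source,
        )

    return build(interp_a, aligned_a, mask_a), build(interp_b, aligned_b, mask_b)


def write_warp(warped_a: WarpedTrajectory, warped_b: WarpedTrajectory, path) -> None:
    """Write per-cell aligned pseudotime for both conditions as a TSV."""
    import pandas as pd

    rows = []
    for w in (warped_a, warped_b):
        if w.cells is None:
            continue
        for cell, orig, new in zip(
            w.cells, w.original_cell_pseudotime, w.cell_aligned_pseudotime
        ):
            rows.append(
                {
                    "cell_id": cell,
                    "condition": w.name,
                    "original_pseudotime": orig,
                    "aligned_pseudotime": new,
                }
            )
    pd.DataFrame(
        rows,
        columns=["cell_id", "condition", "original_pseudotime", "aligned_pseudotime"],
    ).to_csv(path, sep="\t", index=False)
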
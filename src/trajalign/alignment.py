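"""Free-endpoint alignment of two trajectories through their cost matrix.

Classical dynamic time warping forces the path to run corner to corner, which
is wrong whenever one process is truncated or the two processes only share
part of their course. Here the endpoints are data-driven instead:

1. the minimum-cost positions on the first row/column and last row/column of
   ``D`` give provisional start and end points;
2. nearby border positions whose cost is within a cut-off band are admitted
   as alternative endpoints, extending toward the matrix corners;
3. DTW runs for every admissible (start, end) pair, and each resulting path
   is scored by bootstrap resampling of its match costs so paths of different
   lengths compare fairly;
4. among paths scoring below ``min(scores) + mean(S)`` (``S`` the matrix of
   pairwise absolute score differences), the one whose endpoints sit closest
   to the corners is chosen;
5. matches on the chosen path whose cost is closer to the off-path mean than
   to the on-path mean are pruned, so unshared middle sections stay
   unaligned.

All indices in this module are 0-based; output files add 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from trajalign.dissimilarity import DissimilarityMatrix

logger = logging.getLogger("trajalign")

#: Median Spearman cost above which an alignment is flagged as dubious
#: (1.0 is the expected cost of uncorrelated profiles).
DEFAULT_WARN_THRESHOLD = 0.8


@dataclass
class CandidatePath:
    """One DTW path for a particular (start, end) endpoint pair."""

    start: tuple
    end: tuple
    matches: list = field(repr=False)
    match_costs: np.ndarray = field(repr=False)
    total_cost: float = 0.0
    path_score: float = float("nan")

    def __len__(self) -> int:
        return len(self.matches)


@dataclass
class Alignment:
    """Result of the full endpoint search, path selection and pruning."""

    candidates: list = field(repr=False)
    chosen: CandidatePath = None
    path_scores: np.ndarray = field(repr=False, default=None)
    score_distances: np.ndarray = field(repr=False, default=None)
    cut_off_start: float = 0.0
    cut_off_end: float = 0.0
    match_threshold: float = float("nan")
    nonmatch_threshold: float = float("nan")
    kept_matches: list = field(repr=False, default_factory=list)
    segments: list = field(repr=False, default_factory=list)
    n_boot: int = 0
    boot_len: int = 0
    median_cost: float = float("nan")
    warning_flag: bool = False
    warn_threshold: float = DEFAULT_WARN_THRESHOLD
    shape: tuple = None


def _border_positions(shape: tuple, which: str):
    n, m = shape
    if which == "start":
        pos = [(i, 0) for i in range(n)] + [(0, j) for j in range(1, m)]
    else:
        pos = [(i, m - 1) for i in range(n)] + [(n - 1, j) for j in range(m - 1)]
    return pos


def find_min_endpoints(D: np.ndarray) -> tuple[tuple, tuple]:
    """Minimum-cost start and end positions on the borders of ``D``.

    The start is the argmin over the first row and first column; the end the
    argmin over the last row and last column. Ties are broken toward the
    respective corner ((0,0) for the start, (n-1,m-1) for the end) to
    maximize the alignment span.
    """
    D = np.asarray(D, dtype=float)
    n, m = D.shape

    def pick(which: str, corner: tuple) -> tuple:
        pos = _border_positions(D.shape, which)
        vals = np.array([D[p] for p in pos])
        tied = [pos[k] for k in np.nonzero(vals == vals.min())[0]]
        return min(
            tied, key=lambda p: (abs(p[0] - corner[0]) + abs(p[1] - corner[1]), p)
        )

    return pick("start", (0, 0)), pick("end", (n - 1, m - 1))


def _mean_abs_diff(border: np.ndarray) -> float:
    if len(border) < 2:
        return 0.0
    return float(np.abs(np.diff(border)).mean())


def endpoint_cutoffs(D: np.ndarray, start: tuple, end: tuple) -> tuple[float, float]:
    """Cost band limiting how far alternative endpoints may extend.

    Each cut-off is the mean absolute successive difference of the costs
    along the border line holding the provisional endpoint: a rough scale of
    how much the border cost fluctuates per step. A border of length 1 gives
    a cut-off of 0.
    """
    D = np.asarray(D, dtype=float)
    n, m = D.shape
    cut_start = _mean_abs_diff(D[:, 0] if start[1] == 0 else D[0, :])
    cut_end = _mean_abs_diff(D[:, m - 1] if end[1] == m - 1 else D[n - 1, :])
    return cut_start, cut_end


def candidate_endpoints(
    D: np.ndarray, start: tuple, end: tuple, cut_off_start: float, cut_off_end: float
) -> tuple[list, list]:
    """Admissible endpoint sets, extending toward the matrix corners.

    The start set holds every border position between the provisional start
    and (0,0) (both inclusive, along the border line containing the start)
    whose cost differs from the start's cost by at most ``cut_off_start``;
    the end set extends toward (n-1,m-1) analogously. The provisional
    endpoints themselves are always included.
    """
    D = np.asarray(D, dtype=float)
    n, m = D.shape

    def band(anchor: tuple, line: list, cut: float) -> list:
        ref = D[anchor]
        out = [p for p in line if abs(D[p] - ref) <= cut]
        if anchor not in out:
            out.append(anchor)
        return sorted(out)

    if start[1] == 0:
        start_line = [(i, 0) for i in range(0, start[0] + 1)]
    else:
        start_line = [(0, j) for j in range(0, start[1] + 1)]
    if end[1] == m - 1:
        end_line = [(i, m - 1) for i in range(end[0], n)]
    else:
        end_line = [(n - 1, j) for j in range(end[1], m)]
    return band(start, start_line, cut_off_start), band(end, end_line, cut_off_end)


def dtw(D: np.ndarray, start: tuple, end: tuple) -> CandidatePath:
    """Minimal-cost monotone path from ``start`` to ``end`` through ``D``.

    Steps are the symmetric unweighted triple (+1,0), (0,+1), (+1,+1); the
    path cost is the plain sum of the visited entries. Backtrace ties prefer
    the diagonal step, then the horizontal one.
    """
    D = np.asarray(D, dtype=float)
    si, sj = start
    ei, ej = end
    if ei < si or ej < sj:
        raise ValueError(f"end {end} precedes start {start}")
    sub = D[si : ei + 1, sj : ej + 1]
    n, m = sub.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = sub[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + sub[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + sub[i, 0]
        row, prev = acc[i], acc[i - 1]
        for j in range(1, m):
            row[j] = sub[i, j] + min(prev[j - 1], row[j - 1], prev[j])
    # backtrace, diagonal > left > up on ties
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            i, j = 0, j - 1
        elif j == 0:
            i, j = i - 1, 0
        else:
            options = ((acc[i - 1, j - 1], (i - 1, j - 1)),
                       (acc[i, j - 1], (i, j - 1)),
                       (acc[i - 1, j], (i - 1, j)))
            best = min(o[0] for o in options)
            i, j = next(p for v, p in options if v == best)
        path.append((i, j))
    path.reverse()
    matches = [(i + si, j + sj) for i, j in path]
    costs = np.array([D[p] for p in matches])
    return CandidatePath(
        start=start, end=end, matches=matches, match_costs=costs,
        total_cost=float(acc[n - 1, m - 1]),
    )


def bootstrap_path_scores(
    candidates: list, n_boot: int = 1000, seed: int | None = None
) -> tuple[np.ndarray, int]:
    """Length-fair path scores by bootstrap resampling of match costs.

    ``boot_len`` is the length of the shortest candidate. For every path,
    ``n_boot`` resamples of ``boot_len`` match costs (with replacement) are
    averaged; the path score is the mean of those resample means. Scores are
    written onto the candidates and also returned.
    """
    if not candidates:
        raise ValueError("no candidate paths to score")
    rng = np.random.default_rng(seed)
    boot_len = min(len(c) for c in candidates)
    scores = np.empty(len(candidates))
    for k, cand in enumerate(candidates):
        draws = rng.choice(cand.match_costs, size=(n_boot, boot_len), replace=True)
        cand.path_score = float(draws.mean(axis=1).mean())
        scores[k] = cand.path_score
    return scores, boot_len


def select_optimal_path(
    candidates: list, path_scores: np.ndarray, shape: tuple
) -> tuple[CandidatePath, np.ndarray]:
    """Choose the final path from the scored candidates.

    Candidates scoring below ``min(scores) + mean(S)`` survive, where ``S``
    is the full matrix of pairwise absolute score differences (diagonal
    included). Among survivors the path whose start is closest to (0,0) and
    end closest to (n-1,m-1) in Manhattan index distance wins; remaining
    ties go to the lower score, then to enumeration order. When every
    candidate ties at the minimum score (so the strict threshold excludes
    all), the tied minima all survive.
    """
    scores = np.asarray(path_scores, dtype=float)
    S = np.abs(scores[:, None] - scores[None, :])
    threshold = scores.min() + S.mean()
    kept = np.nonzero(scores < threshold)[0]
    if kept.size == 0:
        kept = np.nonzero(scores == scores.min())[0]
    n, m = shape

    def corner_distance(c: CandidatePath) -> int:
        (si, sj), (ei, ej) = c.start, c.end
        return si + sj + (n - 1 - ei) + (m - 1 - ej)

    best = min(kept, key=lambda k: (corner_distance(candidates[k]), scores[k], k))
    return candidates[best], S


def prune_matches(
    D: np.ndarray, chosen: CandidatePath
) -> tuple[list, list, float, float]:
    """Drop path matches that look more like non-matches.

    ``match_threshold`` is the mean cost over the chosen path and
    ``nonmatch_threshold`` the mean of ``D`` off the path, both computed once
    from the un-pruned path. A match is dropped iff its cost is strictly
    closer to the non-match mean. Kept matches are grouped into maximal
    contiguous segments (runs of consecutive path positions).
    """
    D = np.asarray(D, dtype=float)
    on_path = np.zeros(D.shape, dtype=bool)
    for p in chosen.matches:
        on_path[p] = True
    match_threshold = float(D[on_path].mean())
    off = ~on_path
    nonmatch_threshold = float(D[off].mean()) if off.any() else match_threshold

    kept, segments, current = [], [], []
    for p in chosen.matches:
        d = D[p]
        if abs(d - nonmatch_threshold) < abs(d - match_threshold):
            if current:
                segments.append(current)
                current = []
            continue
        kept.append(p)
        current.append(p)
    if current:
        segments.append(current)
    if not kept:
        raise ValueError("no shared process found: every match was pruned")
    return kept, segments, match_threshold, nonmatch_threshold


def alignment_quality(
    chosen: CandidatePath, warn_threshold: float = DEFAULT_WARN_THRESHOLD
) -> tuple[float, bool]:
    """Median path cost and a flag for implausibly dissimilar alignments."""
    median_cost = float(np.median(chosen.match_costs))
    flag = median_cost > warn_threshold
    if flag:
        logger.warning(
            "median path dissimilarity %.3f exceeds %.3f; the two trajectories "
            "may not share a process", median_cost, warn_threshold,
        )
    return median_cost, flag


def align(
    D: DissimilarityMatrix | np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    warn_threshold: float = DEFAULT_WARN_THRESHOLD,
    prune: bool = True,
) -> Alignment:
    """Run the full endpoint search, path selection and pruning on ``D``."""
    values = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    if values.size == 0:
        raise ValueError("empty dissimilarity matrix")
    start, end = find_min_endpoints(values)
    cut_start, cut_end = endpoint_cutoffs(values, start, end)
    start_set, end_set = candidate_endpoints(values, start, end, cut_start, cut_end)
    candidates = []
    for s in start_set:
        for e in end_set:
            if e[0] < s[0] or e[1] < s[1]:
                logger.debug("endpoint pair %s -> %s discarded (non-monotone)", s, e)
                continue
            candidates.append(dtw(values, s, e))
    if not candidates:
        # Degenerate borders (typical of unrelated pairs): every admissible
        # start sits beyond every admissible end. Fall back to the classical
        # corner-to-corner path so a (poor, flagged) alignment still exists.
        logger.warning(
            "no monotone start/end pair on the borders; falling back to a "
            "corner-to-corner alignment"
        )
        n, m = values.shape
        candidates = [dtw(values, (0, 0), (n - 1, m - 1))]
    scores, boot_len = bootstrap_path_scores(candidates, n_boot=n_boot, seed=seed)
    chosen, S = select_optimal_path(candidates, scores, values.shape)
    logger.info(
        "chose path %s -> %s (%d matches) among %d candidates",
        chosen.start, chosen.end, len(chosen), len(candidates),
    )
    if prune:
        kept, segments, mthr, nthr = prune_matches(values, chosen)
    else:
        kept = list(chosen.matches)
        segments = [kept]
        mthr = float(np.mean(chosen.match_costs))
        nthr = float("nan")
    median_cost, flag = alignment_quality(chosen, warn_threshold)
    return Alignment(
        candidates=candidates,
        chosen=chosen,
        path_scores=scores,
        score_distances=S,
        cut_off_start=cut_start,
        cut_off_end=cut_end,
        match_threshold=mthr,
        nonmatch_threshold=nthr,
        kept_matches=kept,
        segments=segments,
        n_boot=n_boot,
        boot_len=boot_len,
        median_cost=median_cost,
        warning_flag=flag,
        warn_threshold=warn_threshold,
        shape=values.shape,
    )


def align_trajectories(
    a,
    b,
    n_points: int = 15,
    metric: str = "spearman",
    n_boot: int = 1000,
    seed: int | None = None,
    warn_threshold: float = DEFAULT_WARN_THRESHOLD,
    gene_list=None,
):
    """Convenience pipeline: harmonize, interpolate, score, align.

    Returns ``(alignment, interp_a, interp_b, dissimilarity)``.
    """
    from trajalign.dissimilarity import dissimilarity_matrix
    from trajalign.interpolation import interpolate
    from trajalign.io import harmonize_genes

    a, b = harmonize_genes(a, b, gene_list)
    ia = interpolate(a, n_points)
    ib = interpolate(b, n_points)
    D = dissimilarity_matrix(ia, ib, metric=metric)
    alignment = align(D, n_boot=n_boot, seed=seed, warn_threshold=warn_threshold)
    return alignment, ia, ib, D
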
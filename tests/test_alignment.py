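import functools

import numpy as np
import pytest

from trajalign.alignment import (
    align,
    alignment_quality,
    bootstrap_path_scores,
    candidate_endpoints,
    dtw,
    endpoint_cutoffs,
    find_min_endpoints,
    prune_matches,
    select_optimal_path,
)


@functools.lru_cache(maxsize=None)
def monotone_paths(di, dj):
    """All step sequences from (0,0) to (di,dj) with unit monotone steps."""
    if di == 0 and dj == 0:
        return (((0, 0),),)
    out = []
    for si, sj in ((1, 0), (0, 1), (1, 1)):
        if di - si >= 0 and dj - sj >= 0:
            for tail in monotone_paths(di - si, dj - sj):
                shifted = tuple((i + si, j + sj) for i, j in tail)
                out.append(((0, 0),) + shifted)
    return tuple(out)


def brute_min_cost(D, start, end):
    """Minimum path cost by explicit enumeration of every monotone path."""
    si, sj = start
    best = np.inf
    for path in monotone_paths(end[0] - si, end[1] - sj):
        total = sum(D[si + i, sj + j] for i, j in path)
        best = min(best, total)
    return best


class TestEndpoints:
    def test_unique_corner_minima(self):
        D = np.ones((4, 4))
        D[0, 0] = 0.0
        D[3, 3] = 0.0
        assert find_min_endpoints(D) == ((0, 0), (3, 3))

    def test_border_argmin(self):
        D = np.ones((3, 3))
        D[:, 0] = [0.9, 0.2, 0.8]
        D[0, :] = [0.9, 0.5, 0.7]
        start, _ = find_min_endpoints(D)
        assert start == (1, 0)

    def test_tie_broken_toward_corner(self):
        D = np.ones((3, 4))
        D[0, 0] = 0.1
        D[0, 2] = 0.1
        start, _ = find_min_endpoints(D)
        assert start == (0, 0)

    def test_cutoff_is_mean_absolute_difference(self):
        D = np.ones((3, 3))
        D[:, 0] = [0.9, 0.2, 0.8]
        start, end = (1, 0), (2, 2)
        cut_start, _ = endpoint_cutoffs(D, start, end)
        assert cut_start == pytest.approx((0.7 + 0.6) / 2)

    def test_cutoff_zero_on_constant_border(self):
        D = np.ones((4, 4))
        D[0, 0] = 0.0
        cs, ce = endpoint_cutoffs(D, (0, 0), (3, 3))
        # start border column 0: diffs (1,0,0) -> mean 1/3
        assert cs == pytest.approx(1.0 / 3.0)

    def test_candidate_sets(self):
        D = np.ones((4, 4))
        D[:, 0] = [0.5, 0.21, 0.20, 0.9]
        start = (2, 0)
        s_set, _ = candidate_endpoints(D, start, (3, 3), 0.05, 0.0)
        # within band: (2,0) itself and (1,0); corner value 0.5 too far
        assert s_set == [(1, 0), (2, 0)]

    def test_start_at_corner_is_singleton(self):
        D = np.ones((3, 3))
        D[0, 0] = 0.0
        s_set, _ = candidate_endpoints(D, (0, 0), (2, 2), 0.0, 0.0)
        assert s_set == [(0, 0)]

    def test_zero_cutoff_distinct_values_singletons(self):
        D = np.arange(16.0).reshape(4, 4)
        s_set, e_set = candidate_endpoints(D, (2, 0), (3, 1), 0.0, 0.0)
        assert s_set == [(2, 0)] and e_set == [(3, 1)]


class TestDTW:
    def test_zero_diagonal_path(self):
        D = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        path = dtw(D, (0, 0), (2, 2))
        assert path.matches == [(0, 0), (1, 1), (2, 2)]
        assert path.total_cost == 0.0

    def test_single_row_visits_every_column(self):
        D = np.array([[0.3, 0.1, 0.8, 0.2]])
        path = dtw(D, (0, 0), (0, 3))
        assert path.matches == [(0, j) for j in range(4)]
        assert path.total_cost == pytest.approx(D.sum())

    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError):
            dtw(np.ones((3, 3)), (2, 1), (1, 2))

    @pytest.mark.parametrize("shape", [(3, 3), (4, 4), (5, 5), (2, 5)])
    def test_optimality_against_enumeration(self, shape, rng):
        for _ in range(20):
            D = rng.uniform(size=shape)
            n, m = shape
            for start in [(0, 0), (1, 0), (0, 1)]:
                for end in [(n - 1, m - 1), (n - 1, m - 2), (n - 2, m - 1)]:
                    if end[0] < start[0] or end[1] < start[1]:
                        continue
                    path = dtw(D, start, end)
                    assert path.total_cost == pytest.approx(
                        brute_min_cost(D, start, end), abs=1e-12
                    )

    def test_paths_are_monotone_unit_steps(self, rng):
        D = rng.uniform(size=(6, 5))
        path = dtw(D, (1, 0), (5, 4))
        steps = np.diff(np.array(path.matches), axis=0)
        assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}


class TestScoringAndSelection:
    def test_constant_costs_score_exactly(self):
        D = np.full((3, 3), 0.4)
        path = dtw(D, (0, 0), (2, 2))
        scores, blen = bootstrap_path_scores([path], n_boot=10, seed=0)
        assert scores[0] == pytest.approx(0.4, abs=1e-12)
        assert blen == len(path)

    def test_separated_costs_rank_stably_across_seeds(self):
        lo = dtw(np.full((3, 3), 0.1), (0, 0), (2, 2))
        hi = dtw(np.full((3, 3), 0.9), (0, 0), (2, 2))
        for seed in (0, 1, 2):
            scores, _ = bootstrap_path_scores([lo, hi], n_boot=200, seed=seed)
            assert scores[0] == pytest.approx(0.1, abs=1e-12)
            assert scores[1] == pytest.approx(0.9, abs=1e-12)

    def test_single_candidate_returned(self):
        path = dtw(np.full((2, 2), 0.5), (0, 0), (1, 1))
        chosen, _ = select_optimal_path([path], np.array([0.5]), (2, 2))
        assert chosen is path

    def test_corner_spanning_wins_on_equal_scores(self):
        D = np.full((4, 4), 0.5)
        full = dtw(D, (0, 0), (3, 3))
        partial = dtw(D, (1, 0), (3, 2))
        chosen, _ = select_optimal_path(
            [partial, full], np.array([0.5, 0.5]), (4, 4)
        )
        assert chosen is full

    def test_high_score_excluded_by_threshold(self):
        D = np.full((4, 4), 0.5)
        paths = [dtw(D, (0, 0), (3, 3)) for _ in range(3)]
        scores = np.array([0.1, 0.12, 0.9])
        S = np.abs(scores[:, None] - scores[None, :])
        threshold = scores.min() + S.mean()
        assert scores[2] >= threshold  # sanity of the hand computation
        chosen, S_out = select_optimal_path(paths, scores, (4, 4))
        np.testing.assert_allclose(S_out, S)
        assert chosen is paths[0]


class TestPruning:
    def test_clean_two_level_matrix_keeps_all(self):
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        path = dtw(D, (0, 0), (3, 3))
        kept, segments, mthr, nthr = prune_matches(D, path)
        assert kept == path.matches
        assert len(segments) == 1
        assert mthr == pytest.approx(0.0)
        assert nthr == pytest.approx(1.0)

    def test_middle_section_pruned_into_two_segments(self):
        n = 9
        D = np.full((n, n), 1.0)
        for k in range(n):
            D[k, k] = 0.95 if 3 <= k <= 5 else 0.0
        path = dtw(D, (0, 0), (n - 1, n - 1))
        kept, segments, mthr, nthr = prune_matches(D, path)
        assert [(k, k) for k in (3, 4, 5)] == [m for m in path.matches if m not in kept]
        assert len(segments) == 2

    def test_equidistant_match_kept(self):
        # cost exactly halfway between thresholds -> strict < keeps it
        D = np.array([[0.0, 1.0], [1.0, 0.5]])
        path = dtw(D, (0, 0), (1, 1))
        # thresholds: match mean over {0, 0.5} = 0.25; nonmatch mean = 1.0
        kept, _, mthr, nthr = prune_matches(D, path)
        assert mthr == pytest.approx(0.25) and nthr == pytest.approx(1.0)
        assert (1, 1) in kept  # |0.5-1.0| == 0.5, |0.5-0.25| == 0.25 -> kept

    def test_at_least_one_match_survives(self, rng):
        # the match nearest the on-path mean is always closer to the match
        # threshold than to the non-match threshold, so pruning can never
        # empty the path
        for _ in range(30):
            D = rng.uniform(size=(5, 6))
            path = dtw(D, (0, 0), (4, 5))
            kept, _, _, _ = prune_matches(D, path)
            assert len(kept) >= 1


class TestQualityAndAlign:
    def test_median_and_flag(self):
        p = dtw(np.zeros((3, 3)), (0, 0), (2, 2))
        assert alignment_quality(p) == (0.0, False)
        p2 = dtw(np.ones((3, 3)), (0, 0), (2, 2))
        assert alignment_quality(p2, warn_threshold=0.8) == (1.0, True)

    def test_thresholds_computed_from_unpruned_path(self):
        n = 9
        D = np.full((n, n), 1.0)
        for k in range(n):
            D[k, k] = 0.95 if 3 <= k <= 5 else 0.0
        al = align(D, n_boot=50, seed=0)
        on_path = np.zeros_like(D, dtype=bool)
        for m in al.chosen.matches:
            on_path[m] = True
        assert al.match_threshold == pytest.approx(D[on_path].mean())
        assert al.nonmatch_threshold == pytest.approx(D[~on_path].mean())

    def test_symmetric_transpose_alignment(self, rng):
        # tie-free random matrix: aligning D and D.T gives mirrored matches
        D = rng.uniform(0.05, 1.0, size=(6, 6))
        a1 = align(D, n_boot=200, seed=7)
        a2 = align(D.T, n_boot=200, seed=7)
        assert sorted((j, i) for i, j in a1.kept_matches) == sorted(a2.kept_matches)

    def test_fixed_seed_reproducible(self, rng):
        D = rng.uniform(size=(8, 8))
        a1 = align(D.copy(), n_boot=300, seed=42)
        a2 = align(D.copy(), n_boot=300, seed=42)
        assert a1.chosen.matches == a2.chosen.matches
        np.testing.assert_array_equal(a1.path_scores, a2.path_scores)
        assert a1.kept_matches == a2.kept_matches
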
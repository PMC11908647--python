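import numpy as np
import pytest
import scipy.stats

from trajalign.alignment import align_trajectories
from trajalign.simulate import simulate_pair
from trajalign.warp import (
    _blocks,
    align_individual_match,
    align_multi_match,
    align_point_pseudotime,
    warp_cells,
    warp_pair,
)


class TestSingleMatchPrimitives:
    def test_individual_match_shifts_suffix(self):
        A, B = align_individual_match(
            np.array([1.0, 5.0, 6.0]), np.array([0.0, 3.0]), (1, 1)
        )
        np.testing.assert_allclose(A, [1.0, 3.0, 4.0])
        np.testing.assert_allclose(B, [0.0, 3.0])

    def test_individual_match_mirrors_to_other_side(self):
        A, B = align_individual_match(
            np.array([0.0, 2.0]), np.array([0.0, 6.0, 7.0]), (1, 1)
        )
        np.testing.assert_allclose(B, [0.0, 2.0, 3.0])

    def test_multi_match_even_spacing_between_anchors(self):
        q = align_multi_match(np.array([1.0, 1.2, 3.9, 4.0]), [0, 1, 2], 3, 4.0)
        np.testing.assert_allclose(q, [1.0, 2.0, 3.0, 4.0])

    def test_multi_match_without_next_is_identity(self):
        q = np.array([1.0, 1.5, 2.5])
        np.testing.assert_array_equal(align_multi_match(q, [0, 1, 2], None), q)


class TestBlocks:
    def test_one_to_one_matches_are_singletons(self):
        matches = [(0, 0), (1, 1), (2, 2)]
        assert _blocks(matches) == [[(0, 0)], [(1, 1)], [(2, 2)]]

    def test_multi_match_grouped(self):
        matches = [(0, 0), (1, 0), (2, 0), (3, 1)]
        assert _blocks(matches) == [[(0, 0), (1, 0), (2, 0)], [(3, 1)]]

    def test_gap_breaks_block(self):
        # (0,1) pruned out of a column run: not adjacent, so no grouping
        matches = [(0, 0), (0, 2), (1, 3)]
        assert _blocks(matches) == [[(0, 0)], [(0, 2)], [(1, 3)]]


class TestPointWarp:
    def test_individual_shift_moves_later_trajectory_back(self):
        # matched pair (A=5, B=3): A shifts to 3, later A points follow
        q_a = np.array([1.0, 5.0, 6.0, 8.0])
        q_b = np.array([0.0, 3.0, 7.0, 9.0])
        A, B = align_point_pseudotime(q_a, q_b, [(1, 1)])
        assert A[1] == B[1] == 3.0
        np.testing.assert_allclose(A[2:], [4.0, 6.0])

    def test_equal_pseudotime_no_change(self):
        q = np.array([0.0, 1.0, 2.0])
        A, B = align_point_pseudotime(q, q.copy(), [(1, 1)])
        np.testing.assert_array_equal(A, q)
        np.testing.assert_array_equal(B, q)

    def test_chain_of_matches_coincides_and_stays_monotone(self):
        q_a = np.array([0.0, 2.0, 5.0, 9.0])
        q_b = np.array([0.0, 1.0, 3.0, 4.0])
        matches = [(0, 0), (1, 1), (2, 2), (3, 3)]
        A, B = align_point_pseudotime(q_a, q_b, matches)
        for i, j in matches:
            assert A[i] == pytest.approx(B[j], abs=1e-9)
        assert np.all(np.diff(A) >= 0) and np.all(np.diff(B) >= 0)

    def test_multi_match_even_spacing(self):
        # A points 1..4 where points 1,2,3 match B point 0 and (4,1) follows;
        # after anchor alignment the two extras are evenly spaced
        q_a = np.array([1.0, 1.5, 3.5, 4.0])
        q_b = np.array([1.0, 4.0])
        matches = [(0, 0), (1, 0), (2, 0), (3, 1)]
        A, B = align_point_pseudotime(q_a, q_b, matches)
        assert A[0] == B[0] == 1.0
        assert A[3] == B[1] == 4.0
        np.testing.assert_allclose(A[1:3], [2.0, 3.0])

    def test_single_extra_point_at_midpoint(self):
        q_a = np.array([1.0, 2.5, 3.0])
        q_b = np.array([1.0, 3.0])
        A, B = align_point_pseudotime(q_a, q_b, [(0, 0), (1, 0), (2, 1)])
        assert A[1] == pytest.approx(2.0)

    def test_trailing_block_preserves_spacing(self):
        # trailing multi-match: first member shifted by -2, gaps preserved
        q_a = np.array([0.0, 5.0, 6.0, 8.0])
        q_b = np.array([0.0, 3.0])
        A, B = align_point_pseudotime(q_a, q_b, [(0, 0), (1, 1), (2, 1), (3, 1)])
        assert A[1] == B[1] == 3.0
        np.testing.assert_allclose(np.diff(A[1:]), [1.0, 2.0])

    def test_idempotent_on_aligned_input(self):
        q_a = np.array([0.0, 2.0, 5.0, 9.0])
        q_b = np.array([0.0, 1.0, 3.0, 4.0])
        matches = [(0, 0), (1, 1), (2, 2), (3, 3)]
        A1, B1 = align_point_pseudotime(q_a, q_b, matches)
        A2, B2 = align_point_pseudotime(A1, B1, matches)
        np.testing.assert_allclose(A2, A1, atol=1e-12)
        np.testing.assert_allclose(B2, B1, atol=1e-12)


class TestCellWarp:
    def test_identity_warp_small_bias(self):
        q = np.linspace(0, 1, 11)
        p = np.random.default_rng(0).uniform(0, 1, 50)
        out = warp_cells(p, q, q, np.full(11, 0.1))
        assert np.max(np.abs(out - p)) <= 0.05  # within half the point spacing

    def test_uniform_shift_passes_through(self, rng):
        q = np.linspace(0, 1, 8)
        p = rng.uniform(0, 1, 40)
        out = warp_cells(p, q, q - 2.0, np.full(8, 0.2))
        base = warp_cells(p, q, q, np.full(8, 0.2))
        np.testing.assert_allclose(out, base - 2.0, atol=1e-9)

    def test_out_of_reach_cell_keeps_offset(self):
        q = np.array([0.0, 1.0])
        out = warp_cells(np.array([50.0]), q, q - 0.5, np.array([0.01, 0.01]))
        assert out[0] == pytest.approx(50.0 - 0.5)


@pytest.fixture(scope="module")
def truncated_warp():
    pair = simulate_pair("truncated", n_cells=300, n_genes=50, seed=4)
    al, ia, ib, _ = align_trajectories(
        pair.trajectory_a, pair.trajectory_b, n_points=15, seed=4
    )
    return al, warp_pair(al, ia, ib)


class TestEndToEnd:
    def test_matched_points_coincide(self, truncated_warp):
        al, (wa, wb) = truncated_warp
        blocks = _blocks(al.kept_matches)
        for block in blocks:
            i, j = block[0]
            assert wa.aligned_point_pseudotime[i] == pytest.approx(
                wb.aligned_point_pseudotime[j], abs=1e-9
            )

    def test_cell_rank_order_preserved(self, truncated_warp):
        _, (wa, wb) = truncated_warp
        for w in (wa, wb):
            rho = scipy.stats.spearmanr(
                w.original_cell_pseudotime, w.cell_aligned_pseudotime
            ).statistic
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_truncated_side_ends_earlier(self, truncated_warp):
        _, (wa, wb) = truncated_warp
        assert wb.cell_aligned_pseudotime.max() < wa.cell_aligned_pseudotime.max()

    def test_aligned_points_monotone(self, truncated_warp):
        _, (wa, wb) = truncated_warp
        assert np.all(np.diff(wa.aligned_point_pseudotime) >= -1e-12)
        assert np.all(np.diff(wb.aligned_point_pseudotime) >= -1e-12)
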
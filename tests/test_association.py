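"""Association: costs, gating, Hungarian assignment, cascade, IoU fallback."""

import itertools

import numpy as np
import pytest

from pentrack.association import (
    INFEASIBLE,
    appearance_cost,
    gate_cost_matrix,
    iou_match,
    matching_cascade,
    solve_assignment,
)
from pentrack.geometry import BBox


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def brute_force_min_cost(costs, max_cost):
    """Exhaustive assignment oracle: maximum cardinality, then minimum cost."""
    n_t, n_d = costs.shape
    k = min(n_t, n_d)
    best_key, best_pairs = (0, 0.0), []
    for rows in itertools.permutations(range(n_t), k):
        for cols in itertools.permutations(range(n_d), k):
            pairs = [
                (r, c)
                for r, c in zip(rows, cols)
                if np.isfinite(costs[r, c]) and costs[r, c] <= max_cost
            ]
            key = (-len(pairs), sum(costs[r, c] for r, c in pairs))
            if key < best_key:
                best_key, best_pairs = key, pairs
    return best_pairs


class TestAppearanceCost:
    def test_identical_vectors_cost_zero(self):
        g = np.array([unit([1, 0, 0])])
        assert appearance_cost([g], [unit([1, 0, 0])])[0, 0] == pytest.approx(0.0)

    def test_orthogonal_vectors_cost_one(self):
        g = np.array([unit([1, 0, 0])])
        assert appearance_cost([g], [unit([0, 1, 0])])[0, 0] == pytest.approx(1.0)

    def test_gallery_minimum_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            gallery = np.array([unit(rng.normal(size=8)) for _ in range(4)])
            feats = [unit(rng.normal(size=8)) for _ in range(3)]
            costs = appearance_cost([gallery], feats)
            for j, f in enumerate(feats):
                expected = min(1.0 - float(g @ f) for g in gallery)
                assert costs[0, j] == pytest.approx(expected)

    def test_empty_gallery_row_infeasible(self):
        costs = appearance_cost([np.zeros((0, 0))], [unit([1, 0])])
        assert np.all(np.isinf(costs[0]))


class TestGate:
    def test_infinite_threshold_is_identity(self, rng):
        costs = rng.uniform(0, 1, (3, 4))
        gating = rng.uniform(0, 100, (3, 4))
        assert np.array_equal(gate_cost_matrix(costs, gating, np.inf), costs)

    def test_zero_threshold_only_exact(self):
        costs = np.array([[0.1, 0.2]])
        gating = np.array([[0.0, 5.0]])
        gated = gate_cost_matrix(costs, gating, 0.0)
        assert gated[0, 0] == 0.1 and np.isinf(gated[0, 1])

    def test_matches_elementwise_mask_oracle(self, rng):
        costs = rng.uniform(0, 1, (4, 5))
        gating = rng.uniform(0, 20, (4, 5))
        thr = 9.4877
        gated = gate_cost_matrix(costs, gating, thr)
        mask = gating > thr
        assert np.all(np.isinf(gated[mask]))
        assert np.array_equal(gated[~mask], costs[~mask])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gate_cost_matrix(np.zeros((2, 2)), np.zeros((2, 3)), 1.0)


class TestSolveAssignment:
    def test_diagonal_optimum(self):
        res = solve_assignment(np.array([[0.0, 9.0], [9.0, 0.0]]), max_cost=10)
        assert sorted(res.matches) == [(0, 0), (1, 1)]

    def test_max_cost_demotes_expensive_pair(self):
        res = solve_assignment(np.array([[5.0, 1.0]]), max_cost=2)
        assert res.matches == [(0, 1)]
        assert res.unmatched_detections == [0]

    def test_empty_inputs(self):
        res = solve_assignment(np.zeros((0, 0)), max_cost=1)
        assert res == ([], [], [])

    def test_random_3x3_matches_permutation_search(self, rng):
        for _ in range(100):
            costs = rng.uniform(0, 1, (3, 3))
            res = solve_assignment(costs, max_cost=np.inf)
            total = sum(costs[r, c] for r, c in res.matches)
            best = min(
                sum(costs[i, p[i]] for i in range(3))
                for p in itertools.permutations(range(3))
            )
            assert total == pytest.approx(best)

    def test_partition_property(self, rng):
        costs = rng.uniform(0, 1, (4, 6))
        res = solve_assignment(costs, max_cost=0.5)
        track_seen = sorted([t for t, _ in res.matches] + res.unmatched_tracks)
        det_seen = sorted([d for _, d in res.matches] + res.unmatched_detections)
        assert track_seen == list(range(4))
        assert det_seen == list(range(6))


class TestMatchingCascade:
    def test_uniform_age_equals_single_assignment(self, rng):
        costs = rng.uniform(0, 1, (4, 4))
        res_c = matching_cascade(
            lambda ti, di: costs[np.ix_(ti, di)], 0.8, [0, 0, 0, 0], 4
        )
        res_s = solve_assignment(costs, 0.8)
        assert sorted(res_c.matches) == sorted(res_s.matches)

    def test_fresh_track_wins_contested_detection(self):
        # both tracks want detection 0 cheaply; the fresher (age 0) track
        # is matched first and the stale one must take detection 1
        costs = np.array([[0.05, 0.6], [0.02, 0.7]])

        def cost_fn(ti, di):
            return costs[np.ix_(ti, di)]

        res = matching_cascade(cost_fn, 0.8, [1, 0], 2)
        assert (1, 0) in res.matches  # fresh track got the contested det
        assert (0, 1) in res.matches

    def test_no_detections_all_unmatched(self):
        res = matching_cascade(lambda ti, di: np.zeros((len(ti), 0)), 0.5, [0, 2], 0)
        assert res.matches == [] and res.unmatched_tracks == [0, 1]

    def test_no_duplicate_assignments(self, rng):
        for _ in range(50):
            ages = rng.integers(0, 4, size=5).tolist()
            costs = rng.uniform(0, 1, (5, 5))
            res = matching_cascade(lambda ti, di: costs[np.ix_(ti, di)], 0.9, ages, 5)
            dets = [d for _, d in res.matches]
            tracks = [t for t, _ in res.matches]
            assert len(dets) == len(set(dets))
            assert len(tracks) == len(set(tracks))
            assert sorted(tracks + res.unmatched_tracks) == list(range(5))
            assert sorted(dets + res.unmatched_detections) == list(range(5))


class TestIoUMatch:
    def test_identical_boxes_matched_at_zero_cost(self):
        b = BBox(0, 0, 10, 10)
        res = iou_match([b], [b], iou_floor=0.3)
        assert res.matches == [(0, 0)]

    def test_disjoint_boxes_unmatched(self):
        res = iou_match([BBox(0, 0, 10, 10)], [BBox(100, 100, 10, 10)], 0.3)
        assert res.matches == []

    def test_crossed_overlaps_match_brute_force(self, rng):
        for _ in range(50):
            tracks = [
                BBox(rng.uniform(0, 30), rng.uniform(0, 30), 20, 20) for _ in range(2)
            ]
            dets = [
                BBox(rng.uniform(0, 30), rng.uniform(0, 30), 20, 20) for _ in range(2)
            ]
            from pentrack.geometry import iou as iou_fn

            costs = np.array(
                [
                    [
                        1 - iou_fn(t, d) if iou_fn(t, d) >= 0.3 else INFEASIBLE
                        for d in dets
                    ]
                    for t in tracks
                ]
            )
            res = iou_match(tracks, dets, 0.3)
            expected = brute_force_min_cost(costs, max_cost=0.7)
            assert sum(costs[r, c] for r, c in res.matches) == pytest.approx(
                sum(costs[r, c] for r, c in expected)
            )
            assert len(res.matches) == len(expected)
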
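"""Evaluation metrics: confusion counts, AP, overlap rate, center error."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pentrack.errors import UndefinedMetricError
from pentrack.geometry import BBox, Detection, iou
from pentrack.metrics import (
    ConfusionCounts,
    average_precision,
    counting_accuracy,
    match_frame,
    overlap_rate,
    precision,
    recall,
    tracking_eval,
)


def table(rows):
    return pd.DataFrame(rows, columns=["frame", "id", "left", "top", "width", "height"])


class TestMatchFrame:
    def test_exact_match(self):
        gt = [BBox(0, 0, 10, 10), BBox(50, 50, 10, 10)]
        counts, pairs = match_frame(gt, gt, 0.5)
        assert (counts.TP, counts.FP, counts.FN) == (2, 0, 0)
        assert sorted(pairs) == [(0, 0), (1, 1)]

    def test_empty_predictions_all_fn(self):
        counts, pairs = match_frame([], [BBox(0, 0, 5, 5)] * 3, 0.5)
        assert (counts.TP, counts.FP, counts.FN) == (0, 0, 3)

    def test_crossed_overlap_2x2_hand_case(self):
        # A prefers G1 (IoU 2/3) and B prefers G2 (IoU 2/3); the weaker
        # cross pairings (1/9 and 3/7) must not steal either gt box
        pred = [BBox(0, 0, 10, 10), BBox(6, 0, 10, 10)]
        gt = [BBox(2, 0, 10, 10), BBox(8, 0, 10, 10)]
        assert iou(pred[0], gt[0]) == pytest.approx(2 / 3)
        assert iou(pred[1], gt[1]) == pytest.approx(2 / 3)
        counts, pairs = match_frame(pred, gt, 0.1)
        assert counts.TP == 2
        assert sorted(pairs) == [(0, 0), (1, 1)]

    def test_random_cases_equal_independent_greedy_trace(self, rng):
        # oracle: a from-scratch trace of descending-IoU one-to-one matching
        for _ in range(50):
            pred = [BBox(rng.uniform(0, 20), rng.uniform(0, 20), 15, 15) for _ in range(3)]
            gt = [BBox(rng.uniform(0, 20), rng.uniform(0, 20), 15, 15) for _ in range(3)]
            counts, pairs = match_frame(pred, gt, 0.3)
            mat = np.array([[iou(p, g) for g in gt] for p in pred])
            expected = []
            work = mat.copy()
            while work.max() >= 0.3:
                i, j = np.unravel_index(np.argmax(work), work.shape)
                expected.append((int(i), int(j)))
                work[i, :] = -1
                work[:, j] = -1
            assert counts.TP == len(expected)
            assert sorted(pairs) == sorted(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


class TestPrecisionRecall:
    def test_closed_forms(self):
        assert precision(ConfusionCounts(7, 3, 0)) == pytest.approx(0.7)
        assert precision(ConfusionCounts(5, 0, 2)) == 1.0
        assert recall(ConfusionCounts(9, 0, 1)) == pytest.approx(0.9)
        assert recall(ConfusionCounts(0, 3, 4)) == 0.0

    def test_random_counts_match_arithmetic(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(x) for x in rng.integers(1, 50, 3))
            c = ConfusionCounts(tp, fp, fn)
            assert precision(c) == pytest.approx(tp / (tp + fp))
            assert recall(c) == pytest.approx(tp / (tp + fn))

    def test_undefined_signalled(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(0, 0, 5))
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 5, 0))


class TestAveragePrecision:
    def gt_frame(self, n, spacing=100.0):
        return {1: [BBox(i * spacing, 0, 10, 10) for i in range(n)]}

    def test_perfect_detector(self):
        gt = self.gt_frame(4)
        dets = [Detection(1, b, 1.0) for b in gt[1]]
        assert average_precision(dets, gt) == pytest.approx(1.0)

    def test_all_false_positives(self):
        gt = self.gt_frame(2)
        dets = [Detection(1, BBox(500 + i * 50, 500, 10, 10), 0.9) for i in range(3)]
        assert average_precision(dets, gt) == pytest.approx(0.0)

    def test_hand_traced_staircase(self):
        # ranked TP, FP, TP, FP, TP over 3 positives:
        # precision envelope gives AP = (1 + 2/3 + 3/5) / 3 = 34/45
        gt = self.gt_frame(3)
        dets = [
            Detection(1, gt[1][0], 0.9),                      # TP
            Detection(1, BBox(500, 500, 10, 10), 0.8),        # FP
            Detection(1, gt[1][1], 0.7),                      # TP
            Detection(1, gt[1][0], 0.6),                      # FP (gt already claimed)
            Detection(1, gt[1][2], 0.5),                      # TP
        ]
        assert average_precision(dets, gt) == pytest.approx(34 / 45)

    def test_eleven_point_mode_on_perfect_detector(self):
        gt = self.gt_frame(4)
        dets = [Detection(1, b, 1.0) for b in gt[1]]
        assert average_precision(dets, gt, mode="eleven_point") == pytest.approx(1.0)

    def test_equal_confidence_order_invariance_value(self):
        # with all scores tied the stated tie-break (input order) fixes the
        # curve; AP must not change when logically identical sets are given
        gt = self.gt_frame(2)
        d_tp = [Detection(1, b, 0.5) for b in gt[1]]
        d_fp = Detection(1, BBox(500, 500, 10, 10), 0.5)
        ap1 = average_precision(d_tp + [d_fp], gt)
        ap2 = average_precision([d_tp[1], d_tp[0]] + [d_fp], gt)
        assert ap1 == pytest.approx(ap2)
        assert 0.0 <= ap1 <= 1.0

    def test_empty_gt_undefined(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([], {})


class TestTrackingEval:
    def test_identical_tables_perfect(self):
        t = table([(1, 1, 0, 0, 10, 10), (1, 2, 50, 50, 10, 10), (2, 1, 5, 0, 10, 10)])
        ev = tracking_eval(t, t)
        assert ev.AOR == pytest.approx(1.0)
        assert ev.ACLE == pytest.approx(0.0)
        assert ev.N == 3

    def test_three_four_five_center_offset(self):
        gt = table([(1, 1, 0, 0, 40, 40)])
        pred = table([(1, 1, 3, 4, 40, 40)])
        ev = tracking_eval(pred, gt)
        assert ev.ACLE == pytest.approx(5.0)

    def test_mixed_case_matches_hand_accumulation(self, rng):
        rows_gt, rows_pred = [], []
        expected_or, expected_cle = [], []
        for f in range(1, 11):
            g = BBox(10 * f, 5 * f, 30, 30)
            p = BBox(10 * f + 2, 5 * f - 1, 30, 30)
            rows_gt.append((f, 1, g.left, g.top, g.width, g.height))
            rows_pred.append((f, 1, p.left, p.top, p.width, p.height))
            expected_or.append(iou(p, g))
            expected_cle.append(np.hypot(2, 1))
        ev = tracking_eval(table(rows_pred), table(rows_gt))
        assert ev.AOR == pytest.approx(np.mean(expected_or))
        assert ev.ACLE == pytest.approx(np.mean(expected_cle))

    def test_no_matches_undefined(self):
        with pytest.raises(UndefinedMetricError):
            tracking_eval(table([(1, 1, 0, 0, 5, 5)]), table([(1, 1, 500, 500, 5, 5)]))


class TestOverlapRate:
    def test_agrees_with_iou(self, rng):
        for _ in range(20):
            a = BBox(rng.uniform(0, 50), rng.uniform(0, 50), 20, 20)
            b = BBox(rng.uniform(0, 50), rng.uniform(0, 50), 20, 20)
            assert overlap_rate(a, b) == iou(a, b)


class TestCountingAccuracy:
    @pytest.mark.parametrize(
        "pred, true, expected",
        [
            (26, 26, 100.0),
            (25, 26, (1 - 1 / 26) * 100),  # = 96.1538...
            (0, 10, 0.0),
            (30, 10, 0.0),  # floored at zero for wild overcounts
        ],
    )
    def test_relative_error_complement(self, pred, true, expected):
        assert counting_accuracy(pred, true) == pytest.approx(expected, abs=1e-9)

    def test_undefined_for_zero_truth(self):
        with pytest.raises(UndefinedMetricError):
            counting_accuracy(5, 0)
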
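"""Detection, tracking and counting evaluation.

Detection quality is summarized by precision, recall and average precision
(the area under the precision-recall curve at a fixed IoU threshold; with a
single object class, mAP equals AP).  Tracking quality uses the overlap
rate OR (the IoU between a predicted and a ground-truth box), its mean AOR
over all matched pairs, the center location error CLE (Euclidean distance
between box centers) and its mean ACLE.  Counting accuracy is the
complement of the relative counting error, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .geometry import BBox, Detection, iou

__all__ = [
    "ConfusionCounts",
    "TrackingEval",
    "match_frame",
    "precision",
    "recall",
    "average_precision",
    "overlap_rate",
    "tracking_eval",
    "counting_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class TrackingEval:
    """Per-object overlap rates and center errors, plus their means."""

    AOR: float
    ACLE: float
    N: int
    OR_n: tuple[float, ...]
    CLE_n: tuple[float, ...]


def match_frame(
    pred: Sequence[BBox], gt: Sequence[BBox], iou_thresh: float
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one box matching by descending IoU.

    Pairs at or above ``iou_thresh`` become true positives; leftover
    predictions are false positives, leftover ground truth false negatives.
    Ties are broken by lower prediction index, then lower gt index.
    """
    if not (0.0 < iou_thresh <= 1.0):
        raise ValueError(f"iou_thresh must lie in (0, 1], got {iou_thresh}")
    candidates = sorted(
        (
            (-iou(p, g), i, j)
            for i, p in enumerate(pred)
            for j, g in enumerate(gt)
            if iou(p, g) >= iou_thresh
        ),
    )
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i not in used_pred and j not in used_gt:
            pairs.append((i, j))
            used_pred.add(i)
            used_gt.add(j)
    tp = len(pairs)
    return ConfusionCounts(tp, len(pred) - tp, len(gt) - tp), pairs


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: no predictions")
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined: no positives")
    return c.TP / (c.TP + c.FN)


def average_precision(
    detections: Iterable[Detection],
    gt_by_frame: Mapping[int, Sequence[BBox]],
    iou_thresh: float = 0.5,
    mode: str = "all_point",
) -> float:
    """Area under the precision-recall curve at a fixed IoU threshold.

    Detections across all frames are ranked by descending confidence (ties
    broken by input order) and greedily matched against the not-yet-claimed
    ground truth of their own frame.  ``mode`` selects all-point
    interpolation (default) or the coarser 11-point average.
    """
    n_pos = sum(len(v) for v in gt_by_frame.values())
    if n_pos == 0:
        raise UndefinedMetricError("AP undefined: no ground-truth boxes")
    dets = list(detections)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    claimed: dict[int, set[int]] = {f: set() for f in gt_by_frame}
    is_tp = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        det = dets[i]
        gt_boxes = gt_by_frame.get(det.frame, ())
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gt_boxes):
            if j in claimed.get(det.frame, set()):
                continue
            o = iou(det.bbox, g)
            if o > best_iou:
                best_j, best_iou = j, o
        if best_j >= 0 and best_iou >= iou_thresh:
            is_tp[rank] = True
            claimed[det.frame].add(best_j)
    if len(dets) == 0:
        return 0.0
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    rec = tp_cum / n_pos
    prec = tp_cum / (tp_cum + fp_cum)
    if mode == "eleven_point":
        return float(
            np.mean(
                [
                    prec[rec >= r].max() if np.any(rec >= r) else 0.0
                    for r in np.linspace(0, 1, 11)
                ]
            )
        )
    if mode != "all_point":
        raise ValueError(f"unknown AP mode {mode!r}")
    # right-envelope the precision curve, then integrate over recall steps
    mrec = np.concatenate([[0.0], rec, [1.0]])
    mprec = np.concatenate([[0.0], prec, [0.0]])
    for i in range(len(mprec) - 2, -1, -1):
        mprec[i] = max(mprec[i], mprec[i + 1])
    steps = np.flatnonzero(np.diff(mrec) > 0)
    return float(np.sum((mrec[steps + 1] - mrec[steps]) * mprec[steps + 1]))


def overlap_rate(pred: BBox, gt: BBox) -> float:
    """OR: identical to the IoU of the predicted and labeled boxes."""
    return iou(pred, gt)


def _boxes_by_frame(table: pd.DataFrame) -> dict[int, list[BBox]]:
    out: dict[int, list[BBox]] = {}
    for r in table.itertuples():
        out.setdefault(int(r.frame), []).append(
            BBox(r.left, r.top, r.width, r.height)
        )
    return out


def tracking_eval(
    track_table: pd.DataFrame, gt_table: pd.DataFrame, iou_thresh: float = 0.5
) -> TrackingEval:
    """AOR and ACLE of a track table against ground truth.

    Per frame, predicted boxes are matched one-to-one to ground truth
    (greedy descending IoU at ``iou_thresh``); every matched pair n
    contributes an overlap rate OR_n and a center location error CLE_n, and
    the averages are taken over all N matched pairs.
    """
    pred_frames = _boxes_by_frame(track_table)
    gt_frames = _boxes_by_frame(gt_table)
    ors: list[float] = []
    cles: list[float] = []
    for frame in sorted(set(pred_frames) & set(gt_frames)):
        preds, gts = pred_frames[frame], gt_frames[frame]
        _, pairs = match_frame(preds, gts, iou_thresh)
        for i, j in pairs:
            ors.append(iou(preds[i], gts[j]))
            (px, py), (gx, gy) = preds[i].center, gts[j].center
            cles.append(float(np.hypot(px - gx, py - gy)))
    if not ors:
        raise UndefinedMetricError("tracking_eval undefined: no matched pairs")
    return TrackingEval(
        AOR=float(np.mean(ors)),
        ACLE=float(np.mean(cles)),
        N=len(ors),
        OR_n=tuple(ors),
        CLE_n=tuple(cles),
    )


def counting_accuracy(predicted: int, true: int) -> float:
    """Percentage complement of the relative counting error, floored at 0."""
    if true <= 0:
        raise UndefinedMetricError("counting accuracy undefined for true <= 0")
    if predicted < 0:
        raise ValueError("predicted count must be non-negative")
    return max(0.0, (1.0 - abs(predicted - true) / true) * 100.0)
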
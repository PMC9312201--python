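"""Track-detection association: costs, gating, assignment, cascade, IoU fallback.

Cost matrices are plain float arrays with rows = tracks and columns =
detections; ``INFEASIBLE`` (np.inf) marks forbidden pairs.  The minimum-cost
assignment is solved with the Hungarian algorithm
(:func:`scipy.optimize.linear_sum_assignment`); matched pairs whose cost
exceeds ``max_cost`` are demoted back to unmatched, which also removes any
pair that was only matched because every alternative was infeasible.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BBox, iou

__all__ = [
    "INFEASIBLE",
    "AssignmentResult",
    "appearance_cost",
    "gate_cost_matrix",
    "solve_assignment",
    "matching_cascade",
    "iou_match",
]

INFEASIBLE = np.inf
_LARGE = 1e9  # finite stand-in for INFEASIBLE inside the Hungarian solver


class AssignmentResult(NamedTuple):
    matches: list[tuple[int, int]]
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


def appearance_cost(
    galleries: Sequence[np.ndarray], feats: Sequence[np.ndarray] | np.ndarray
) -> np.ndarray:
    """Smallest cosine distance between each track's gallery and each feature.

    ``galleries[i]`` is an (n_i, d) array of unit vectors accumulated for
    track i; an empty gallery makes the whole row infeasible.
    """
    feats = np.atleast_2d(np.asarray(feats, dtype=float))
    costs = np.full((len(galleries), feats.shape[0]), INFEASIBLE)
    for i, gallery in enumerate(galleries):
        g = np.atleast_2d(np.asarray(gallery, dtype=float))
        if g.size == 0:
            continue
        costs[i] = (1.0 - g @ feats.T).min(axis=0)
    return costs


def gate_cost_matrix(
    costs: np.ndarray, gating: np.ndarray, threshold: float
) -> np.ndarray:
    """Mark pairs whose Mahalanobis gating distance exceeds the threshold."""
    if costs.shape != gating.shape:
        raise ValueError(f"shape mismatch: {costs.shape} vs {gating.shape}")
    gated = costs.copy()
    gated[gating > threshold] = INFEASIBLE
    return gated


def solve_assignment(costs: np.ndarray, max_cost: float) -> AssignmentResult:
    """Minimum-cost bipartite assignment with a feasibility ceiling."""
    costs = np.asarray(costs, dtype=float)
    n_tracks, n_dets = costs.shape if costs.ndim == 2 else (0, 0)
    if n_tracks == 0 or n_dets == 0:
        return AssignmentResult([], list(range(n_tracks)), list(range(n_dets)))
    solvable = np.where(np.isfinite(costs), np.minimum(costs, _LARGE), _LARGE)
    rows, cols = linear_sum_assignment(solvable)
    matches, un_tracks, un_dets = [], set(range(n_tracks)), set(range(n_dets))
    for r, c in zip(rows, cols):
        if np.isfinite(costs[r, c]) and costs[r, c] <= max_cost:
            matches.append((int(r), int(c)))
            un_tracks.discard(int(r))
            un_dets.discard(int(c))
    return AssignmentResult(matches, sorted(un_tracks), sorted(un_dets))


def matching_cascade(
    cost_fn: Callable[[Sequence[int], Sequence[int]], np.ndarray],
    max_cost: float,
    track_ages: Sequence[int],
    n_detections: int,
    detection_indices: Sequence[int] | None = None,
) -> AssignmentResult:
    """Age-prioritized association: freshest tracks get first pick.

    Tracks are grouped by ``track_ages`` (frames since last successful
    match) and matched group by group in ascending age against the
    detections still unclaimed, so a recently seen track can never lose a
    detection to a staler one.  ``cost_fn(track_idx, det_idx)`` must return
    the cost sub-matrix for the given index subsets.
    """
    if detection_indices is None:
        detection_indices = list(range(n_detections))
    unmatched_dets = list(detection_indices)
    matches: list[tuple[int, int]] = []
    for age in sorted(set(track_ages)):
        if not unmatched_dets:
            break
        level = [i for i, a in enumerate(track_ages) if a == age]
        sub = np.asarray(cost_fn(level, unmatched_dets), dtype=float)
        res = solve_assignment(sub, max_cost)
        matches.extend((level[r], unmatched_dets[c]) for r, c in res.matches)
        unmatched_dets = [unmatched_dets[c] for c in res.unmatched_detections]
    matched_tracks = {t for t, _ in matches}
    unmatched_tracks = [i for i in range(len(track_ages)) if i not in matched_tracks]
    return AssignmentResult(matches, unmatched_tracks, unmatched_dets)


def iou_match(
    track_boxes: Sequence[BBox], det_boxes: Sequence[BBox], iou_floor: float
) -> AssignmentResult:
    """Assignment on cost 1 - IoU; pairs below the IoU floor stay unmatched."""
    costs = np.full((len(track_boxes), len(det_boxes)), INFEASIBLE)
    for i, tb in enumerate(track_boxes):
        for j, db in enumerate(det_boxes):
            overlap = iou(tb, db)
            if overlap >= iou_floor:
                costs[i, j] = 1.0 - overlap
    return solve_assignment(costs, max_cost=1.0 - iou_floor)
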
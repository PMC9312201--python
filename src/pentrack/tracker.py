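"""Per-frame tracking orchestration and track lifecycle management.

Each frame runs the six-step tracking-by-detection flow: Kalman prediction
for every live track, detection preprocessing (confidence filter + NMS),
appearance features attached to the surviving detections, data association
(appearance cascade over confirmed tracks, then IoU matching for tentative
and just-missed tracks), Kalman update plus lifecycle bookkeeping, and
finally emission of the confirmed, currently matched tracks.

Lifecycle: a new track is *tentative* and must be matched ``n_init``
consecutive frames (counting its spawning frame) to become *confirmed*; a
tentative track that misses a frame is dropped immediately; any track whose
staleness counter a_k — frames since its last successful match — exceeds
``max_age`` is deleted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .association import (
    appearance_cost,
    gate_cost_matrix,
    iou_match,
    matching_cascade,
    solve_assignment,
)
from .errors import SequencingError
from .geometry import (
    BBox,
    Detection,
    filter_confidence,
    from_measurement,
    nms,
    to_measurement,
)
from .motion import GATING_DIM, KalmanFilter, KalmanState

__all__ = ["TrackStatus", "Track", "TrackerConfig", "Tracker", "run_tracker"]

TRACK_COLUMNS = ["frame", "id", "left", "top", "width", "height"]


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """All tracker knobs in one place; defaults follow common MOT practice.

    ``gate_threshold`` defaults to the 0.95 chi-square quantile with 4
    degrees of freedom (the measurement dimensionality), the customary
    Mahalanobis gate.
    """

    max_age: int = 30              # A_max: staleness limit in frames
    n_init: int = 3                # consecutive matches needed to confirm
    tau: float = 0.5               # detection confidence floor
    nms_thresh: float = 0.5        # NMS IoU ceiling
    gate_threshold: float = field(
        default_factory=lambda: float(chi2.ppf(0.95, df=GATING_DIM))
    )
    max_cost: float = 0.2          # appearance cosine-distance ceiling
    iou_floor: float = 0.3         # minimum IoU for the fallback matcher
    gallery_size: int = 100        # appearance ring-buffer length per track
    pos_weight: float = 1.0 / 20   # Kalman position noise scale (of box height)
    vel_weight: float = 1.0 / 160  # Kalman velocity noise scale

    def __post_init__(self) -> None:
        if self.max_age < 1 or self.n_init < 1:
            raise ValueError("max_age and n_init must be >= 1")


class Track:
    """One tracked identity: motion belief, lifecycle state, feature gallery."""

    def __init__(
        self, track_id: int, kstate: KalmanState, n_init: int, gallery_size: int
    ):
        self.id = track_id
        self.kstate = kstate
        self.status = TrackStatus.TENTATIVE if n_init > 1 else TrackStatus.CONFIRMED
        self.hits = 1          # consecutive matched frames, spawning frame included
        self.a_k = 0           # frames since last successful match
        self._n_init = n_init
        self._gallery: list[np.ndarray] = []
        self._gallery_size = gallery_size

    @property
    def is_confirmed(self) -> bool:
        return self.status is TrackStatus.CONFIRMED

    @property
    def is_tentative(self) -> bool:
        return self.status is TrackStatus.TENTATIVE

    @property
    def is_deleted(self) -> bool:
        return self.status is TrackStatus.DELETED

    @property
    def bbox(self) -> BBox:
        return from_measurement(self.kstate.measurement)

    @property
    def gallery(self) -> np.ndarray:
        if not self._gallery:
            return np.zeros((0, 0))
        return np.vstack(self._gallery)

    def predict(self, kf: KalmanFilter) -> None:
        self.kstate = kf.predict(self.kstate)
        self.a_k += 1

    def update(self, kf: KalmanFilter, det: Detection) -> None:
        self.kstate = kf.update(self.kstate, to_measurement(det.bbox))
        self.hits += 1
        self.a_k = 0
        if det.feature is not None:
            self._gallery.append(det.feature)
            del self._gallery[: -self._gallery_size]
        if self.is_tentative and self.hits >= self._n_init:
            self.status = TrackStatus.CONFIRMED

    def mark_missed(self, max_age: int) -> None:
        if self.is_tentative or self.a_k > max_age:
            self.status = TrackStatus.DELETED


class Tracker:
    """Stateful multi-object tracker driven one frame at a time."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.kf = KalmanFilter(self.config.pos_weight, self.config.vel_weight)
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame = 0

    # -- association helpers ------------------------------------------------

    def _cascade_cost_fn(self, tracks: list[Track], dets: list[Detection]):
        use_appearance = all(d.feature is not None for d in dets) and len(dets) > 0
        feats = (
            np.array([d.feature for d in dets]) if use_appearance else None
        )
        measurements = np.array(
            [to_measurement(d.bbox).as_array() for d in dets]
        ).reshape(len(dets), 4)
        cfg = self.config

        def cost_fn(track_idx: Sequence[int], det_idx: Sequence[int]) -> np.ndarray:
            sub_tracks = [tracks[i] for i in track_idx]
            sub_meas = measurements[list(det_idx)]
            gating = np.array(
                [self.kf.gating_distance(t.kstate, sub_meas) for t in sub_tracks]
            ).reshape(len(sub_tracks), len(det_idx))
            if use_appearance:
                costs = appearance_cost(
                    [t.gallery for t in sub_tracks],
                    feats[list(det_idx)],
                )
            else:
                # degraded mode without re-ID features: motion distance is
                # the cost itself, capped by the same chi-square gate
                costs = gating.copy()
            return gate_cost_matrix(costs, gating, cfg.gate_threshold)

        max_cost = cfg.max_cost if use_appearance else cfg.gate_threshold
        return cost_fn, max_cost

    # -- the per-frame step --------------------------------------------------

    def step(
        self, frame_dets: list[Detection], frame: int | None = None
    ) -> list[tuple[int, BBox]]:
        """Advance one frame; returns (id, box) for confirmed matched tracks."""
        frames = {d.frame for d in frame_dets}
        if len(frames) > 1:
            raise SequencingError(f"detections from multiple frames: {sorted(frames)}")
        if frames:
            frame = frames.pop()
        elif frame is None:
            frame = self._last_frame + 1
        if frame != self._last_frame + 1:
            raise SequencingError(
                f"expected frame {self._last_frame + 1}, got {frame}"
            )
        self._last_frame = frame
        cfg = self.config

        # (1) predict
        for t in self.tracks:
            t.predict(self.kf)

        # (2) preprocess
        dets = nms(filter_confidence(frame_dets, cfg.tau), cfg.nms_thresh)

        # (3)+(4) associate: cascade over confirmed tracks, freshest first
        confirmed = [t for t in self.tracks if t.is_confirmed]
        cost_fn, max_cost = self._cascade_cost_fn(confirmed, dets)
        cascade = matching_cascade(
            cost_fn, max_cost, [t.a_k for t in confirmed], len(dets)
        )
        matches = [(confirmed[r], dets[c]) for r, c in cascade.matches]

        # IoU fallback: tentative tracks plus confirmed ones missed just now
        iou_pool = [t for t in self.tracks if t.is_tentative]
        leftover_confirmed = []
        for i in cascade.unmatched_tracks:
            (iou_pool if confirmed[i].a_k == 1 else leftover_confirmed).append(
                confirmed[i]
            )
        remaining = [dets[j] for j in cascade.unmatched_detections]
        fallback = iou_match(
            [t.bbox for t in iou_pool], [d.bbox for d in remaining], cfg.iou_floor
        )
        matches += [(iou_pool[r], remaining[c]) for r, c in fallback.matches]
        unmatched_tracks = (
            leftover_confirmed
            + [iou_pool[i] for i in fallback.unmatched_tracks]
        )
        unmatched_dets = [remaining[j] for j in fallback.unmatched_detections]

        # (5) update, lifecycle, births
        for track, det in matches:
            track.update(self.kf, det)
        for track in unmatched_tracks:
            track.mark_missed(cfg.max_age)
        for det in unmatched_dets:
            self._spawn(det)
        self.tracks = [t for t in self.tracks if not t.is_deleted]

        # (6) emit
        return [
            (t.id, t.bbox)
            for t in self.tracks
            if t.is_confirmed and t.a_k == 0
        ]

    def _spawn(self, det: Detection) -> None:
        track = Track(
            self._next_id,
            self.kf.initiate(to_measurement(det.bbox)),
            self.config.n_init,
            self.config.gallery_size,
        )
        if det.feature is not None:
            track._gallery.append(det.feature)
        self.tracks.append(track)
        self._next_id += 1

    def run(self, frame_sequences: Iterable[list[Detection]]) -> pd.DataFrame:
        """Batch driver: one ``step`` per frame, results stacked in a table."""
        rows = []
        for frame_idx, dets in enumerate(frame_sequences, start=1):
            for track_id, box in self.step(dets, frame=frame_idx):
                rows.append(
                    (frame_idx, track_id, box.left, box.top, box.width, box.height)
                )
        return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def run_tracker(
    frame_sequences: Iterable[list[Detection]], config: TrackerConfig | None = None
) -> pd.DataFrame:
    """Convenience wrapper: fresh tracker, one pass over the sequence."""
    return Tracker(config).run(frame_sequences)
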
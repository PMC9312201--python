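"""Bounding boxes, measurement-space conversion, and detection preprocessing.

Coordinates are continuous pixels with the origin at the image top-left,
x rightward and y downward; boxes are stored as (left, top, width, height)
to stay bit-compatible with the MOT-Challenge interchange format, and frame
indices are 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidBoxError, InvalidMeasurementError

__all__ = [
    "BBox",
    "Detection",
    "MeasurementVec",
    "iou",
    "to_measurement",
    "from_measurement",
    "filter_confidence",
    "nms",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned rectangle in pixel coordinates.

    Parameters
    ----------
    left, top : float
        Coordinates of the top-left corner.
    width, height : float
        Side lengths; must be strictly positive.
    """

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidBoxError(
                f"box sides must be positive, got {self.width}x{self.height}"
            )

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class MeasurementVec:
    """Box in measurement space: center (u, v), aspect ratio gamma = w/h, height h."""

    u: float
    v: float
    gamma: float
    h: float

    def __post_init__(self) -> None:
        if not (self.gamma > 0 and self.h > 0):
            raise InvalidMeasurementError(
                f"gamma and h must be positive, got gamma={self.gamma}, h={self.h}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v, self.gamma, self.h], dtype=float)


@dataclass(frozen=True)
class Detection:
    """One detector output: a frame-stamped box with confidence.

    ``feature`` is an optional unit-norm appearance embedding (re-ID vector)
    used by the association cascade; detectors without a re-ID head leave it
    ``None`` and the tracker falls back to motion-only matching.
    """

    frame: int
    bbox: BBox
    confidence: float
    feature: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame indices are 1-based, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        if self.feature is not None:
            f = np.asarray(self.feature, dtype=float)
            norm = float(np.linalg.norm(f))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"feature must be unit-norm, got |f| = {norm}")
            object.__setattr__(self, "feature", f)


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.right, b.right) - max(a.left, b.left)
    iy = min(a.bottom, b.bottom) - max(a.top, b.top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return min(inter / (a.area + b.area - inter), 1.0)


def to_measurement(b: BBox) -> MeasurementVec:
    """Convert a box to the (u, v, gamma, h) measurement the Kalman filter observes."""
    return MeasurementVec(
        u=b.left + b.width / 2.0,
        v=b.top + b.height / 2.0,
        gamma=b.width / b.height,
        h=b.height,
    )


def from_measurement(m: MeasurementVec) -> BBox:
    """Inverse of :func:`to_measurement`."""
    width = m.gamma * m.h
    return BBox(left=m.u - width / 2.0, top=m.v - m.h / 2.0, width=width, height=m.h)


def filter_confidence(dets: list[Detection], tau: float) -> list[Detection]:
    """Keep detections with confidence >= tau, preserving order."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    return [d for d in dets if d.confidence >= tau]


def nms(dets: list[Detection], iou_thresh: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending confidence (ties broken by lower input
    index); a box is dropped when its IoU with an already kept box exceeds
    ``iou_thresh``.  Kept detections are returned in their original input
    order, so the operation is idempotent and order-stable.
    """
    if not (0.0 < iou_thresh <= 1.0):
        raise ValueError(f"iou_thresh must lie in (0, 1], got {iou_thresh}")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept: list[int] = []
    for i in order:
        if all(iou(dets[i].bbox, dets[j].bbox) <= iou_thresh for j in kept):
            kept.append(i)
    return [dets[i] for i in sorted(kept)]
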
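"""Single-line counting over tracker output.

A virtual counting line is drawn across the scene.  Two grow-only sets
drive the count: set ``A`` holds every track id whose box center has
touched the line, and set ``B`` holds every id that touched the line and
then detached on the far side.  The running count is ``|B|``.  Because ids
are collected in sets, a target dithering on the line, retreating to its
entry side, or re-crossing is never counted twice — the failure modes the
single-line scheme is designed to avoid.

"Touching" is modeled as the center entering a band of configurable
half-width around the line segment; a sign-flip fallback registers fast
targets whose center jumps the band between consecutive observations.
Crossings are registered only while the center's projection lies within
the segment (extended by the band half-width at the endpoints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .geometry import BBox

__all__ = [
    "CountingLine",
    "CounterState",
    "LineCounter",
    "side_of",
    "update_counter",
    "count",
    "interval_counts",
]

#: side labels returned by :func:`side_of`
NEGATIVE, ON_BAND, POSITIVE = -1, 0, 1


@dataclass(frozen=True)
class CountingLine:
    """The counting line: endpoints, touch band, and countable direction.

    ``direction_mode`` filters which crossings count: ``"both"`` (default),
    ``"left_to_right"`` (entry on the left of the directed line p1->p2,
    i.e. the positive side), or ``"right_to_left"``.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    band_halfwidth: float = 0.0
    direction_mode: str = "both"

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ConfigError("counting line endpoints must differ")
        if self.band_halfwidth < 0:
            raise ConfigError("band_halfwidth must be >= 0")
        if self.direction_mode not in ("both", "left_to_right", "right_to_left"):
            raise ConfigError(f"unknown direction_mode {self.direction_mode!r}")

    @property
    def length(self) -> float:
        return math.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1])

    def _geometry(self, point: tuple[float, float]) -> tuple[float, float, float]:
        """(signed cross product, perpendicular distance, projection along line)."""
        dx, dy = self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]
        rx, ry = point[0] - self.p1[0], point[1] - self.p1[1]
        cross = dx * ry - dy * rx
        length = self.length
        return cross, abs(cross) / length, (dx * rx + dy * ry) / length

    def within_segment(self, point: tuple[float, float]) -> bool:
        """Is the point's projection inside the segment, band-extended?"""
        _, _, proj = self._geometry(point)
        return -self.band_halfwidth <= proj <= self.length + self.band_halfwidth


def side_of(point: tuple[float, float], line: CountingLine) -> int:
    """Which side of the (infinite) line the point lies on.

    Returns ``POSITIVE`` / ``NEGATIVE`` by the sign of the 2-D cross
    product of (p2 - p1) with (point - p1), or ``ON_BAND`` when the
    perpendicular distance is within the band half-width.
    """
    cross, dist, _ = line._geometry(point)
    if dist <= line.band_halfwidth:
        return ON_BAND
    return POSITIVE if cross > 0 else NEGATIVE


def _countable(entry_side: int, exit_side: int, mode: str) -> bool:
    if mode == "left_to_right":
        return entry_side == POSITIVE and exit_side == NEGATIVE
    if mode == "right_to_left":
        return entry_side == NEGATIVE and exit_side == POSITIVE
    return exit_side != entry_side


@dataclass
class CounterState:
    """Grow-only bookkeeping of the counter: B is always a subset of A."""

    A: set[int] = field(default_factory=set)
    B: set[int] = field(default_factory=set)
    entry_side: dict[int, int | None] = field(default_factory=dict)
    last_side: dict[int, int] = field(default_factory=dict)


class LineCounter:
    """The single-line counting state machine, fed one frame at a time."""

    def __init__(self, line: CountingLine):
        self.line = line
        self.state = CounterState()

    @property
    def count(self) -> int:
        return len(self.state.B)

    def update(self, frame_tracks: list[tuple[int, BBox]]) -> "CounterState":
        """Observe one frame of confirmed (id, box) tracker output."""
        st = self.state
        for track_id, box in frame_tracks:
            center = box.center
            side = side_of(center, self.line)
            within = self.line.within_segment(center)
            prev = st.last_side.get(track_id)
            if side == ON_BAND:
                if within and track_id not in st.A:
                    st.A.add(track_id)
                    st.entry_side[track_id] = prev  # None if first seen on-band
                continue  # still touching: last off-band side is unchanged
            if (
                track_id not in st.A
                and prev is not None
                and side != prev
                and within
            ):
                # jumped the band in a single step: register the touch
                st.A.add(track_id)
                st.entry_side[track_id] = prev
            if track_id in st.A and track_id not in st.B:
                entry = st.entry_side.get(track_id)
                if entry is None:
                    # approach side unknown (first ever seen on the line):
                    # adopt this side, so a later full crossing still counts
                    st.entry_side[track_id] = side
                elif _countable(entry, side, self.line.direction_mode):
                    st.B.add(track_id)
            st.last_side[track_id] = side
        return st


def update_counter(
    state: CounterState, frame_tracks: list[tuple[int, BBox]], line: CountingLine
) -> CounterState:
    """Functional wrapper over :class:`LineCounter` for a single frame."""
    counter = LineCounter(line)
    counter.state = state
    return counter.update(frame_tracks)


def count(state: CounterState) -> int:
    """The running count: the number of ids that completed a crossing."""
    return len(state.B)


def interval_counts(
    track_table: pd.DataFrame, line: CountingLine, interval_frames: int
) -> list[int]:
    """Cumulative count at the end of each interval of ``interval_frames``.

    Mirrors the periodic-reporting protocol used when validating counts
    against manual tallies over fixed time windows.
    """
    if interval_frames < 1:
        raise ConfigError("interval_frames must be >= 1")
    counter = LineCounter(line)
    if len(track_table) == 0:
        return []
    last_frame = int(track_table["frame"].max())
    by_frame = dict(tuple(track_table.groupby("frame")))
    counts = []
    for frame in range(1, last_frame + 1):
        group = by_frame.get(frame)
        if group is not None:
            counter.update(
                [
                    (int(r.id), BBox(r.left, r.top, r.width, r.height))
                    for r in group.itertuples()
                ]
            )
        if frame % interval_frames == 0:
            counts.append(counter.count)
    if last_frame % interval_frames != 0:
        counts.append(counter.count)
    return counts
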
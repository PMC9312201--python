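"""Synthetic pen-scene simulator.

Generates ground-truth trajectories of animals milling about a pen under a
fixed overhead-oblique camera, together with degraded detector output, so
the tracker, counter and metrics can be exercised end-to-end without any
video.  The simulator emulates the statistics that matter to a
tracking-by-detection pipeline:

* 10-30 targets moving with noisy constant velocity (a heading random
  walk at constant speed, reflected at the pen walls);
* bounding-box jitter on the detected boxes;
* occlusion-driven missed detections: when two ground-truth boxes overlap
  beyond a threshold, the box farther from the camera (higher bottom edge
  in the oblique view) is dropped with an elevated probability;
* uniform false positives at a Poisson rate per frame;
* identity-correlated appearance embeddings: each identity owns a fixed
  random unit vector, and its detections emit noisy renormalized copies.

When a ``crossing_schedule`` and counting line are configured, the
scheduled targets instead follow straight paths that cross the line at the
scheduled frames while the remaining targets stay on the entry side —
scripted scenes with an exactly known crossing count.

Randomness is split into named substreams (motion / dropout / jitter /
false positives / features) so that toggling one corruption does not shift
the draws of the others; everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import CountingLine, side_of
from .errors import ConfigError
from .geometry import BBox, Detection, iou

__all__ = [
    "SceneConfig",
    "SimulatedScene",
    "simulate",
    "scripted_crossing_scene",
    "true_crossings",
    "occlusion_encounter",
]


@dataclass(frozen=True)
class SceneConfig:
    """All simulator parameters.  Defaults model a surveillance view of a
    pen holding around fifteen animals (pens hold a dozen to two dozen),
    boxes of ~40 px, mild detector jitter and a light miss/false-positive
    load."""

    n_targets: int = 15
    arena: tuple[float, float] = (1280.0, 720.0)
    frames: int = 200
    speed_mean: float = 3.0          # px per frame
    speed_std: float = 1.0
    turn_std: float = 0.15           # rad per frame, heading random walk
    box_size_mean: float = 40.0      # px
    box_size_std: float = 6.0
    jitter_sigma: float = 1.0        # px, detection box noise
    p_miss_base: float = 0.05
    p_miss_occluded: float = 0.5
    occlusion_iou: float = 0.3
    fp_rate: float = 0.2             # expected false positives per frame
    feature_dim: int = 32            # 0 disables appearance features
    feature_noise: float = 0.1
    line: CountingLine | None = None
    crossing_schedule: tuple[tuple[int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_targets <= 50):
            raise ConfigError("n_targets must lie in [1, 50]")
        for p in (self.p_miss_base, self.p_miss_occluded):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("miss probabilities must lie in [0, 1]")
        if not (0.0 < self.occlusion_iou < 1.0):
            raise ConfigError("occlusion_iou must lie in (0, 1)")
        if self.box_size_mean >= min(self.arena) / 2:
            raise ConfigError("boxes do not fit in the arena")
        if self.crossing_schedule is not None:
            ids = [i for i, _ in self.crossing_schedule]
            if len(ids) != len(set(ids)):
                raise ConfigError("crossing_schedule repeats a target id")
            if self.line is None:
                raise ConfigError("crossing_schedule requires a counting line")
            if any(i < 1 or i > self.n_targets for i in ids):
                raise ConfigError("scheduled ids must lie in [1, n_targets]")


@dataclass(frozen=True)
class SimulatedScene:
    """Ground-truth tracks, per-frame detections, and the generating config."""

    gt: pd.DataFrame                    # frame, id, left, top, width, height
    detections: list[list[Detection]]   # detections[f-1] belongs to frame f
    config: SceneConfig


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _free_paths(cfg: SceneConfig, rng: np.random.Generator, sizes: np.ndarray):
    """Heading-random-walk constant-speed motion, reflected at the walls."""
    W, H = cfg.arena
    n, T = cfg.n_targets, cfg.frames
    speeds = np.clip(rng.normal(cfg.speed_mean, cfg.speed_std, n), 0.1, None)
    headings = rng.uniform(0, 2 * math.pi, n)
    lo = sizes / 2.0  # (n, 2) half-sizes: centers must stay inside by these
    centers = np.column_stack(
        [
            rng.uniform(lo[:, 0], W - lo[:, 0]),
            rng.uniform(lo[:, 1], H - lo[:, 1]),
        ]
    )
    out = np.empty((T, n, 2))
    for t in range(T):
        out[t] = centers
        headings = headings + rng.normal(0.0, cfg.turn_std, n)
        centers = centers + speeds[:, None] * np.column_stack(
            [np.cos(headings), np.sin(headings)]
        )
        # reflect at the pen walls
        for axis, limit in ((0, W), (1, H)):
            low, high = lo[:, axis], limit - lo[:, axis]
            under = centers[:, axis] < low
            over = centers[:, axis] > high
            centers[under, axis] = 2 * low[under] - centers[under, axis]
            centers[over, axis] = 2 * high[over] - centers[over, axis]
            if axis == 0:
                headings[under | over] = math.pi - headings[under | over]
            else:
                headings[under | over] = -headings[under | over]
    return out


def _ray_extent(
    q: np.ndarray, direction: np.ndarray, half: np.ndarray, arena: tuple[float, float]
) -> float:
    """How far a center can travel from q along direction and stay in the pen."""
    extent = math.inf
    for axis, limit in ((0, arena[0]), (1, arena[1])):
        d = direction[axis]
        if abs(d) < 1e-12:
            continue
        for bound in (half[axis], limit - half[axis]):
            s = (bound - q[axis]) / d
            if s > 0:
                extent = min(extent, s)
    return 0.0 if math.isinf(extent) else extent


def _scripted_paths(cfg: SceneConfig, sizes: np.ndarray) -> np.ndarray:
    """Straight crossing paths for scheduled ids; the rest parked off-line."""
    line = cfg.line
    assert line is not None and cfg.crossing_schedule is not None
    W, H = cfg.arena
    T, n = cfg.frames, cfg.n_targets
    p1 = np.array(line.p1, dtype=float)
    d = np.array(line.p2, dtype=float) - p1
    length = float(np.linalg.norm(d))
    u = d / length
    n_pos = np.array([-u[1], u[0]])  # unit normal toward the positive side
    schedule = dict(cfg.crossing_schedule)
    crossers = sorted(schedule)
    speed = max(cfg.speed_mean, 0.5)
    out = np.empty((T, n, 2))
    lane = {tid: (k + 0.5) * length / len(crossers) for k, tid in enumerate(crossers)}
    bystander_rank = 0
    for tid in range(1, n + 1):
        half = sizes[tid - 1] / 2.0
        if tid in schedule:
            f_cross = schedule[tid]
            if not (1 <= f_cross <= T):
                raise ConfigError(f"crossing frame {f_cross} outside the scene")
            q = p1 + u * lane[tid]
            d_in = 0.9 * _ray_extent(q, n_pos, half, cfg.arena)
            d_out = 0.9 * _ray_extent(q, -n_pos, half, cfg.arena)
            if min(d_in, d_out) <= line.band_halfwidth + speed:
                raise ConfigError("counting line too close to the pen wall")
            for t in range(1, T + 1):
                s = speed * (f_cross - t)  # signed distance from the line
                out[t - 1, tid - 1] = q + n_pos * float(np.clip(s, -d_out, d_in))
        else:
            # park bystanders on the entry side, well clear of the band
            margin = line.band_halfwidth + 4 * speed + max(sizes[:, 1]) / 2
            q = p1 + u * ((bystander_rank + 0.5) * length / max(n - len(crossers), 1))
            d_in = _ray_extent(q, n_pos, half, cfg.arena)
            s = min(max(margin, 0.6 * d_in), 0.95 * d_in)
            out[:, tid - 1] = q + n_pos * s
            bystander_rank += 1
    return out


def _degrade(
    cfg: SceneConfig,
    centers: np.ndarray,
    sizes: np.ndarray,
    streams: dict[str, np.random.Generator],
) -> tuple[pd.DataFrame, list[list[Detection]]]:
    """Shared detector-degradation pipeline: jitter, misses, false positives."""
    T, n = centers.shape[:2]
    dropout, jitter, fp, feat = (
        streams["dropout"],
        streams["jitter"],
        streams["fp"],
        streams["features"],
    )
    use_features = cfg.feature_dim > 0
    if use_features:
        id_vecs = np.array(
            [_unit(feat.standard_normal(cfg.feature_dim)) for _ in range(n)]
        )
    rows = []
    detections: list[list[Detection]] = []
    for t in range(T):
        boxes = [
            BBox(
                centers[t, i, 0] - sizes[i, 0] / 2,
                centers[t, i, 1] - sizes[i, 1] / 2,
                sizes[i, 0],
                sizes[i, 1],
            )
            for i in range(n)
        ]
        for i, b in enumerate(boxes):
            rows.append((t + 1, i + 1, b.left, b.top, b.width, b.height))
        # per-target-frame draws happen unconditionally so substreams stay
        # aligned when a corruption is toggled
        miss_u = dropout.uniform(size=n)
        box_noise = jitter.normal(0.0, 1.0, size=(n, 4))
        confs = np.clip(jitter.normal(0.9, 0.05, size=n), 0.55, 0.999)
        feat_noise = (
            feat.standard_normal((n, cfg.feature_dim)) if use_features else None
        )
        frame_dets: list[Detection] = []
        for i, b in enumerate(boxes):
            occluded = any(
                j != i
                and iou(b, boxes[j]) > cfg.occlusion_iou
                and b.bottom < boxes[j].bottom  # farther from the camera
                for j in range(n)
            )
            p_miss = cfg.p_miss_occluded if occluded else cfg.p_miss_base
            if miss_u[i] < p_miss:
                continue
            noisy = BBox(
                b.left + cfg.jitter_sigma * box_noise[i, 0],
                b.top + cfg.jitter_sigma * box_noise[i, 1],
                max(b.width + cfg.jitter_sigma * box_noise[i, 2] / 2, 4.0),
                max(b.height + cfg.jitter_sigma * box_noise[i, 3] / 2, 4.0),
            )
            feature = None
            if use_features:
                feature = _unit(id_vecs[i] + cfg.feature_noise * feat_noise[i])
            frame_dets.append(
                Detection(t + 1, noisy, float(confs[i]), feature)
            )
        n_fp = fp.poisson(cfg.fp_rate)
        for _ in range(n_fp):
            w = float(np.clip(fp.normal(cfg.box_size_mean, cfg.box_size_std), 8, None))
            h = float(np.clip(fp.normal(cfg.box_size_mean, cfg.box_size_std), 8, None))
            left = fp.uniform(0, cfg.arena[0] - w)
            top = fp.uniform(0, cfg.arena[1] - h)
            feature = _unit(fp.standard_normal(cfg.feature_dim)) if use_features else None
            frame_dets.append(
                Detection(t + 1, BBox(left, top, w, h), float(fp.uniform(0.55, 0.8)), feature)
            )
        detections.append(frame_dets)
    gt = pd.DataFrame(rows, columns=["frame", "id", "left", "top", "width", "height"])
    return gt, detections


def simulate(cfg: SceneConfig) -> SimulatedScene:
    """Generate one scene: ground truth plus degraded detections."""
    ss = np.random.SeedSequence(cfg.seed)
    names = ("motion", "dropout", "jitter", "fp", "features")
    streams = dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))
    sizes = np.clip(
        streams["motion"].normal(
            cfg.box_size_mean, cfg.box_size_std, (cfg.n_targets, 2)
        ),
        8.0,
        None,
    )
    if np.any(sizes.max(axis=0) >= np.array(cfg.arena)):
        raise ConfigError("a sampled box does not fit in the arena")
    if cfg.crossing_schedule is not None:
        centers = _scripted_paths(cfg, sizes)
    else:
        centers = _free_paths(cfg, streams["motion"], sizes)
    gt, detections = _degrade(cfg, centers, sizes, streams)
    return SimulatedScene(gt=gt, detections=detections, config=cfg)


def scripted_crossing_scene(
    k: int, line: CountingLine, cfg: SceneConfig
) -> SimulatedScene:
    """A scene where exactly ``k`` identities cross the counting line.

    Target ids 1..k cross at evenly spaced frames (or at the frames of
    ``cfg.crossing_schedule`` when provided); the remaining targets stay
    parked on the entry side.
    """
    if k > cfg.n_targets:
        raise ConfigError(f"k={k} exceeds n_targets={cfg.n_targets}")
    if cfg.crossing_schedule is not None:
        schedule = cfg.crossing_schedule
        if len(schedule) != k:
            raise ConfigError("crossing_schedule length must equal k")
    else:
        first, last = 30, max(cfg.frames - 40, 31)
        gap = max((last - first) // max(k, 1), 1)
        schedule = tuple((i + 1, first + i * gap) for i in range(k))
    cfg = dataclasses.replace(cfg, line=line, crossing_schedule=schedule)
    if k == 0:
        # no crossers: park everyone (empty schedule still needs the line)
        cfg = dataclasses.replace(cfg, crossing_schedule=tuple())
    return simulate(cfg)


def true_crossings(gt: pd.DataFrame, line: CountingLine) -> int:
    """Number of distinct ground-truth ids whose center changes line side."""
    strict = dataclasses.replace(line, band_halfwidth=0.0)
    crossed = 0
    for _, group in gt.groupby("id"):
        sides = [
            side_of((r.left + r.width / 2, r.top + r.height / 2), strict)
            for r in group.sort_values("frame").itertuples()
        ]
        signs = [s for s in sides if s != 0]
        if any(a != b for a, b in zip(signs, signs[1:])):
            crossed += 1
    return crossed


def occlusion_encounter(
    seed: int,
    with_features: bool,
    occlusion_frames: int = 10,
    frames: int = 80,
) -> tuple[list[list[Detection]], dict[str, dict[int, tuple[float, float]]]]:
    """Two targets meet head-on, vanish behind each other, back off, reappear.

    A walks right and B walks left along the same corridor; shortly before
    their meeting point both are hidden for ``occlusion_frames`` frames
    (mutual occlusion), and nine frames in each backs away from the
    encounter.  The constant-velocity predictions therefore overshoot past
    the meeting point and land almost exactly on the *other* target's
    reappearance position, while each target's own reappearance stays
    within the Mahalanobis gate: motion-only association prefers the
    swapped pairing, whereas per-identity appearance features keep the
    correct one.  This is the confusion mode that motivates adding an
    appearance term to an occlusion-heavy tracker.

    Returns the per-frame detections and the true center of each target
    (``{"A": {frame: (x, y)}, "B": ...}``) for identity bookkeeping.
    """
    rng = np.random.default_rng(seed)
    v, y, size = 4.0, 200.0, 40.0
    t0 = 25                              # last frame before the occlusion
    t_rev = t0 + 9                       # both back off nine frames in
    t1 = t0 + occlusion_frames           # last hidden frame
    # positions at occlusion start: A left of the meeting point, B right
    delta = 40.0
    xa0, xb0 = 300.0 - delta, 300.0 + delta
    feat_a = _unit(rng.standard_normal(32))
    feat_b = _unit(rng.standard_normal(32))
    truth: dict[str, dict[int, tuple[float, float]]] = {"A": {}, "B": {}}
    dets: list[list[Detection]] = []
    for t in range(1, frames + 1):
        if t <= t0:
            xa = xa0 - v * (t0 - t)
            xb = xb0 + v * (t0 - t)
        elif t <= t_rev:
            xa = xa0 + v * (t - t0)
            xb = xb0 - v * (t - t0)
        else:
            xa = xa0 + v * (t_rev - t0) - v * (t - t_rev)
            xb = xb0 - v * (t_rev - t0) + v * (t - t_rev)
        truth["A"][t] = (xa, y)
        truth["B"][t] = (xb, y)
        frame_dets: list[Detection] = []
        if not (t0 < t <= t1):
            for x, f in ((xa, feat_a), (xb, feat_b)):
                jx, jy = rng.normal(0, 0.3, 2)
                box = BBox(x - size / 2 + jx, y - size / 2 + jy, size, size)
                frame_dets.append(
                    Detection(
                        t,
                        box,
                        0.95,
                        _unit(f + 0.05 * rng.standard_normal(32))
                        if with_features
                        else None,
                    )
                )
        dets.append(frame_dets)
    return dets, truth
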
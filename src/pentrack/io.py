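"""MOT-Challenge file I/O, appearance sidecars, and structured configuration.

Detections and tracks travel in the MOT-Challenge comma-separated layout —
``frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z`` — so any
third-party detector (e.g. a YOLO-family head detector) can feed the
tracker unchanged.  Appearance features ride in a sidecar CSV keyed by
``frame, det_index`` with one column per feature dimension, where
``det_index`` is the 0-based position of the detection within its frame's
rows.  Configuration lives in a single YAML file with ``scene``,
``tracker`` and ``line`` sections.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .counting import CountingLine
from .errors import ParseError
from .geometry import BBox, Detection
from .scene import SceneConfig
from .tracker import TrackerConfig

__all__ = [
    "MOT_COLUMNS",
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "read_features",
    "write_features",
    "load_config",
    "dump_config",
    "config_hash",
    "line_from_config",
    "scene_from_config",
    "tracker_from_config",
]

MOT_COLUMNS = ["frame", "id", "left", "top", "width", "height", "conf", "x", "y", "z"]

logger = logging.getLogger("pentrack")


def _read_mot(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=MOT_COLUMNS)
    try:
        df = pd.read_csv(path, header=None, names=MOT_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in MOT_COLUMNS[:7]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[MOT_COLUMNS[:7]].isna().any(axis=1)
    if bad.any():
        raise ParseError(f"malformed row in {path}", line=int(bad.idxmax()) + 1)
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def read_detections(
    path: str | Path, features_path: str | Path | None = None
) -> list[list[Detection]]:
    """Read a MOT det file into per-frame detection lists (index 0 = frame 1).

    Missing frames yield empty lists; the id column is ignored.  When a
    features sidecar is given, each detection gets its unit-norm embedding.
    """
    df = _read_mot(path)
    features = read_features(features_path) if features_path else {}
    n_frames = int(df["frame"].max()) if len(df) else 0
    per_frame: list[list[Detection]] = [[] for _ in range(n_frames)]
    for row in df.itertuples():
        frame = int(row.frame)
        idx = len(per_frame[frame - 1])
        try:
            det = Detection(
                frame=frame,
                bbox=BBox(row.left, row.top, row.width, row.height),
                confidence=float(row.conf),
                feature=features.get((frame, idx)),
            )
        except ValueError as exc:
            raise ParseError(f"invalid detection in {path}: {exc}", line=row.Index + 1)
        per_frame[frame - 1].append(det)
    logger.info("read %d detections over %d frames from %s", len(df), n_frames, path)
    return per_frame


def write_detections(detections: list[list[Detection]], path: str | Path) -> None:
    """Write per-frame detections as MOT det rows (id = -1, 6-decimal fields)."""
    rows = [
        (d.frame, -1, d.bbox.left, d.bbox.top, d.bbox.width, d.bbox.height,
         d.confidence, -1, -1, -1)
        for frame in detections
        for d in frame
    ]
    pd.DataFrame(rows, columns=MOT_COLUMNS).to_csv(
        path, header=False, index=False, float_format="%.6f"
    )
    logger.info("wrote %d detection rows to %s", len(rows), path)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a MOT gt/track file into a (frame, id, left, top, width, height) table."""
    df = _read_mot(path)
    out = df[["frame", "id", "left", "top", "width", "height"]].copy()
    out["frame"] = out["frame"].astype(int)
    out["id"] = out["id"].astype(int)
    return out


def write_tracks(track_table: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as MOT gt-style rows with conf = 1."""
    df = track_table.copy()
    for col, value in (("conf", 1), ("x", -1), ("y", -1), ("z", -1)):
        df[col] = value
    df[MOT_COLUMNS].to_csv(path, header=False, index=False, float_format="%.6f")
    logger.info("wrote %d track rows to %s", len(df), path)


def read_features(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    """Read an appearance sidecar: (frame, det_index) -> unit vector."""
    path = Path(path)
    if path.stat().st_size == 0:
        return {}
    try:
        df = pd.read_csv(path, header=None)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected frame, det_index, f0...; got {df.shape[1]} columns")
    out = {}
    for row in df.itertuples(index=False):
        vals = np.asarray(row[2:], dtype=float)
        out[(int(row[0]), int(row[1]))] = vals / np.linalg.norm(vals)
    return out


def write_features(detections: list[list[Detection]], path: str | Path) -> None:
    """Write the features of per-frame detections as a sidecar CSV."""
    rows = []
    for frame_dets in detections:
        for idx, d in enumerate(frame_dets):
            if d.feature is not None:
                rows.append([d.frame, idx, *d.feature])
    pd.DataFrame(rows).to_csv(path, header=False, index=False, float_format="%.8f")


# -- configuration -----------------------------------------------------------


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return cfg


def dump_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a config mapping, for run logging."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def line_from_config(cfg: dict[str, Any]) -> CountingLine:
    """Build the counting line from a ``line`` section:
    ``{x1, y1, x2, y2, band, direction}``."""
    section = cfg.get("line", cfg)
    return CountingLine(
        p1=(float(section["x1"]), float(section["y1"])),
        p2=(float(section["x2"]), float(section["y2"])),
        band_halfwidth=float(section.get("band", 0.0)),
        direction_mode=section.get("direction", "both"),
    )


def _build(cls, section: dict[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ParseError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**section)


def scene_from_config(cfg: dict[str, Any], seed: int | None = None) -> SceneConfig:
    section = dict(cfg.get("scene", {}))
    if seed is not None:
        section["seed"] = seed
    if "arena" in section:
        section["arena"] = tuple(section["arena"])
    if "crossing_schedule" in section and section["crossing_schedule"] is not None:
        section["crossing_schedule"] = tuple(
            (int(i), int(f)) for i, f in section["crossing_schedule"]
        )
    if "line" in cfg:
        section["line"] = line_from_config(cfg)
    return _build(SceneConfig, section)


def tracker_from_config(cfg: dict[str, Any]) -> TrackerConfig:
    return _build(TrackerConfig, dict(cfg.get("tracker", {})))
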
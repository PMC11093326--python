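"""Readers and writers for MOTChallenge text files, pose CSVs and configs.

The MOT dialect is the 10-column CSV used by the MOTChallenge benchmarks::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

Columns beyond ``conf`` are ignored on read and written as -1.  ``id = -1``
marks an identity-free raw detection.  Boxes are stored on disk as
(left, top, width, height) and in memory as center + size.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import IO, Union

import yaml

from .datamodel import (
    CameraIntrinsics,
    Config,
    Detection,
    FilterConfig,
    FrameTable,
    TrackerConfig,
    UAVPose,
)

PathOrIO = Union[str, Path, IO[str]]


def _as_text_stream(src: PathOrIO, mode: str = "r"):
    if isinstance(src, (str, Path)):
        return open(src, mode), True
    return src, False


class MOTParseError(ValueError):
    """Raised for a malformed MOT line; message names the line number."""


def read_mot_file(src: PathOrIO) -> FrameTable:
    """Parse a MOTChallenge det/gt/result file into a :class:`FrameTable`."""
    stream, close = _as_text_stream(src)
    records: list[Detection] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MOTParseError(
                    f"line {lineno}: expected >= 7 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                left, top, w, h, conf = (float(p) for p in parts[2:7])
            except ValueError as exc:
                raise MOTParseError(f"line {lineno}: {exc}") from None
            if w <= 0 or h <= 0:
                raise MOTParseError(
                    f"line {lineno}: non-positive box size ({w}, {h})"
                )
            try:
                records.append(
                    Detection.from_ltwh(
                        frame, left, top, w, h,
                        score=min(max(conf, 0.0), 1.0),
                        id=None if tid == -1 else tid,
                    )
                )
            except ValueError as exc:
                raise MOTParseError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            stream.close()
    return FrameTable(records)


def _fmt(x: float) -> str:
    """Shortest exact decimal: integers bare, floats via repr (round-trips)."""
    return str(int(x)) if x == int(x) else repr(float(x))


def write_mot_file(table: FrameTable, dst: PathOrIO, require_ids: bool = True) -> None:
    """Write a table in MOTChallenge field order, sorted by (frame, id)."""
    stream, close = _as_text_stream(dst, "w")
    try:
        for d in table:
            if d.id is None and require_ids:
                raise ValueError(f"record in frame {d.frame} has no id")
            tid = -1 if d.id is None else d.id
            stream.write(
                f"{d.frame},{tid},{_fmt(d.left)},{_fmt(d.top)},"
                f"{_fmt(d.size[0])},{_fmt(d.size[1])},{_fmt(d.score)},"
                "-1,-1,-1\n"
            )
    finally:
        if close:
            stream.close()


def mot_to_string(table: FrameTable, require_ids: bool = True) -> str:
    buf = _io.StringIO()
    write_mot_file(table, buf, require_ids=require_ids)
    return buf.getvalue()


POSE_COLUMNS = ["frame", "X", "Y", "Z", "roll", "pitch", "yaw", "pan", "tilt"]


def read_pose_file(src: PathOrIO) -> list[UAVPose]:
    """Read a pose CSV with header frame,X,Y,Z,roll,pitch,yaw,pan,tilt."""
    import pandas as pd

    df = pd.read_csv(src)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose file missing columns: {missing}")
    poses = [
        UAVPose(
            frame=int(r.frame),
            position=(float(r.X), float(r.Y), float(r.Z)),
            attitude=(float(r.roll), float(r.pitch), float(r.yaw)),
            gimbal=(float(r.pan), float(r.tilt)),
        )
        for r in df.itertuples()
    ]
    return sorted(poses, key=lambda p: p.frame)


def write_pose_file(poses: list[UAVPose], dst: PathOrIO) -> None:
    import pandas as pd

    rows = [
        dict(
            frame=p.frame, X=p.position[0], Y=p.position[1], Z=p.position[2],
            roll=p.attitude[0], pitch=p.attitude[1], yaw=p.attitude[2],
            pan=p.gimbal[0], tilt=p.gimbal[1],
        )
        for p in poses
    ]
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(dst, index=False)


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in '{section}' section: {sorted(unknown)}")
    if "transition" in data and data["transition"] is not None:
        data = dict(data)
        data["transition"] = [list(map(float, row)) for row in data["transition"]]
    if "models" in data:
        data = dict(data)
        data["models"] = tuple(data["models"])
    return cls(**data)


def load_config(src: PathOrIO) -> Config:
    """Load a YAML config; missing keys take documented defaults (L0 = 20)."""
    stream, close = _as_text_stream(src)
    try:
        doc = yaml.safe_load(stream) or {}
    finally:
        if close:
            stream.close()
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")

    tracker = _build_section(TrackerConfig, doc.get("tracker", {}) or {}, "tracker")
    filt = _build_section(FilterConfig, doc.get("filter", {}) or {}, "filter")
    scenario = None
    if "scenario" in doc and doc["scenario"]:
        from .simulate import ScenarioConfig

        scenario = _build_section(ScenarioConfig, doc["scenario"], "scenario")
    cfg = Config(tracker=tracker, filter=filt, scenario=scenario,
                 paths=doc.get("paths", {}) or {})
    cfg.validate()
    return cfg


def dump_config(cfg: Config, dst: PathOrIO) -> None:
    doc: dict = {
        "tracker": dataclasses.asdict(cfg.tracker),
        "filter": dataclasses.asdict(cfg.filter),
        "paths": dict(cfg.paths),
    }
    doc["filter"]["models"] = list(doc["filter"]["models"])
    if cfg.scenario is not None:
        doc["scenario"] = dataclasses.asdict(cfg.scenario)
    stream, close = _as_text_stream(dst, "w")
    try:
        yaml.safe_dump(doc, stream, sort_keys=False)
    finally:
        if close:
            stream.close()


def default_intrinsics() -> CameraIntrinsics:
    """640x640 frame with a 90 degree field of view (f = 320 px)."""
    return CameraIntrinsics(f=320.0, principal_point=(320.0, 320.0),
                            image_size=(640, 640))
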
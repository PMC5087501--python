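"""Readers and writers for the on-disk stream formats.

Sensor CSV: header ``time,ax,ay,az,gx,gy,gz`` (time in s, accel in g, gyro
in rad/s). Skeleton JSONL: one frame per line,
``{"t": <s>, "joints": {"left_hand": [x, y, z], ...}}`` with the 12
canonical joint names; a long-form CSV ``time,joint,x,y,z`` is also read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hiermotion.datamodel import (
    JOINT_NAMES,
    FormatError,
    SensorStream,
    SkeletonStream,
    StreamValidationError,
)

SENSOR_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]


def read_sensor_csv(path: str | Path, subject_id: str | None = None) -> SensorStream:
    """Read a wrist inertial recording; rows are sorted by time."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    times = df["time"].to_numpy(dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise StreamValidationError(f"{path}: duplicate or non-monotone timestamps")
    return SensorStream(
        subject_id=subject_id or Path(path).stem,
        timestamps=times,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
    )


def write_sensor_csv(stream: SensorStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.timestamps, stream.accel, stream.gyro]),
        columns=SENSOR_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_skeleton_jsonl(path: str | Path, track_id: str | None = None) -> SkeletonStream:
    """Read a skeleton track from JSON-lines.

    A frame listing fewer than 12 joints has the absent joints marked
    missing (NaN); an unknown joint name is a format error; an empty file
    is an error.
    """
    times: list[float] = []
    per_joint: dict[str, list[list[float]]] = {name: [] for name in JOINT_NAMES}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON") from exc
            if "t" not in rec or "joints" not in rec:
                raise FormatError(f"{path}:{lineno}: frame needs 't' and 'joints'")
            unknown = set(rec["joints"]) - set(JOINT_NAMES)
            if unknown:
                raise FormatError(
                    f"{path}:{lineno}: unknown joint name(s) {sorted(unknown)}"
                )
            times.append(float(rec["t"]))
            for name in JOINT_NAMES:
                coords = rec["joints"].get(name)
                if coords is None:
                    per_joint[name].append([np.nan, np.nan, np.nan])
                else:
                    if len(coords) != 3:
                        raise FormatError(
                            f"{path}:{lineno}: joint {name!r} needs 3 coordinates"
                        )
                    per_joint[name].append([float(c) for c in coords])
    if not times:
        raise FormatError(f"{path}: empty skeleton stream")
    order = np.argsort(times, kind="stable")
    return SkeletonStream(
        track_id=track_id or Path(path).stem,
        frame_times=np.asarray(times, dtype=float)[order],
        joints={
            name: np.asarray(rows, dtype=float)[order]
            for name, rows in per_joint.items()
        },
    )


def write_skeleton_jsonl(stream: SkeletonStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(stream.frame_times):
            joints = {
                name: [float(v) for v in stream.joints[name][i]]
                for name in JOINT_NAMES
                if not stream.missing[name][i]
            }
            fh.write(json.dumps({"t": float(t), "joints": joints}) + "\n")


def read_skeleton_csv(path: str | Path, track_id: str | None = None) -> SkeletonStream:
    """Read the long-form skeleton CSV ``time,joint,x,y,z``."""
    df = pd.read_csv(path)
    required = ["time", "joint", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    unknown = set(df["joint"].unique()) - set(JOINT_NAMES)
    if unknown:
        raise FormatError(f"{path}: unknown joint name(s) {sorted(unknown)}")
    if df.empty:
        raise FormatError(f"{path}: empty skeleton stream")
    times = np.sort(df["time"].unique())
    time_index = {t: i for i, t in enumerate(times)}
    joints = {name: np.full((len(times), 3), np.nan) for name in JOINT_NAMES}
    for row in df.itertuples(index=False):
        joints[row.joint][time_index[row.time]] = (row.x, row.y, row.z)
    return SkeletonStream(
        track_id=track_id or Path(path).stem,
        frame_times=times.astype(float),
        joints=joints,
    )
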
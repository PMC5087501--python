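"""Domain types: inertial streams, skeleton tracks, 6-second windows.

Coordinate conventions: skeleton joints are 3-D camera-frame positions in
meters, +y up. Accelerometer channels are in g (clipped to +/-2 g),
gyroscope channels in rad/s (clipped to +/-4 rad/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from hiermotion.config import RunConfig

logger = logging.getLogger(__name__)

#: Canonical joint names tracked by the camera, in frozen order.
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "left_elbow",
    "right_elbow",
    "left_hand",
    "right_hand",
    "left_knee",
    "right_knee",
    "left_foot",
    "right_foot",
    "hip_center",
    "left_hip",
    "right_hip",
)

ACCEL_CHANNELS = ("ax", "ay", "az")
GYRO_CHANNELS = ("gx", "gy", "gz")
SENSOR_CHANNELS = ACCEL_CHANNELS + GYRO_CHANNELS


class FormatError(ValueError):
    """A file does not conform to the expected on-disk schema."""


class StreamValidationError(ValueError):
    """Stream content violates an invariant (ordering, shape, labels)."""


def _clip_with_warning(values: np.ndarray, limit: float, what: str) -> np.ndarray:
    out_of_range = np.abs(values) > limit
    if np.any(out_of_range):
        logger.warning(
            "%d %s samples outside +/-%g clipped", int(out_of_range.sum()), what, limit
        )
        values = np.clip(values, -limit, limit)
    return values


@dataclass
class SensorStream:
    """A wrist inertial recording: timestamps + 3-axis accel + 3-axis gyro.

    ``accel`` and ``gyro`` are (n, 3) float arrays; timestamps are seconds,
    strictly increasing. Out-of-range samples are clipped to the sensor
    ranges with a logged warning rather than rejected.
    """

    subject_id: str
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    rate_hz: float = 50.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise StreamValidationError(
                f"channel shapes {self.accel.shape}/{self.gyro.shape} inconsistent "
                f"with {n} timestamps"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise StreamValidationError("timestamps must be strictly increasing")
        cfg = RunConfig()
        self.accel = _clip_with_warning(self.accel, cfg.accel_range_g, "accelerometer")
        self.gyro = _clip_with_warning(self.gyro, cfg.gyro_range_rad_s, "gyroscope")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def slice_time(self, start: float, stop: float) -> "SensorWindow":
        """Samples with timestamps in the half-open interval [start, stop)."""
        mask = (self.timestamps >= start) & (self.timestamps < stop)
        return SensorWindow(
            subject_id=self.subject_id,
            timestamps=self.timestamps[mask],
            accel=self.accel[mask],
            gyro=self.gyro[mask],
        )


@dataclass
class SensorWindow:
    """One 6-second inertial segment (~300 samples x 6 channels)."""

    subject_id: str
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    window_index: int | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise StreamValidationError("window channel shapes inconsistent")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    def channels(self) -> np.ndarray:
        """(n, 6) array in frozen order ax, ay, az, gx, gy, gz."""
        return np.hstack([self.accel, self.gyro])


@dataclass
class SkeletonStream:
    """A camera skeleton track: per-frame 3-D positions of the 12 joints.

    ``joints`` maps each canonical joint name to an (n_frames, 3) float
    array; missing observations are NaN rows, mirrored in ``missing``.
    """

    track_id: str
    frame_times: np.ndarray
    joints: dict[str, np.ndarray]
    missing: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n = self.frame_times.shape[0]
        unknown = set(self.joints) - set(JOINT_NAMES)
        if unknown:
            raise FormatError(f"unknown joint name(s): {sorted(unknown)}")
        for name in JOINT_NAMES:
            arr = np.asarray(
                self.joints.get(name, np.full((n, 3), np.nan)), dtype=float
            )
            if arr.shape != (n, 3):
                raise StreamValidationError(
                    f"joint {name!r} has shape {arr.shape}, expected {(n, 3)}"
                )
            self.joints[name] = arr
            self.missing[name] = np.isnan(arr).any(axis=1)
        if n > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise StreamValidationError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return self.frame_times.shape[0]

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.frame_times[-1] - self.frame_times[0])

    def slice_time(self, start: float, stop: float) -> "SkeletonWindow":
        mask = (self.frame_times >= start) & (self.frame_times < stop)
        return SkeletonWindow(
            track_id=self.track_id,
            frame_times=self.frame_times[mask],
            joints={k: v[mask] for k, v in self.joints.items()},
        )


@dataclass
class SkeletonWindow:
    """One 6-second skeleton segment (~180 frames x 12 joints x 3 coords)."""

    track_id: str
    frame_times: np.ndarray
    joints: dict[str, np.ndarray]
    window_index: int | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n = self.frame_times.shape[0]
        for name, arr in self.joints.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise StreamValidationError(f"joint {name!r} frame count mismatch")
            self.joints[name] = arr

    def __len__(self) -> int:
        return self.frame_times.shape[0]

    def valid_frames(self, joint: str = "hip_center") -> np.ndarray:
        """Boolean mask of frames where ``joint`` is observed."""
        return ~np.isnan(self.joints[joint]).any(axis=1)


@dataclass(frozen=True)
class Segment:
    """One labeled (or unlabeled) 6-second analysis window.

    Windows are assigned by the half-open interval [start, start + 6 s);
    consecutive segments are non-overlapping.
    """

    window_index: int
    start_time: float
    label: str | None = None

    def interval(self, cfg: RunConfig | None = None) -> tuple[float, float]:
        window = (cfg or RunConfig()).window_seconds
        return (self.start_time, self.start_time + window)


def segment_windows(
    stream_duration: float,
    cfg: RunConfig | None = None,
    start_time: float = 0.0,
) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping 6-s segments.

    The trailing partial window is dropped, so a duration shorter than one
    window yields an empty list (240 s -> 40 segments).
    """
    cfg = cfg or RunConfig()
    if stream_duration < 0:
        raise ValueError("stream_duration must be non-negative")
    n = int(np.floor(stream_duration / cfg.window_seconds))
    return [
        Segment(window_index=i, start_time=start_time + i * cfg.window_seconds)
        for i in range(n)
    ]
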
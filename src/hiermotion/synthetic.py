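"""Synthetic multimodal sessions and scenes with known ground truth.

Emulates the signal structure the pipeline consumes: 50 Hz wrist inertial
streams and 30 Hz skeleton tracks whose hand-motion bursts co-occur
within a subject, activity-conditioned window statistics, and planted
group structure for the partition search. Hand-motion bursts are
two-state on/off processes with exponential dwell times, which produces
the thresholdable velocity structure the binarized-NCC mapping assumes.
Standing is modeled with one accelerometer axis pinned at +1 g (the
watch axis parallel to gravity). All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from hiermotion.config import RunConfig
from hiermotion.datamodel import (
    JOINT_NAMES,
    Segment,
    SensorStream,
    SkeletonStream,
    segment_windows,
)
from hiermotion.grouping import Partition

#: Eight-activity benchmark: brushing, calling, computer working,
#: drinking, eating, reading, sitting, standing.
ACTIVITY_LABELS = ("BR", "CL", "CW", "DK", "ET", "RD", "ST", "SD")

#: Planted grouping used by default in partition-search experiments:
#: standing alone (gravity-aligned accel mean), computer working with
#: sitting (both still), reading alone (page flips), calling alone
#: (still hand while standing), and the three hand-to-mouth/face
#: activities together.
PLANTED_PARTITION = Partition(
    (("SD",), ("CW", "ST"), ("RD",), ("CL",), ("BR", "DK", "ET"))
)

MOTION_ONLY_LABELS = ("walking", "standing", "sitting", "running")


@dataclass
class ActivityProfile:
    """Activity-conditioned signal statistics for one activity.

    Units: accel in g, gyro in rad/s, skeleton offsets/amplitudes in
    meters, frequencies in Hz, dwell times in seconds.
    """

    name: str
    group: str
    pose: str = "standing"  # base skeleton pose: "standing" | "sitting"
    accel_mean: tuple[float, float, float] = (0.0, 1.0, 0.0)
    accel_noise: float = 0.03
    accel_osc_amp: float = 0.0
    accel_osc_freq: float = 1.0
    gyro_noise: float = 0.05
    burst_level: float = 0.0       # gyro magnitude while the hand is active
    burst_freq: float = 2.0        # oscillation rate inside a burst
    burst_on_mean: float = 1.5     # exponential mean dwell, active state
    burst_off_mean: float = 2.0    # exponential mean dwell, idle state
    hand_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hand_amp: float = 0.0
    hand_freq: float = 2.0
    joint_jitter: float = 0.0015
    shape_proto: np.ndarray | None = None  # 70-dim Dirichlet mean, optional
    ehd_proto: np.ndarray | None = None    # 80-dim Dirichlet mean, optional

    def __post_init__(self) -> None:
        for nm in ("accel_noise", "gyro_noise", "joint_jitter",
                   "burst_on_mean", "burst_off_mean"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


def default_profiles() -> dict[str, ActivityProfile]:
    """Profile catalog for the 8 benchmark + 4 motion-only activities."""
    p: dict[str, ActivityProfile] = {}
    p["SD"] = ActivityProfile("SD", "g_stand", pose="standing",
                              accel_mean=(0.0, 1.0, 0.0), accel_noise=0.015,
                              burst_level=0.3, burst_off_mean=8.0)
    p["CW"] = ActivityProfile("CW", "g_still", pose="sitting",
                              accel_mean=(0.36, 0.80, 0.40), accel_noise=0.03,
                              burst_level=0.8, burst_on_mean=0.8,
                              burst_off_mean=2.0,
                              hand_offset=(0.05, 0.10, -0.25), hand_amp=0.02,
                              hand_freq=4.0)
    p["ST"] = ActivityProfile("ST", "g_still", pose="sitting",
                              accel_mean=(0.38, 0.78, 0.42), accel_noise=0.03,
                              burst_level=0.5, burst_off_mean=6.0,
                              hand_offset=(0.0, 0.0, 0.0), hand_amp=0.01)
    p["RD"] = ActivityProfile("RD", "g_read", pose="sitting",
                              accel_mean=(0.15, 0.90, 0.25), accel_noise=0.04,
                              burst_level=1.8, burst_on_mean=0.6,
                              burst_off_mean=4.0,
                              hand_offset=(0.0, 0.15, -0.20), hand_amp=0.08,
                              hand_freq=1.0)
    p["CL"] = ActivityProfile("CL", "g_call", pose="standing",
                              accel_mean=(0.70, 0.50, 0.20), accel_noise=0.02,
                              burst_level=0.4, burst_off_mean=10.0,
                              hand_offset=(-0.05, 0.55, 0.0), hand_amp=0.01)
    p["BR"] = ActivityProfile("BR", "g_hand", pose="standing",
                              accel_mean=(0.45, 0.70, 0.30), accel_noise=0.08,
                              accel_osc_amp=0.30, accel_osc_freq=3.0,
                              burst_level=2.6, burst_freq=3.0,
                              burst_on_mean=3.0, burst_off_mean=1.0,
                              hand_offset=(-0.05, 0.50, -0.05), hand_amp=0.10,
                              hand_freq=3.0)
    p["DK"] = ActivityProfile("DK", "g_hand", pose="sitting",
                              accel_mean=(0.50, 0.62, 0.32), accel_noise=0.06,
                              accel_osc_amp=0.10, accel_osc_freq=1.0,
                              burst_level=2.0, burst_freq=1.0,
                              burst_on_mean=1.5, burst_off_mean=3.0,
                              hand_offset=(0.00, 0.35, -0.10), hand_amp=0.15,
                              hand_freq=0.8)
    p["ET"] = ActivityProfile("ET", "g_hand", pose="sitting",
                              accel_mean=(0.48, 0.66, 0.28), accel_noise=0.06,
                              accel_osc_amp=0.12, accel_osc_freq=1.5,
                              burst_level=2.1, burst_freq=1.5,
                              burst_on_mean=1.2, burst_off_mean=1.5,
                              hand_offset=(0.00, 0.30, -0.15), hand_amp=0.12,
                              hand_freq=1.5)
    # Motion-only activities (no camera): the skeleton side is unused.
    p["standing"] = replace(p["SD"], name="standing", group="mo_static")
    p["sitting"] = ActivityProfile("sitting", "mo_static", pose="sitting",
                                   accel_mean=(0.38, 0.78, 0.42),
                                   accel_noise=0.02, burst_level=0.3,
                                   burst_off_mean=8.0)
    p["walking"] = ActivityProfile("walking", "mo_dyn", pose="standing",
                                   accel_mean=(0.10, 0.95, 0.10),
                                   accel_noise=0.08, accel_osc_amp=0.40,
                                   accel_osc_freq=2.0, burst_level=1.2,
                                   burst_freq=2.0, burst_on_mean=30.0,
                                   burst_off_mean=0.5, hand_amp=0.15,
                                   hand_freq=2.0)
    p["running"] = ActivityProfile("running", "mo_dyn", pose="standing",
                                   accel_mean=(0.15, 0.90, 0.15),
                                   accel_noise=0.15, accel_osc_amp=0.90,
                                   accel_osc_freq=3.0, burst_level=2.8,
                                   burst_freq=3.0, burst_on_mean=30.0,
                                   burst_off_mean=0.5, hand_amp=0.25,
                                   hand_freq=3.0)
    return p


_BASE_POSES = {
    # 12 joints, meters, +y up, camera looking along +z ~2.5 m away.
    "standing": {
        "head": (0.00, 1.70, 2.50),
        "left_elbow": (-0.25, 1.25, 2.50),
        "right_elbow": (0.25, 1.25, 2.50),
        "left_hand": (-0.30, 1.00, 2.45),
        "right_hand": (0.30, 1.00, 2.45),
        "left_knee": (-0.12, 0.55, 2.50),
        "right_knee": (0.12, 0.55, 2.50),
        "left_foot": (-0.12, 0.08, 2.50),
        "right_foot": (0.12, 0.08, 2.50),
        "hip_center": (0.00, 1.00, 2.50),
        "left_hip": (-0.12, 1.00, 2.50),
        "right_hip": (0.12, 1.00, 2.50),
    },
    "sitting": {
        "head": (0.00, 1.35, 2.50),
        "left_elbow": (-0.25, 0.95, 2.45),
        "right_elbow": (0.25, 0.95, 2.45),
        "left_hand": (-0.25, 0.80, 2.30),
        "right_hand": (0.25, 0.80, 2.30),
        "left_knee": (-0.12, 0.50, 2.20),
        "right_knee": (0.12, 0.50, 2.20),
        "left_foot": (-0.12, 0.08, 2.25),
        "right_foot": (0.12, 0.08, 2.25),
        "hip_center": (0.00, 0.65, 2.50),
        "left_hip": (-0.12, 0.65, 2.50),
        "right_hip": (0.12, 0.65, 2.50),
    },
}


def burst_indicator(
    rng: np.random.Generator,
    n_samples: int,
    rate_hz: float,
    on_mean_s: float,
    off_mean_s: float,
    start_state: bool | None = None,
) -> np.ndarray:
    """Two-state on/off process with exponential dwell times (bool array)."""
    out = np.zeros(n_samples, dtype=bool)
    if start_state is None:
        start_state = rng.random() < on_mean_s / (on_mean_s + off_mean_s)
    state, i = bool(start_state), 0
    while i < n_samples:
        dwell = rng.exponential(on_mean_s if state else off_mean_s)
        j = min(n_samples, i + max(1, int(round(dwell * rate_hz))))
        out[i:j] = state
        state, i = not state, j
    return out


def _sensor_signals(
    rng: np.random.Generator,
    profile: ActivityProfile,
    t: np.ndarray,
    burst: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n = t.size
    accel = np.tile(np.asarray(profile.accel_mean, dtype=float), (n, 1))
    if profile.accel_osc_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=3)
        for ax in range(3):
            accel[:, ax] += profile.accel_osc_amp * np.sin(
                2 * np.pi * profile.accel_osc_freq * t + phase[ax]
            ) / (1.0 + ax)  # axis-dependent attenuation
    accel += rng.normal(0.0, profile.accel_noise, size=(n, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    osc = np.abs(np.sin(2 * np.pi * profile.burst_freq * t + rng.uniform(0, 2 * np.pi)))
    gyro = (
        burst[:, None]
        * profile.burst_level
        * osc[:, None]
        * direction[None, :]
    )
    gyro = gyro + rng.normal(0.0, profile.gyro_noise, size=(n, 3))
    return accel, gyro


def _skeleton_frames(
    rng: np.random.Generator,
    profile: ActivityProfile,
    t: np.ndarray,
    burst: np.ndarray,
    watch_hand: str = "left_hand",
) -> dict[str, np.ndarray]:
    pose = _BASE_POSES[profile.pose]
    joints: dict[str, np.ndarray] = {}
    for name in JOINT_NAMES:
        base = np.asarray(pose[name], dtype=float)
        joints[name] = np.tile(base, (t.size, 1)) + rng.normal(
            0.0, profile.joint_jitter, size=(t.size, 3)
        )
    hand = joints[watch_hand]
    hand += np.asarray(profile.hand_offset, dtype=float)[None, :]
    if profile.hand_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sway = profile.hand_amp * np.sin(2 * np.pi * profile.hand_freq * t + phase)
        motion_dir = rng.normal(size=3)
        motion_dir /= np.linalg.norm(motion_dir)
        hand += burst[:, None] * sway[:, None] * motion_dir[None, :]
    return joints


def gen_session(
    schedule: list[tuple[str, float]],
    cfg: RunConfig | None = None,
    seed: int = 0,
    subject_id: str = "s1",
    profiles: dict[str, ActivityProfile] | None = None,
) -> tuple[SensorStream, SkeletonStream, list[Segment]]:
    """One subject performing ``schedule`` = [(activity, duration_s), ...].

    Returns the 50 Hz inertial stream, the 30 Hz skeleton track and the
    labeled 6-s segments (a segment takes the label of the activity at
    its start). Deterministic given the seed.
    """
    cfg = cfg or RunConfig()
    profiles = profiles or default_profiles()
    duration = float(sum(d for _, d in schedule))
    if duration <= 0:
        raise ValueError("schedule must cover a positive duration")
    rng = np.random.default_rng(seed)
    n_sensor = int(round(duration * cfg.sensor_rate_hz))
    n_skel = int(round(duration * cfg.skeleton_rate_hz))
    t_sensor = np.arange(n_sensor) / cfg.sensor_rate_hz
    t_skel = np.arange(n_skel) / cfg.skeleton_rate_hz
    accel = np.zeros((n_sensor, 3))
    gyro = np.zeros((n_sensor, 3))
    joints = {name: np.zeros((n_skel, 3)) for name in JOINT_NAMES}

    start = 0.0
    for activity, dur in schedule:
        prof = profiles[activity]
        m_sensor = (t_sensor >= start) & (t_sensor < start + dur)
        m_skel = (t_skel >= start) & (t_skel < start + dur)
        ts = t_sensor[m_sensor] - start
        burst = burst_indicator(
            rng, ts.size, cfg.sensor_rate_hz, prof.burst_on_mean, prof.burst_off_mean
        )
        a, g = _sensor_signals(rng, prof, ts, burst)
        accel[m_sensor], gyro[m_sensor] = a, g
        tk = t_skel[m_skel] - start
        burst_k = burst[
            np.clip((tk * cfg.sensor_rate_hz).astype(int), 0, ts.size - 1)
        ]
        frames = _skeleton_frames(rng, prof, tk, burst_k, cfg.watch_hand)
        for name in JOINT_NAMES:
            joints[name][m_skel] = frames[name]
        start += dur

    sensor = SensorStream(subject_id=subject_id, timestamps=t_sensor,
                          accel=np.clip(accel, -cfg.accel_range_g, cfg.accel_range_g),
                          gyro=np.clip(gyro, -cfg.gyro_range_rad_s, cfg.gyro_range_rad_s),
                          rate_hz=cfg.sensor_rate_hz)
    skeleton = SkeletonStream(track_id=f"track_{subject_id}",
                              frame_times=t_skel, joints=joints)
    segments = segment_windows(duration, cfg)
    bounds = np.cumsum([0.0] + [d for _, d in schedule])
    labeled = []
    for seg in segments:
        k = int(np.searchsorted(bounds, seg.start_time, side="right") - 1)
        labeled.append(Segment(seg.window_index, seg.start_time, schedule[k][0]))
    return sensor, skeleton, labeled


@dataclass
class SceneSpec:
    """A multi-person scene for mapping experiments.

    ``overlap`` is the fraction of activity slots in which all subjects
    perform co-occurring hand motion (mapping-ambiguous time); outside
    those slots exactly one subject is active at a time.
    """

    n_subjects: int = 2
    duration_s: float = 900.0
    overlap: float = 0.0
    slot_seconds: float = 6.0
    seed: int = 0
    all_idle: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a scene needs at least 2 subjects")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap fraction must lie in [0, 1]")
        if self.duration_s <= 0 or self.slot_seconds <= 0:
            raise ValueError("durations must be positive")


def gen_scene(
    spec: SceneSpec, cfg: RunConfig | None = None
) -> tuple[list[SkeletonStream], list[SensorStream], dict[str, str]]:
    """Generate paired streams for ``spec.n_subjects`` and ground truth.

    Returns (skeleton tracks, sensor streams, mapping track_id ->
    subject_id). Within a slot each active subject's gyro bursts and
    image-hand bursts share one indicator; in overlap slots all subjects
    share the *same* indicator, so their binarized series are identical
    there and carry no identity information.
    """
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(spec.seed)
    n_slots = int(np.floor(spec.duration_s / spec.slot_seconds))
    duration = n_slots * spec.slot_seconds
    n_sensor = int(round(duration * cfg.sensor_rate_hz))
    n_skel = int(round(duration * cfg.skeleton_rate_hz))
    t_sensor = np.arange(n_sensor) / cfg.sensor_rate_hz
    t_skel = np.arange(n_skel) / cfg.skeleton_rate_hz
    per_slot_sensor = int(round(spec.slot_seconds * cfg.sensor_rate_hz))

    # Per-slot activity pattern.
    active = np.zeros((spec.n_subjects, n_slots), dtype=bool)
    shared_slot = np.zeros(n_slots, dtype=bool)
    if not spec.all_idle:
        for s in range(n_slots):
            if rng.random() < spec.overlap:
                active[:, s] = True
                shared_slot[s] = True
            else:
                active[rng.integers(spec.n_subjects), s] = True

    # Per-subject burst indicator at sensor rate.
    indicators = np.zeros((spec.n_subjects, n_sensor), dtype=bool)
    for s in range(n_slots):
        sl = slice(s * per_slot_sensor, (s + 1) * per_slot_sensor)
        if shared_slot[s]:
            shared = burst_indicator(rng, per_slot_sensor, cfg.sensor_rate_hz,
                                     2.0, 0.8, start_state=True)
            for i in range(spec.n_subjects):
                indicators[i, sl] = shared
        else:
            for i in range(spec.n_subjects):
                if active[i, s]:
                    indicators[i, sl] = burst_indicator(
                        rng, per_slot_sensor, cfg.sensor_rate_hz, 2.0, 0.8,
                        start_state=True,
                    )

    prof = ActivityProfile("free", "scene", pose="standing",
                           accel_mean=(0.2, 0.9, 0.2), accel_noise=0.05,
                           burst_level=2.6, burst_freq=2.0,
                           hand_amp=0.14, hand_freq=2.0)
    skeletons, sensors, truth = [], [], {}
    for i in range(spec.n_subjects):
        sid = f"s{i + 1}"
        accel, gyro = _sensor_signals(rng, prof, t_sensor, indicators[i])
        sensors.append(SensorStream(
            subject_id=sid, timestamps=t_sensor,
            accel=np.clip(accel, -cfg.accel_range_g, cfg.accel_range_g),
            gyro=np.clip(gyro, -cfg.gyro_range_rad_s, cfg.gyro_range_rad_s),
            rate_hz=cfg.sensor_rate_hz,
        ))
        burst_k = indicators[i][
            np.clip((t_skel * cfg.sensor_rate_hz).astype(int), 0, n_sensor - 1)
        ]
        joints = _skeleton_frames(rng, prof, t_skel, burst_k, cfg.watch_hand)
        # separate subjects laterally in camera space
        shift = np.array([1.2 * i - 0.6 * (spec.n_subjects - 1), 0.0, 0.0])
        joints = {k: v + shift for k, v in joints.items()}
        track = SkeletonStream(track_id=f"track_{sid}", frame_times=t_skel,
                               joints=joints)
        skeletons.append(track)
        truth[track.track_id] = sid
    return skeletons, sensors, truth


def _prototypes(labels, n_bins: int, seed: int = 12345) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    return {
        lab: rng.dirichlet(np.full(n_bins, 0.6))
        for lab in sorted(labels)
    }


def gen_edge_histograms(
    labels, seed: int = 0, concentration: float = 200.0
) -> np.ndarray:
    """80-dim edge-histogram stand-ins: per-activity Dirichlet prototype
    plus Dirichlet sampling noise (rows align with ``labels``)."""
    labels = np.asarray(labels)
    protos = _prototypes(np.unique(labels), 80)
    rng = np.random.default_rng(seed)
    return np.vstack([
        rng.dirichlet(protos[lab] * concentration + 1e-3) for lab in labels
    ])


def gen_striped_crop(
    size: tuple[int, int] = (32, 32), orientation: str = "vertical",
    period: int = 2, low: float = 0.0, high: float = 255.0,
) -> np.ndarray:
    """Synthetic grayscale crop of alternating stripes (EHD exercise)."""
    h, w = size
    idx = np.arange(w if orientation == "vertical" else h)
    line = np.where((idx // (period // 2 or 1)) % 2 == 0, low, high)
    if orientation == "vertical":
        return np.tile(line, (h, 1))
    return np.tile(line[:, None], (1, w))


def gen_grouped_features(
    labels=ACTIVITY_LABELS,
    partition: Partition = PLANTED_PARTITION,
    n_per_class: int = 50,
    seed: int = 0,
    motion_separation: float = 6.0,
    visual_separation: float = 3.0,
    noise: float = 1.0,
    n_motion_features: int = 26,
    n_visual_features: int = 150,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrices with planted group structure.

    The motion block separates *groups* only: all activities of a group
    share one motion mean (between-group separation ``motion_separation``
    against unit noise, within-group separation zero). The visual block
    separates activities *within* a group but is aliased across groups:
    activities occupying the same within-group position share a visual
    mean, so visual features alone cannot resolve the group. Together the
    two blocks identify the activity — the structure the two-layer
    classifier exploits.

    Returns (X_motion, X_visual, y), deterministic in ``seed``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    labels = tuple(labels)
    if set(labels) != set(partition.labels):
        raise ValueError("partition must cover exactly the label set")
    rng = np.random.default_rng(seed)
    group_means = rng.normal(size=(partition.m, n_motion_features))
    group_means *= motion_separation / np.linalg.norm(group_means, axis=1,
                                                     keepdims=True)
    max_size = max(len(g) for g in partition.groups)
    index_means = rng.normal(size=(max_size, n_visual_features))
    index_means *= visual_separation / np.linalg.norm(index_means, axis=1,
                                                     keepdims=True)
    membership = partition.group_index()
    within_index = {
        lab: gi for group in partition.groups for gi, lab in enumerate(group)
    }
    Xm, Xv, y = [], [], []
    for lab in sorted(labels):
        g = membership[lab]
        Xm.append(group_means[g] + rng.normal(0.0, noise,
                                              size=(n_per_class, n_motion_features)))
        Xv.append(index_means[within_index[lab]] +
                  rng.normal(0.0, noise, size=(n_per_class, n_visual_features)))
        y.extend([lab] * n_per_class)
    return np.vstack(Xm), np.vstack(Xv), np.asarray(y)
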
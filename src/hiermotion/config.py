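"""Run configuration.

Every numeric constant used by the pipeline is a named key here, so an
experiment is fully described by one flat YAML document. Defaults are the
published operating point of the method.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Flat configuration for the whole pipeline.

    Parameters
    ----------
    window_seconds : float
        Duration of one analysis segment. Fixed at 6 s by the protocol.
    sensor_rate_hz : float
        Nominal inertial sampling rate (accelerometer + gyroscope).
    skeleton_rate_hz : float
        Nominal skeleton frame rate of the depth camera.
    t_gyro, t_image : float
        Hand-activity thresholds on the gyroscope velocity norm (rad/s)
        and on the image-space hand velocity (m/frame). Defaults are the
        fitted operating values 1.3 and 0.023.
    t_gyro_grid_*, t_image_grid_* : float
        Grid ranges/steps for threshold fitting. The gyro grid spans the
        sensor's +/-4 rad/s range; the image grid brackets 0.023.
    median_filter_len : int
        Odd length of the median filter applied to velocity series at the
        comparison rate, in samples.
    comparison_rate_hz : float
        Common clock the two velocity modalities are aggregated onto
        (per-interval maximum) before binarization.
    invalid_epsilon : float
        A 6-s mapping window where every candidate NCC is within this of 0
        is an invalid interval and casts no vote.
    svm_c : float
        Regularization strength of the linear-kernel SVMs.
    cv_folds : int
        Stratified folds for group-accuracy estimation inside the group
        selection search.
    random_seed : int
        Seed for every stochastic component.
    watch_hand : str
        Joint carrying the watch; the smart watch is worn on the left hand.
    ehd_threshold : float
        Minimum oriented-edge response for a block to count as an edge
        (MPEG-7 reference value 11 on 8-bit intensities).
    """

    window_seconds: float = 6.0
    sensor_rate_hz: float = 50.0
    skeleton_rate_hz: float = 30.0
    accel_range_g: float = 2.0
    gyro_range_rad_s: float = 4.0

    t_gyro: float = 1.3
    t_image: float = 0.023
    t_gyro_grid_min: float = 0.0
    t_gyro_grid_max: float = 4.0
    t_gyro_grid_step: float = 0.05
    t_image_grid_min: float = 0.0
    t_image_grid_max: float = 0.1
    t_image_grid_step: float = 0.001

    median_filter_len: int = 5
    comparison_rate_hz: float = 1.0
    invalid_epsilon: float = 0.05
    exclusive_assignment: bool = False

    svm_c: float = 1.0
    cv_folds: int = 5
    random_seed: int = 0

    watch_hand: str = "left_hand"
    ehd_threshold: float = 11.0
    use_ehd: bool = True

    motion_only_labels: tuple[str, ...] = (
        "walking",
        "standing",
        "sitting",
        "running",
    )

    def __post_init__(self) -> None:
        for name in (
            "window_seconds",
            "sensor_rate_hz",
            "skeleton_rate_hz",
            "comparison_rate_hz",
            "svm_c",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.median_filter_len < 1 or self.median_filter_len % 2 == 0:
            raise ValueError("median_filter_len must be an odd integer >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.t_gyro < 0 or self.t_image < 0:
            raise ValueError("thresholds must be non-negative")

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_seconds * self.sensor_rate_hz))

    @property
    def frames_per_window(self) -> int:
        return int(round(self.window_seconds * self.skeleton_rate_hz))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a flat ``key: value`` YAML document."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "motion_only_labels" in raw:
            raw["motion_only_labels"] = tuple(raw["motion_only_labels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["motion_only_labels"] = list(doc["motion_only_labels"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
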
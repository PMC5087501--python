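"""Motion-sensor feature vector for one 6-second inertial window.

Per channel (ax, ay, az, gx, gy, gz): mean, population variance, range and
spectral energy; plus one absolute-change (AC) statistic per sensor triple
(accelerometer, gyroscope). 4 x 6 + 2 = 26 features in frozen order.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from hiermotion.datamodel import SENSOR_CHANNELS, SensorWindow

#: Frozen feature ordering; models are only portable under this ordering.
MOTION_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mean_{c}" for c in SENSOR_CHANNELS]
    + [f"var_{c}" for c in SENSOR_CHANNELS]
    + [f"range_{c}" for c in SENSOR_CHANNELS]
    + [f"specen_{c}" for c in SENSOR_CHANNELS]
    + ["ac_accel", "ac_gyro"]
)


class InsufficientWindowError(ValueError):
    """A window is too short for the requested statistic."""


def _require_samples(n: int) -> None:
    if n < 2:
        raise InsufficientWindowError(f"window has {n} samples, need >= 2")


def basic_stats(window: SensorWindow) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel mean, population variance (divide by N) and range.

    Returns three length-6 arrays in channel order ax..gz.
    """
    x = window.channels()
    _require_samples(x.shape[0])
    mean = x.mean(axis=0)
    var = x.var(axis=0)  # population convention (ddof=0)
    rng = x.max(axis=0) - x.min(axis=0)
    return mean, var, rng


def spectral_energy(channel: np.ndarray) -> float:
    """DC-excluded periodogram energy of one channel.

    sum_{k != 0} |X_k|^2 / N^2 for the length-N DFT X. The DC bin is
    excluded so a constant signal has zero energy; a pure cosine of
    amplitude A spanning an integer number of cycles yields A^2 / 2.
    """
    x = np.asarray(channel, dtype=float)
    _require_samples(x.shape[0])
    n = x.shape[0]
    spectrum = np.fft.rfft(x)
    # rfft halves the spectrum; double the shared bins (not DC, not Nyquist
    # when n is even) to recover the full-DFT energy.
    mags = np.abs(spectrum) ** 2
    weights = np.full(mags.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    total = float(np.sum(weights[1:] * mags[1:]))
    return total / n**2


def absolute_change(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Windowed mean absolute sample-to-sample change over three axes.

    (1/N) * sum over the three axes of |v_i - v_{i-1}| for i = 2..N; the
    N - 1 first differences are divided by N, matching the printed
    normalizer of the defining formula.
    """
    arrs = [np.asarray(a, dtype=float) for a in (x, y, z)]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise ValueError("axes must be 1-D arrays of equal length")
    _require_samples(n)
    return float(sum(np.abs(np.diff(a)).sum() for a in arrs) / n)


def motion_features(window: SensorWindow) -> np.ndarray:
    """Assemble the 26-element motion feature vector in frozen order."""
    mean, var, rng = basic_stats(window)
    energies = np.array([spectral_energy(window.channels()[:, j]) for j in range(6)])
    ac_a = absolute_change(window.accel[:, 0], window.accel[:, 1], window.accel[:, 2])
    ac_g = absolute_change(window.gyro[:, 0], window.gyro[:, 1], window.gyro[:, 2])
    return np.concatenate([mean, var, rng, energies, [ac_a, ac_g]])


class MotionFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: SensorWindow list -> (n, 26) matrix."""

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self.n_features_out_ = len(MOTION_FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([motion_features(w) for w in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(MOTION_FEATURE_NAMES, dtype=object)
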
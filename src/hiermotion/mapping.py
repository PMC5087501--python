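"""NCC-based binding of wrist sensor streams to camera skeleton tracks.

In a multi-person scene the camera sees several skeletons and the server
receives several watch streams; which watch belongs to which skeleton is
unknown. Both modalities, however, observe the same quantity — how active
the watch hand is. The gyroscope velocity norm and the image-space hand
speed are each aggregated onto a common 1 Hz clock, median-filtered,
thresholded into binary "hand active" indicator series GT(t) and IT(t),
and compared window-by-window with a normalized cross correlation

    N = sum(GT * IT) / sqrt(sum(GT^2) * sum(IT^2)) in [0, 1].

Each 6-s window votes for the sensor with the highest N against the
skeleton; windows where every candidate's N is near zero (nobody moved)
are invalid and cast no vote; the sensor collecting the most votes over a
long recording is bound to the skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import linear_sum_assignment

from hiermotion.config import RunConfig
from hiermotion.datamodel import SensorStream, SkeletonStream
from hiermotion.features.visual import hand_velocity


class NoOverlapError(ValueError):
    """Candidate streams share no usable time span."""


@dataclass
class VelocitySeries:
    """A non-negative activity-level series from one modality.

    ``modality`` is "gyro" (rad/s) or "image" (m/frame).
    """

    times: np.ndarray
    values: np.ndarray
    source_id: str = ""
    modality: str = "gyro"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values[~np.isnan(self.values)] < 0):
            raise ValueError("velocity values must be non-negative")


@dataclass
class BinaryActivitySeries:
    """Aligned 0/1 hand-active indicators on a common clock."""

    times: np.ndarray
    values: np.ndarray
    threshold: float
    source_id: str = ""
    modality: str = "gyro"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary series values must be 0 or 1")


def gyro_velocity(stream: SensorStream) -> VelocitySeries:
    """Per-sample Euclidean norm of the 3-axis gyroscope (rad/s)."""
    return VelocitySeries(
        times=stream.timestamps,
        values=np.linalg.norm(stream.gyro, axis=1),
        source_id=stream.subject_id,
        modality="gyro",
    )


def image_velocity(skeleton: SkeletonStream, joint: str = "left_hand") -> VelocitySeries:
    """Hand speed from the skeleton track (m/frame), at frame times."""
    v = hand_velocity(skeleton, joint)
    v = np.where(np.isnan(v), np.nan, v)
    return VelocitySeries(
        times=skeleton.frame_times[1:],
        values=v,
        source_id=skeleton.track_id,
        modality="image",
    )


def aggregate_to_clock(
    series: VelocitySeries, t0: float, t1: float, rate_hz: float = 1.0
) -> VelocitySeries:
    """Per-interval maximum of a series on the clock [t0, t1) at rate_hz.

    The maximum (rather than the mean) preserves brief hand motions at
    either native rate; empty or all-missing intervals read 0 (inactive).
    """
    n = int(np.floor((t1 - t0) * rate_hz))
    edges = t0 + np.arange(n + 1) / rate_hz
    out = np.zeros(n)
    idx = np.searchsorted(series.times, edges)
    for k in range(n):
        chunk = series.values[idx[k] : idx[k + 1]]
        chunk = chunk[~np.isnan(chunk)]
        if chunk.size:
            out[k] = chunk.max()
    return VelocitySeries(
        times=edges[:-1], values=out, source_id=series.source_id,
        modality=series.modality,
    )


def smooth(series: VelocitySeries, filter_len: int = 5) -> VelocitySeries:
    """Median filter with edge replication; length preserved."""
    if filter_len < 1 or filter_len % 2 == 0:
        raise ValueError("filter_len must be an odd integer >= 1")
    values = median_filter(series.values, size=filter_len, mode="nearest")
    return VelocitySeries(
        times=series.times, values=values, source_id=series.source_id,
        modality=series.modality,
    )


def binarize(series: VelocitySeries, threshold: float) -> BinaryActivitySeries:
    """Strict-greater thresholding into a 0/1 hand-active indicator."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    active = np.nan_to_num(series.values, nan=0.0) > threshold
    return BinaryActivitySeries(
        times=series.times,
        values=active.astype(np.uint8),
        threshold=threshold,
        source_id=series.source_id,
        modality=series.modality,
    )


def ncc(gt: BinaryActivitySeries | np.ndarray, it: BinaryActivitySeries | np.ndarray) -> float:
    """Normalized cross correlation of two aligned binary series.

    Returns NaN (undefined) when either series is identically zero, since
    the denominator vanishes; otherwise a value in [0, 1].
    """
    a = np.asarray(gt.values if isinstance(gt, BinaryActivitySeries) else gt, dtype=float)
    b = np.asarray(it.values if isinstance(it, BinaryActivitySeries) else it, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share length and clock")
    denom = np.sum(a * a) * np.sum(b * b)
    if denom == 0:
        return float("nan")
    return float(np.sum(a * b) / np.sqrt(denom))


def threshold_objective(gt: np.ndarray, it: np.ndarray) -> float:
    """Score of one (T_gyro, T_image) choice on aligned binary indicators.

    sum(GT*IT) / max(sum GT, sum IT) - sum(GT*IT) / D over the D aligned
    test points: the first term rewards agreement of the active sets, the
    second penalizes thresholds so low that everything looks active.
    Returns -inf when neither indicator ever fires.
    """
    gt = np.asarray(gt, dtype=float)
    it = np.asarray(it, dtype=float)
    if gt.shape != it.shape or gt.ndim != 1 or gt.size == 0:
        raise ValueError("indicators must be equal-length non-empty 1-D arrays")
    d = gt.size
    s_g, s_i, s_gi = gt.sum(), it.sum(), float(np.sum(gt * it))
    m = max(s_g, s_i)
    if m == 0:
        return float("-inf")
    return s_gi / m - s_gi / d


def fit_thresholds(
    paired: list[tuple[VelocitySeries, VelocitySeries]],
    cfg: RunConfig | None = None,
) -> tuple[float, float]:
    """Grid-search the activity thresholds on paired same-subject series.

    Each pair (gyro velocity, image hand velocity) is aggregated onto the
    common comparison clock and median-filtered; the pooled points from
    all pairs are thresholded at every grid combination and the
    combination maximizing :func:`threshold_objective` is returned. Ties
    break toward the smallest T_gyro, then the smallest T_image.
    """
    cfg = cfg or RunConfig()
    tg_grid = np.arange(
        cfg.t_gyro_grid_min, cfg.t_gyro_grid_max + cfg.t_gyro_grid_step / 2,
        cfg.t_gyro_grid_step,
    )
    ti_grid = np.arange(
        cfg.t_image_grid_min, cfg.t_image_grid_max + cfg.t_image_grid_step / 2,
        cfg.t_image_grid_step,
    )
    if tg_grid.size == 0 or ti_grid.size == 0:
        raise ValueError("threshold grids must be non-empty")
    if not paired:
        raise ValueError("need at least one paired series")
    vg_parts, vi_parts = [], []
    for g, im in paired:
        t0 = max(g.times[0], im.times[0])
        t1 = min(g.times[-1], im.times[-1])
        if t1 - t0 <= 1.0 / cfg.comparison_rate_hz:
            raise NoOverlapError("paired series do not overlap in time")
        ga = smooth(aggregate_to_clock(g, t0, t1, cfg.comparison_rate_hz),
                    cfg.median_filter_len)
        ia = smooth(aggregate_to_clock(im, t0, t1, cfg.comparison_rate_hz),
                    cfg.median_filter_len)
        vg_parts.append(ga.values)
        vi_parts.append(ia.values)
    vg = np.concatenate(vg_parts)
    vi = np.concatenate(vi_parts)
    d = vg.size
    # Vectorized sweep: indicator matrices (n_thresholds, D).
    gt_mat = (vg[None, :] > tg_grid[:, None]).astype(float)
    it_mat = (vi[None, :] > ti_grid[:, None]).astype(float)
    s_g = gt_mat.sum(axis=1)
    s_i = it_mat.sum(axis=1)
    s_gi = gt_mat @ it_mat.T  # (n_tg, n_ti)
    denom = np.maximum(s_g[:, None], s_i[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        obj = s_gi / denom - s_gi / d
    obj[denom == 0] = -np.inf
    best = np.unravel_index(int(np.argmax(obj)), obj.shape)
    # argmax returns the first (row-major) maximum: smallest T_gyro, then
    # smallest T_image — the required deterministic tie-break.
    return float(tg_grid[best[0]]), float(ti_grid[best[1]])


@dataclass
class MappingResult:
    """Outcome of binding skeleton tracks to sensor streams.

    ``ncc_table`` has shape (n_skeletons, n_sensors, n_windows) with NaN
    where the NCC was undefined; ``votes`` counts, per skeleton, the
    windows each sensor won; ``assignment`` maps each track id to the
    winning sensor id or None when undetermined.
    """

    skeleton_ids: list[str]
    sensor_ids: list[str]
    ncc_table: np.ndarray
    votes: np.ndarray
    invalid_windows: np.ndarray
    assignment: dict[str, str | None] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.ncc_table.shape[2]

    def to_dict(self) -> dict:
        """JSON-serializable summary (per-pair votes, N summaries, result)."""
        out: dict = {"assignment": self.assignment, "pairs": []}
        for i, sk in enumerate(self.skeleton_ids):
            for j, se in enumerate(self.sensor_ids):
                vals = self.ncc_table[i, j]
                defined = vals[~np.isnan(vals)]
                out["pairs"].append(
                    {
                        "skeleton": sk,
                        "sensor": se,
                        "votes": int(self.votes[i, j]),
                        "ncc_mean": float(defined.mean()) if defined.size else None,
                        "ncc_defined_windows": int(defined.size),
                    }
                )
            out.setdefault("invalid_windows", {})[sk] = int(
                self.invalid_windows[i].sum()
            )
        out["n_windows"] = self.n_windows
        return out


def match_streams(
    skeletons: list[SkeletonStream],
    sensors: list[SensorStream],
    cfg: RunConfig | None = None,
) -> MappingResult:
    """Bind each skeleton track to the sensor stream that generated it.

    Protocol: per 6-s window of the overlapping span, the NCC between the
    binarized indicators of every (skeleton, sensor) pair is computed; a
    window where every candidate's N is within ``invalid_epsilon`` of 0
    (or undefined for all candidates) is invalid and dropped; every other
    window votes for the argmax sensor; the assignment is the sensor with
    the most votes. Ties — within a window or in the final tally — are
    left unresolved rather than guessed.
    """
    cfg = cfg or RunConfig()
    if not skeletons or not sensors:
        raise ValueError("need at least one skeleton and one sensor stream")
    t0 = max(
        [s.frame_times[0] for s in skeletons] + [s.timestamps[0] for s in sensors]
    )
    t1 = min(
        [s.frame_times[-1] for s in skeletons] + [s.timestamps[-1] for s in sensors]
    )
    if t1 - t0 < cfg.window_seconds:
        raise NoOverlapError("streams overlap for less than one window")

    def prep(v: VelocitySeries, threshold: float) -> np.ndarray:
        agg = aggregate_to_clock(v, t0, t1, cfg.comparison_rate_hz)
        return binarize(smooth(agg, cfg.median_filter_len), threshold).values

    gt = [prep(gyro_velocity(s), cfg.t_gyro) for s in sensors]
    it = [prep(image_velocity(s, cfg.watch_hand), cfg.t_image) for s in skeletons]

    per_win = int(round(cfg.window_seconds * cfg.comparison_rate_hz))
    n_win = len(it[0]) // per_win
    n_sk, n_se = len(skeletons), len(sensors)
    table = np.full((n_sk, n_se, n_win), np.nan)
    for w in range(n_win):
        sl = slice(w * per_win, (w + 1) * per_win)
        for i in range(n_sk):
            for j in range(n_se):
                table[i, j, w] = ncc(it[i][sl], gt[j][sl])

    votes = np.zeros((n_sk, n_se), dtype=int)
    invalid = np.zeros((n_sk, n_win), dtype=bool)
    for i in range(n_sk):
        for w in range(n_win):
            vals = table[i, :, w]
            defined = vals[~np.isnan(vals)]
            if defined.size == 0 or np.all(np.abs(defined) <= cfg.invalid_epsilon):
                invalid[i, w] = True
                continue
            scores = np.nan_to_num(vals, nan=0.0)
            top = scores.max()
            winners = np.flatnonzero(scores == top)
            if winners.size == 1:
                votes[i, winners[0]] += 1

    assignment: dict[str, str | None] = {}
    if cfg.exclusive_assignment and n_se >= n_sk:
        rows, cols = linear_sum_assignment(-votes)
        for i, j in zip(rows, cols):
            assignment[skeletons[i].track_id] = (
                sensors[j].subject_id if votes[i, j] > 0 else None
            )
    else:
        for i, sk in enumerate(skeletons):
            top = votes[i].max()
            winners = np.flatnonzero(votes[i] == top)
            if top == 0 or winners.size > 1:
                assignment[sk.track_id] = None
            else:
                assignment[sk.track_id] = sensors[winners[0]].subject_id

    return MappingResult(
        skeleton_ids=[s.track_id for s in skeletons],
        sensor_ids=[s.subject_id for s in sensors],
        ncc_table=table,
        votes=votes,
        invalid_windows=invalid,
        assignment=assignment,
    )
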
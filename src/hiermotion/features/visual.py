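"""Visual feature vector: skeleton shape histogram + edge histogram.

The shape histogram accumulates, over a 6-s window, the hip-centered
spherical angles of every tracked joint: the zenith angle (measured from
the +y camera vertical) is split into 7 equal bins and the azimuth angle
(in the x-z plane, counter-clockwise from +x) into 10, giving 70 bins
normalized to sum 1. The edge histogram descriptor (EHD) summarizes the
oriented-edge content of a grayscale hand-region crop: 4 x 4 sub-images,
each scanned in 2 x 2-pixel blocks classified by the strongest of five
oriented edge operators, yielding 16 x 5 = 80 bins. Concatenation gives
the 150-element visual feature vector.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from hiermotion.datamodel import SkeletonStream, SkeletonWindow

N_ZENITH_BINS = 7
N_AZIMUTH_BINS = 10
N_SHAPE_BINS = N_ZENITH_BINS * N_AZIMUTH_BINS
N_EHD_SUBIMAGES = 16
N_EDGE_TYPES = 5
N_EHD_BINS = N_EHD_SUBIMAGES * N_EDGE_TYPES

SHAPE_FEATURE_NAMES = tuple(f"sh_{i:02d}" for i in range(N_SHAPE_BINS))
EHD_FEATURE_NAMES = tuple(f"ehd_{i:02d}" for i in range(N_EHD_BINS))
VISUAL_FEATURE_NAMES = SHAPE_FEATURE_NAMES + EHD_FEATURE_NAMES

#: 2x2 oriented edge operators (vertical, horizontal, 45, 135,
#: non-directional), applied to block pixels [[a, b], [c, d]]. All are
#: zero-sum, so the descriptor ignores constant intensity shifts.
_SQRT2 = np.sqrt(2.0)
EDGE_OPERATORS = np.array(
    [
        [[1.0, -1.0], [1.0, -1.0]],          # vertical edge
        [[1.0, 1.0], [-1.0, -1.0]],          # horizontal edge
        [[_SQRT2, 0.0], [0.0, -_SQRT2]],     # 45-degree edge
        [[0.0, _SQRT2], [-_SQRT2, 0.0]],     # 135-degree edge
        [[2.0, -2.0], [-2.0, 2.0]],          # non-directional edge
    ]
)


class MissingJointError(ValueError):
    """Requested joint is not tracked for enough frames."""


class EmptyWindowError(ValueError):
    """No frame in the window has the data required for the feature."""


def hand_velocity(skeleton: SkeletonStream | SkeletonWindow, joint: str) -> np.ndarray:
    """Per-frame hand speed: Euclidean norm of the positional first
    differences of ``joint``, in meters per frame.

    Length is ``n_frames - 1``; entries adjacent to a missing observation
    are NaN. Differencing removes any constant translation of the scene.
    """
    if joint not in skeleton.joints:
        raise MissingJointError(f"joint {joint!r} not present")
    pos = skeleton.joints[joint]
    tracked = ~np.isnan(pos).any(axis=1)
    if tracked.sum() < 2:
        raise MissingJointError(f"joint {joint!r} tracked for < 2 frames")
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def spherical_bins(rel: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zenith/azimuth bin indices of hip-centered offsets ``rel`` (m, 3).

    Returns (zenith_bin, azimuth_bin, valid) where valid excludes offsets
    of (near-)zero radius, which have undefined angles.
    """
    rel = np.asarray(rel, dtype=float)
    r = np.linalg.norm(rel, axis=1)
    valid = r > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        zen = np.arccos(np.clip(rel[:, 1] / np.where(valid, r, 1.0), -1.0, 1.0))
        azi = np.mod(np.arctan2(rel[:, 2], rel[:, 0]), 2.0 * np.pi)
    zbin = np.minimum((zen / (np.pi / N_ZENITH_BINS)).astype(int), N_ZENITH_BINS - 1)
    abin = np.minimum(
        (azi / (2.0 * np.pi / N_AZIMUTH_BINS)).astype(int), N_AZIMUTH_BINS - 1
    )
    return zbin, abin, valid


def shape_histogram(window: SkeletonWindow) -> np.ndarray:
    """70-bin hip-centered angular histogram of joint positions.

    Every tracked joint in every frame with an observed hip center
    contributes one count at its (zenith, azimuth) bin; the hip center
    itself sits at radius zero and is skipped. Counts are normalized to
    sum 1. Frame order within the window is irrelevant, and translating
    the whole skeleton leaves the histogram unchanged.
    """
    hip = window.joints["hip_center"]
    hip_ok = ~np.isnan(hip).any(axis=1)
    if not hip_ok.any():
        raise EmptyWindowError("no frame with an observed hip center")
    counts = np.zeros((N_ZENITH_BINS, N_AZIMUTH_BINS))
    for name, pos in window.joints.items():
        if name == "hip_center":
            continue
        ok = hip_ok & ~np.isnan(pos).any(axis=1)
        if not ok.any():
            continue
        zbin, abin, valid = spherical_bins(pos[ok] - hip[ok])
        np.add.at(counts, (zbin[valid], abin[valid]), 1.0)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts.ravel()


def edge_histogram(crop: np.ndarray, threshold: float = 11.0) -> np.ndarray:
    """MPEG-7-style edge histogram descriptor of a grayscale crop.

    The crop is divided into 4 x 4 sub-images; each sub-image is scanned
    in non-overlapping 2 x 2-pixel blocks and each block is classified by
    the strongest of the five oriented edge operators, provided the
    response exceeds ``threshold`` (otherwise the block is edge-free).
    Per-sub-image 5-bin histograms, normalized by the sub-image block
    count, are concatenated row-major into 80 values in [0, 1].
    """
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 2 or crop.shape[0] < 16 or crop.shape[1] < 16:
        raise ValueError(f"crop must be 2-D and >= 16x16 pixels, got {crop.shape}")
    sub_h, sub_w = crop.shape[0] // 4, crop.shape[1] // 4
    hist = np.zeros((4, 4, N_EDGE_TYPES))
    for si in range(4):
        for sj in range(4):
            sub = crop[si * sub_h : (si + 1) * sub_h, sj * sub_w : (sj + 1) * sub_w]
            bh, bw = sub.shape[0] // 2, sub.shape[1] // 2
            blocks = (
                sub[: bh * 2, : bw * 2]
                .reshape(bh, 2, bw, 2)
                .transpose(0, 2, 1, 3)
                .reshape(-1, 2, 2)
            )
            responses = np.abs(
                np.einsum("bij,kij->bk", blocks, EDGE_OPERATORS)
            )
            strongest = responses.argmax(axis=1)
            passed = responses.max(axis=1) > threshold
            if passed.any():
                np.add.at(hist[si, sj], strongest[passed], 1.0)
            hist[si, sj] /= blocks.shape[0]
    return hist.reshape(-1)


def visual_features(
    window: SkeletonWindow,
    crop: np.ndarray | None = None,
    edge_hist: np.ndarray | None = None,
    use_ehd: bool = True,
    ehd_threshold: float = 11.0,
) -> np.ndarray:
    """Concatenate [shape histogram || EHD] into the visual feature vector.

    The edge histogram may be supplied precomputed (``edge_hist``) or be
    derived from a grayscale ``crop``; with ``use_ehd=False`` the
    70-element shape-histogram-only variant is returned.
    """
    sh = shape_histogram(window)
    if not use_ehd:
        return sh
    if edge_hist is not None:
        edge_hist = np.asarray(edge_hist, dtype=float)
        if edge_hist.shape != (N_EHD_BINS,):
            raise ValueError(f"edge histogram must have length {N_EHD_BINS}")
    elif crop is not None:
        edge_hist = edge_histogram(crop, threshold=ehd_threshold)
    else:
        raise ValueError("use_ehd=True requires a crop or a precomputed histogram")
    return np.concatenate([sh, edge_hist])


class VisualFeatureExtractor(BaseEstimator, TransformerMixin):
    """Sklearn transformer assembling visual feature rows.

    ``transform`` accepts a list of SkeletonWindow (``use_ehd=False``) or
    of ``(SkeletonWindow, edge_histogram_or_crop)`` pairs.
    """

    def __init__(self, use_ehd: bool = True, ehd_threshold: float = 11.0):
        self.use_ehd = use_ehd
        self.ehd_threshold = ehd_threshold

    def fit(self, X, y=None):
        self.n_features_out_ = N_SHAPE_BINS + (N_EHD_BINS if self.use_ehd else 0)
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            if isinstance(item, tuple):
                window, extra = item
            else:
                window, extra = item, None
            kwargs: dict = {"use_ehd": self.use_ehd, "ehd_threshold": self.ehd_threshold}
            if extra is not None:
                arr = np.asarray(extra)
                if arr.ndim == 2:
                    kwargs["crop"] = arr
                else:
                    kwargs["edge_hist"] = arr
            rows.append(visual_features(window, **kwargs))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = SHAPE_FEATURE_NAMES + (EHD_FEATURE_NAMES if self.use_ehd else ())
        return np.asarray(names, dtype=object)
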
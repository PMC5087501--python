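import numpy as np
import pytest

from hiermotion.datamodel import JOINT_NAMES, SkeletonStream, SkeletonWindow
from hiermotion.features.visual import (
    EmptyWindowError,
    MissingJointError,
    N_AZIMUTH_BINS,
    N_ZENITH_BINS,
    edge_histogram,
    hand_velocity,
    shape_histogram,
    spherical_bins,
    visual_features,
)
from hiermotion.synthetic import gen_striped_crop


def _stream(hand_positions, n=None):
    n = n or len(hand_positions)
    joints = {
        name: np.tile([0.0, 1.0, 2.5], (n, 1)) for name in JOINT_NAMES
    }
    joints["left_hand"] = np.asarray(hand_positions, dtype=float)
    return SkeletonStream("t", np.arange(n) / 30.0, joints)


def _window(joints, n):
    full = {name: np.tile([0.0, 1.0, 2.5], (n, 1)) for name in JOINT_NAMES}
    full.update({k: np.asarray(v, float) for k, v in joints.items()})
    return SkeletonWindow("t", np.arange(n) / 30.0, full)


class TestHandVelocity:
    def test_static_joint_zero(self):
        v = hand_velocity(_stream(np.tile([0.1, 1.0, 2.0], (10, 1))), "left_hand")
        assert v.shape == (9,)
        assert np.allclose(v, 0.0)

    def test_unit_step_per_frame(self):
        pos = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        v = hand_velocity(_stream(pos), "left_hand")
        assert np.allclose(v, 1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(20, 3))
        v1 = hand_velocity(_stream(pos), "left_hand")
        v2 = hand_velocity(_stream(pos + [5.0, -2.0, 9.0]), "left_hand")
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_untracked_joint_error(self):
        s = _stream(np.full((5, 3), np.nan))
        with pytest.raises(MissingJointError):
            hand_velocity(s, "left_hand")


class TestShapeHistogram:
    def test_joint_above_hip_lands_in_zenith_bin_zero(self):
        # one frame: left hand straight up (+y) from the hip center
        w = _window(
            {"hip_center": [[0.0, 1.0, 2.5]], "left_hand": [[0.0, 1.5, 2.5]]},
            n=1,
        )
        h = shape_histogram(w).reshape(N_ZENITH_BINS, N_AZIMUTH_BINS)
        # the probe joint is the only off-origin... other joints sit at the
        # hip position (radius 0) and are skipped, so all mass is zenith 0
        assert h[0].sum() == pytest.approx(1.0)
        assert h[1:].sum() == pytest.approx(0.0)

    def test_sums_to_one(self):
        rng = np.random.default_rng(4)
        joints = {
            name: rng.normal([0, 1, 2.5], 0.4, size=(12, 3)) for name in JOINT_NAMES
        }
        h = shape_histogram(SkeletonWindow("t", np.arange(12) / 30.0, joints))
        assert h.shape == (70,)
        assert h.sum() == pytest.approx(1.0)
        assert np.all(h >= 0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        joints = {
            name: rng.normal([0, 1, 2.5], 0.4, size=(6, 3)) for name in JOINT_NAMES
        }
        w1 = SkeletonWindow("t", np.arange(6) / 30.0, joints)
        shifted = {k: v + [3.0, -1.0, 0.5] for k, v in joints.items()}
        w2 = SkeletonWindow("t", np.arange(6) / 30.0, shifted)
        np.testing.assert_allclose(shape_histogram(w1), shape_histogram(w2),
                                   atol=1e-12)

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(10)
        joints = {
            name: rng.normal([0, 1, 2.5], 0.3, size=(8, 3)) for name in JOINT_NAMES
        }
        w1 = SkeletonWindow("t", np.arange(8) / 30.0, joints)
        perm = rng.permutation(8)
        w2 = SkeletonWindow(
            "t", np.arange(8) / 30.0, {k: v[perm] for k, v in joints.items()}
        )
        np.testing.assert_allclose(shape_histogram(w1), shape_histogram(w2))

    def test_bins_match_per_angle_brute_force(self):
        rng = np.random.default_rng(21)
        rel = rng.normal(size=(1000, 3))
        zbin, abin, valid = spherical_bins(rel)
        assert valid.all()
        for i in range(1000):
            x, y, z = rel[i]
            r = np.sqrt(x * x + y * y + z * z)
            theta = np.arccos(y / r)
            phi = np.arctan2(z, x) % (2 * np.pi)
            assert zbin[i] == min(int(theta // (np.pi / 7)), 6)
            assert abin[i] == min(int(phi // (2 * np.pi / 10)), 9)

    def test_no_valid_frame_is_error(self):
        w = _window({"hip_center": np.full((3, 3), np.nan)}, n=3)
        with pytest.raises(EmptyWindowError):
            shape_histogram(w)


class TestEdgeHistogram:
    def test_flat_crop_all_zero(self):
        assert np.allclose(edge_histogram(np.full((32, 32), 128.0)), 0.0)

    def test_vertical_stripes_fill_vertical_bins(self):
        crop = gen_striped_crop((32, 32), "vertical")
        h = edge_histogram(crop).reshape(16, 5)
        # every sub-image: all blocks classified as vertical edges
        assert np.allclose(h[:, 0], 1.0)
        assert np.allclose(h[:, 1:], 0.0)

    def test_horizontal_stripes_fill_horizontal_bins(self):
        crop = gen_striped_crop((32, 32), "horizontal")
        h = edge_histogram(crop).reshape(16, 5)
        assert np.allclose(h[:, 1], 1.0)

    def test_length_and_intensity_shift_invariance(self):
        rng = np.random.default_rng(3)
        crop = rng.uniform(0, 255, size=(33, 47))
        h1 = edge_histogram(crop)
        h2 = edge_histogram(crop + 40.0)
        assert h1.shape == (80,)
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_small_crop_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            edge_histogram(np.zeros((8, 8)))


class TestVisualFeatureVector:
    def _skel_window(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        joints = {
            name: rng.normal([0, 1, 2.5], 0.3, size=(n, 3)) for name in JOINT_NAMES
        }
        return SkeletonWindow("t", np.arange(n) / 30.0, joints)

    def test_full_vector_length_150(self):
        w = self._skel_window()
        vec = visual_features(w, crop=gen_striped_crop())
        assert vec.shape == (150,)
        vec2 = visual_features(w, crop=gen_striped_crop())
        np.testing.assert_array_equal(vec, vec2)

    def test_precomputed_edge_histogram_accepted(self):
        w = self._skel_window()
        eh = np.linspace(0, 1, 80)
        vec = visual_features(w, edge_hist=eh)
        np.testing.assert_array_equal(vec[70:], eh)

    def test_no_ehd_variant_is_70(self):
        assert visual_features(self._skel_window(), use_ehd=False).shape == (70,)

    def test_missing_crop_is_error(self):
        with pytest.raises(ValueError, match="requires"):
            visual_features(self._skel_window())
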
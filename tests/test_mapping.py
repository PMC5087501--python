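import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiermotion.config import RunConfig
from hiermotion.datamodel import SensorStream
from hiermotion.mapping import (
    NoOverlapError,
    VelocitySeries,
    aggregate_to_clock,
    binarize,
    fit_thresholds,
    gyro_velocity,
    match_streams,
    ncc,
    smooth,
    threshold_objective,
)
from hiermotion.synthetic import SceneSpec, gen_scene


def _vel(values, rate=1.0, **kw):
    values = np.asarray(values, float)
    return VelocitySeries(times=np.arange(len(values)) / rate, values=values, **kw)


class TestGyroVelocity:
    def test_zero_gyro(self):
        s = SensorStream("s", np.arange(5) / 50, np.zeros((5, 3)), np.zeros((5, 3)))
        assert np.allclose(gyro_velocity(s).values, 0.0)

    def test_3_4_0_norm_is_5(self):
        g = np.array([[3.0, 4.0, 0.0]])
        s = SensorStream("s", [0.0], np.zeros((1, 3)), g)
        assert gyro_velocity(s).values[0] == pytest.approx(5.0)

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(-4, 4, size=(20, 3))
        s1 = SensorStream("s", np.arange(20) / 50, np.zeros((20, 3)), g)
        s2 = SensorStream("s", np.arange(20) / 50, np.zeros((20, 3)), g[:, [2, 0, 1]])
        np.testing.assert_allclose(gyro_velocity(s1).values, gyro_velocity(s2).values)


class TestSmoothBinarize:
    def test_length_one_filter_is_identity(self):
        v = _vel([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(smooth(v, 1).values, v.values)

    def test_spike_removed(self):
        np.testing.assert_array_equal(smooth(_vel([0, 10, 0]), 3).values, [0, 0, 0])

    def test_monotone_unchanged(self):
        v = _vel([0.0, 1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(smooth(v, 3).values, v.values)

    def test_even_filter_length_rejected(self):
        with pytest.raises(ValueError):
            smooth(_vel([0.0, 1.0]), 4)

    def test_binarize_strict_comparison(self):
        b = binarize(_vel([1.0, 1.4]), 1.3)
        assert b.values.tolist() == [0, 1]
        assert binarize(_vel([0.1, 0.2]), 1.3).values.tolist() == [0, 0]
        assert binarize(_vel([0.1, 0.2]), 0.0).values.tolist() == [1, 1]


class TestNcc:
    def test_identical_series(self):
        assert ncc(np.array([1, 0, 1]), np.array([1, 0, 1])) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ncc(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_worked_example(self):
        assert ncc(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == pytest.approx(0.5)

    def test_zero_series_undefined(self):
        assert np.isnan(ncc(np.zeros(4), np.array([1, 0, 1, 0])))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ncc(np.zeros(3), np.zeros(4))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=40))
    def test_ncc_in_unit_interval(self, pairs):
        a = np.array([p[0] for p in pairs], float)
        b = np.array([p[1] for p in pairs], float)
        value = ncc(a, b)
        assert np.isnan(value) or 0.0 <= value <= 1.0


class TestThresholdFitting:
    def test_objective_worked_example(self):
        gt = np.array([1.0, 1.0, 0.0, 0.0])
        it = np.array([1.0, 0.0, 1.0, 0.0])
        assert threshold_objective(gt, it) == pytest.approx(0.25)

    def test_grid_search_matches_brute_force(self):
        """Vectorized sweep equals an explicit double loop with the same
        tie-break (smallest T_gyro, then smallest T_image)."""
        rng = np.random.default_rng(42)
        vg = rng.uniform(0, 4, size=1000)
        vi = rng.uniform(0, 0.1, size=1000)
        cfg = RunConfig(median_filter_len=1)
        tg, ti = fit_thresholds(
            [(_vel(vg, rate=1.0, modality="gyro"), _vel(vi, rate=1.0, modality="image"))],
            cfg,
        )
        # the 1 Hz input on a 1 Hz comparison clock passes through the
        # aggregation unchanged (last sample trimmed by the half-open span)
        vg_c, vi_c = vg[:-1], vi[:-1]
        tg_grid = np.arange(0, 4.0 + 0.025, 0.05)
        ti_grid = np.arange(0, 0.1 + 0.0005, 0.001)
        best, best_obj = None, -np.inf
        for a in tg_grid:
            for b in ti_grid:
                obj = threshold_objective((vg_c > a).astype(float),
                                          (vi_c > b).astype(float))
                if obj > best_obj:
                    best, best_obj = (a, b), obj
        assert tg == pytest.approx(best[0])
        assert ti == pytest.approx(best[1])

    def test_planted_threshold_recovery(self):
        rng = np.random.default_rng(7)
        true_tg, true_ti = 1.3, 0.023
        z = rng.random(1500) < 0.5
        vg = np.where(z, rng.uniform(true_tg, 4.0, 1500),
                      rng.uniform(0.0, true_tg, 1500))
        vi = np.where(z, rng.uniform(true_ti, 0.1, 1500),
                      rng.uniform(0.0, true_ti, 1500))
        cfg = RunConfig(median_filter_len=1)
        tg, ti = fit_thresholds([(_vel(vg), _vel(vi, modality="image"))], cfg)
        assert abs(tg - true_tg) <= cfg.t_gyro_grid_step
        assert abs(ti - true_ti) <= cfg.t_image_grid_step

    def test_default_thresholds_without_fitting(self, cfg):
        assert cfg.t_gyro == 1.3
        assert cfg.t_image == 0.023

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_thresholds([])


class TestAggregation:
    def test_per_second_max(self):
        v = _vel([0.0, 3.0, 1.0, 0.5], rate=2.0)  # two samples per second
        agg = aggregate_to_clock(v, 0.0, 2.0, 1.0)
        np.testing.assert_array_equal(agg.values, [3.0, 1.0])


class TestMatchStreams:
    def test_single_pair_full_vote_share(self):
        skeletons, sensors, truth = gen_scene(
            SceneSpec(n_subjects=2, duration_s=120.0, seed=3)
        )
        res = match_streams(skeletons[:1], sensors[:1])
        valid = res.n_windows - int(res.invalid_windows[0].sum())
        assert res.assignment["track_s1"] == "s1"
        assert res.votes[0, 0] == valid > 0

    def test_two_subject_scene_recovered(self):
        skeletons, sensors, truth = gen_scene(
            SceneSpec(n_subjects=2, duration_s=900.0, overlap=0.0, seed=1)
        )
        res = match_streams(skeletons, sensors)
        assert {k: res.assignment[k] for k in truth} == truth

    def test_still_scene_undetermined(self):
        skeletons, sensors, _ = gen_scene(
            SceneSpec(n_subjects=2, duration_s=120.0, seed=2, all_idle=True)
        )
        res = match_streams(skeletons, sensors)
        assert res.invalid_windows.all()
        assert all(v is None for v in res.assignment.values())

    def test_sensor_permutation_equivariance(self):
        skeletons, sensors, truth = gen_scene(
            SceneSpec(n_subjects=3, duration_s=300.0, seed=5)
        )
        res1 = match_streams(skeletons, sensors)
        res2 = match_streams(skeletons, sensors[::-1])
        assert res1.assignment == res2.assignment
        np.testing.assert_array_equal(res1.votes, res2.votes[:, ::-1])

    def test_no_overlap_error(self):
        skeletons, sensors, _ = gen_scene(SceneSpec(duration_s=60.0, seed=0))
        shifted = SensorStream(
            "s1", sensors[0].timestamps + 1e6, sensors[0].accel, sensors[0].gyro
        )
        with pytest.raises(NoOverlapError):
            match_streams(skeletons, [shifted])
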
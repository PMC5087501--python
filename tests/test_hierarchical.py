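import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from hiermotion.grouping import Partition
from hiermotion.hierarchical import (
    HierarchicalActivityClassifier,
    MotionOnlyClassifier,
    fuse,
    make_flat_classifier,
    predict_dispatch,
)
from hiermotion.synthetic import PLANTED_PARTITION, gen_grouped_features


def _motion_only_data(seed=0, n=40):
    rng = np.random.default_rng(seed)
    labels = ("walking", "standing", "sitting", "running")
    means = np.eye(4) * 8.0
    X = np.vstack([rng.normal(means[i], 1.0, (n, 4)) for i in range(4)])
    y = np.repeat(labels, n)
    return X, y


class TestFusion:
    def test_worked_example(self):
        p_group = {"g1": 0.9, "g2": 0.1}
        p_act = {"a1": 0.2, "a2": 0.3, "a3": 0.5}
        group_of = {"a1": "g1", "a2": "g1", "a3": "g2"}
        best, scores = fuse(p_act, p_group, group_of)
        assert scores == pytest.approx({"a1": 0.18, "a2": 0.27, "a3": 0.05})
        assert best == "a2"

    def test_uniform_group_probs_reduce_to_visual_argmax(self):
        p_group = {"g1": 0.5, "g2": 0.5}
        p_act = {"a1": 0.2, "a2": 0.3, "a3": 0.5}
        group_of = {"a1": "g1", "a2": "g1", "a3": "g2"}
        best, _ = fuse(p_act, p_group, group_of)
        assert best == "a3"

    def test_one_hot_group_restricts_to_group(self):
        p_group = {"g1": 1.0, "g2": 0.0}
        p_act = {"a1": 0.1, "a2": 0.2, "a3": 0.7}
        group_of = {"a1": "g1", "a2": "g1", "a3": "g2"}
        best, scores = fuse(p_act, p_group, group_of)
        assert best == "a2"
        assert scores["a3"] == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_act, n_grp = rng.integers(2, 7), rng.integers(1, 4)
            acts = [f"a{i}" for i in range(n_act)]
            grps = [f"g{i}" for i in range(n_grp)]
            p_act = dict(zip(acts, rng.dirichlet(np.ones(n_act))))
            p_grp = dict(zip(grps, rng.dirichlet(np.ones(n_grp))))
            group_of = {a: grps[rng.integers(n_grp)] for a in acts}
            best, scores = fuse(p_act, p_grp, group_of)
            # independent exhaustive loop
            expected = {a: p_act[a] * p_grp[group_of[a]] for a in acts}
            assert scores == pytest.approx(expected)
            top = max(expected.values())
            assert scores[best] == pytest.approx(top)
            assert best == min(a for a in acts if expected[a] == top)
            # fused mass never exceeds 1
            assert sum(scores.values()) <= 1.0 + 1e-9


class TestHierarchicalClassifier:
    def test_separable_data_high_accuracy(self):
        # large class separation: both layers should resolve their task
        Xm, Xv, y = gen_grouped_features(seed=0, n_per_class=40,
                                         visual_separation=5.0)
        X = np.hstack([Xm, Xv])
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.3, random_state=0, stratify=y
        )
        clf = HierarchicalActivityClassifier(
            partition=PLANTED_PARTITION, n_motion_features=Xm.shape[1],
            random_state=0,
        ).fit(Xtr, ytr)
        assert np.mean(clf.predict(Xte) == yte) >= 0.9
        proba = clf.predict_proba(Xte)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_single_group_partition_reduces_to_visual(self):
        Xm, Xv, y = gen_grouped_features(seed=1, n_per_class=20)
        X = np.hstack([Xm, Xv])
        clf = HierarchicalActivityClassifier(
            partition=Partition.single_group(sorted(set(y))),
            n_motion_features=Xm.shape[1], random_state=1,
        ).fit(X, y)
        scores = clf.fused_scores(X[:5])
        # layer 1 is the constant-probability classifier
        p_act = clf.layer2_.predict_proba(Xv[:5])
        np.testing.assert_allclose(scores, p_act, atol=1e-12)

    def test_mismatched_rows_rejected(self):
        Xm, Xv, y = gen_grouped_features(seed=2, n_per_class=10)
        with pytest.raises(ValueError):
            HierarchicalActivityClassifier(
                partition=PLANTED_PARTITION, n_motion_features=Xm.shape[1]
            ).fit(np.hstack([Xm, Xv]), y[:-3])

    def test_label_outside_partition_rejected(self):
        Xm, Xv, y = gen_grouped_features(seed=3, n_per_class=10)
        bad = Partition((tuple(sorted(set(y)))[:-1],))  # drops one label
        with pytest.raises(ValueError, match="outside"):
            HierarchicalActivityClassifier(
                partition=bad, n_motion_features=Xm.shape[1]
            ).fit(np.hstack([Xm, Xv]), y)

    def test_fused_scores_bounded_by_one(self):
        Xm, Xv, y = gen_grouped_features(seed=4, n_per_class=20)
        X = np.hstack([Xm, Xv])
        clf = HierarchicalActivityClassifier(
            partition=PLANTED_PARTITION, n_motion_features=Xm.shape[1],
            random_state=4,
        ).fit(X, y)
        scores = clf.fused_scores(X[:20])
        assert np.all(scores >= 0)
        assert np.all(scores.sum(axis=1) <= 1.0 + 1e-9)


class TestMotionOnlyClassifier:
    def test_separable_four_class_accuracy(self):
        X, y = _motion_only_data()
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.3, random_state=0, stratify=y
        )
        clf = MotionOnlyClassifier(random_state=0).fit(Xtr, ytr)
        assert np.mean(clf.predict(Xte) == yte) >= 0.9

    def test_training_row_predicts_own_label(self):
        X, y = _motion_only_data(seed=1)
        clf = MotionOnlyClassifier(random_state=1).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_wrong_label_set_rejected(self):
        X, y = _motion_only_data()
        mask = y != "running"
        with pytest.raises(ValueError, match="exactly the labels"):
            MotionOnlyClassifier().fit(X[mask], y[mask])


@pytest.fixture(scope="module")
def models():
    Xm, Xv, y = gen_grouped_features(seed=0, n_per_class=20)
    hier = HierarchicalActivityClassifier(
        partition=PLANTED_PARTITION, n_motion_features=Xm.shape[1],
        random_state=0,
    ).fit(np.hstack([Xm, Xv]), y)
    Xmo, ymo = _motion_only_data()
    mo = MotionOnlyClassifier(random_state=0).fit(Xmo, ymo)
    return {"hierarchical": hier, "motion_only": mo}, Xm, Xv, Xmo


class TestDispatch:
    def test_visual_present_uses_hierarchy(self, models):
        md, Xm, Xv, _ = models
        out = predict_dispatch(md, Xm[0], Xv[0])
        assert out["path"] == "hierarchical"
        assert out["label"] in md["hierarchical"].classes_
        assert len(out["scores"]) == 8

    def test_visual_absent_uses_motion_only(self, models):
        md, _, _, Xmo = models
        out = predict_dispatch(md, Xmo[0], None)
        assert out["path"] == "motion_only"
        assert out["label"] in ("walking", "standing", "sitting", "running")

    def test_both_absent_is_error(self, models):
        md, *_ = models
        with pytest.raises(ValueError):
            predict_dispatch(md, None, None)


def test_flat_baseline_trains():
    Xm, Xv, y = gen_grouped_features(seed=6, n_per_class=15)
    X = np.hstack([Xm, Xv])
    clf = make_flat_classifier(1.0, 6).fit(X, y)
    assert set(clf.classes_) == set(y)
    assert clf.predict(X[:3]).shape == (3,)
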
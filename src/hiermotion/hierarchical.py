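"""Two-layer hierarchical activity classifier with probability fusion.

Layer 1 sees only motion-sensor features and predicts which *group* of
activities the window belongs to (groups come from the automatic group
selection, or are supplied). Layer 2 sees only visual features and scores
all N activities globally. The fused score of activity a with containing
group g_a is

    score(a) = P(a | image) * P(g_a | sensor)

and the predicted activity is the argmax (ties broken in canonical label
order). When the subject is outside the camera view only motion features
exist, and a single-layer classifier over the four motion-detectable
activities (walking, standing, sitting, running) takes over.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from hiermotion.config import RunConfig
from hiermotion.grouping import Partition, select_groups

MOTION_ONLY_LABELS = ("walking", "standing", "sitting", "running")


def _default_prob_classifier(C: float, random_state: int | None):
    # Platt-calibrated probabilities for the multi-class linear SVM.
    return CalibratedClassifierCV(
        SVC(kernel="linear", C=C, class_weight="balanced",
            random_state=random_state),
        method="sigmoid", cv=5, ensemble=False,
    )


class _ConstantProbClassifier(BaseEstimator, ClassifierMixin):
    """Single-class degenerate layer: P = 1 for the only group."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        return np.ones((np.asarray(X).shape[0], 1))

    def predict(self, X):
        return np.repeat(self.classes_[0], np.asarray(X).shape[0])


def fuse(
    p_activity: Mapping[str, float],
    p_group: Mapping,
    group_of: Mapping[str, object],
) -> tuple[str, dict[str, float]]:
    """Fuse layer probabilities into activity scores.

    ``p_activity`` maps activity -> P(a|image), ``p_group`` maps group
    key -> P(g|sensor) and ``group_of`` maps each activity to its group
    key. Returns the argmax activity (canonical/sorted label order breaks
    ties) and the full score table.
    """
    scores = {
        a: float(p_activity[a]) * float(p_group[group_of[a]])
        for a in sorted(p_activity)
    }
    top = max(scores.values())
    best = next(a for a in sorted(scores) if scores[a] == top)
    return best, scores


class HierarchicalActivityClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer classifier over side-by-side motion and visual features.

    ``fit``/``predict`` take ``X = [motion | visual]`` with the first
    ``n_motion_features`` columns the motion block. ``partition`` may be a
    :class:`~hiermotion.grouping.Partition`, ``None`` (run the automatic
    group selection on the motion block), or a list of label groups.

    Fitted attributes: ``classes_``, ``partition_``, ``layer1_``
    (group classifier), ``layer2_`` (activity classifier).
    """

    def __init__(
        self,
        partition: Partition | list | None = None,
        n_motion_features: int = 26,
        C: float = 1.0,
        base_estimator=None,
        selection_cv: int = 5,
        random_state: int | None = None,
    ):
        self.partition = partition
        self.n_motion_features = n_motion_features
        self.C = C
        self.base_estimator = base_estimator
        self.selection_cv = selection_cv
        self.random_state = random_state

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] <= self.n_motion_features:
            raise ValueError(
                f"X must have more than n_motion_features={self.n_motion_features} "
                f"columns (motion block then visual block); got shape {X.shape}"
            )
        return X[:, : self.n_motion_features], X[:, self.n_motion_features :]

    def _make_clf(self):
        if self.base_estimator is not None:
            return clone(self.base_estimator)
        return _default_prob_classifier(self.C, self.random_state)

    def fit(self, X, y):
        Xm, Xv = self._split(X)
        y = np.asarray(y)
        if y.shape[0] != Xm.shape[0]:
            raise ValueError("X and y must have equal row counts")
        self.classes_ = np.unique(y)
        if any(np.sum(y == c) == 0 for c in self.classes_):
            raise ValueError("every class needs at least one sample")

        if self.partition is None:
            cfg = RunConfig(cv_folds=self.selection_cv, svm_c=self.C,
                            random_seed=self.random_state or 0)
            part, _ = select_groups(Xm, y, cfg, random_state=self.random_state)
        elif isinstance(self.partition, Partition):
            part = self.partition
        else:
            part = Partition(tuple(tuple(g) for g in self.partition))
        missing = set(self.classes_) - set(part.labels)
        if missing:
            raise ValueError(f"labels outside the partition: {sorted(missing)}")
        self.partition_ = part

        membership = part.group_index()
        y_group = np.array([membership[lab] for lab in y])
        if part.m == 1:
            self.layer1_ = _ConstantProbClassifier().fit(Xm, y_group)
        else:
            self.layer1_ = self._make_clf().fit(Xm, y_group)
        self.layer2_ = self._make_clf().fit(Xv, y)
        return self

    def fused_scores(self, X) -> np.ndarray:
        """Unnormalized fused score table, columns in ``classes_`` order."""
        check_is_fitted(self, "layer2_")
        Xm, Xv = self._split(X)
        p_group = self.layer1_.predict_proba(Xm)
        group_cols = {g: j for j, g in enumerate(self.layer1_.classes_)}
        p_act = self.layer2_.predict_proba(Xv)
        act_cols = {a: j for j, a in enumerate(self.layer2_.classes_)}
        membership = self.partition_.group_index()
        scores = np.empty((Xm.shape[0], len(self.classes_)))
        for j, a in enumerate(self.classes_):
            g = membership[a]
            scores[:, j] = p_act[:, act_cols[a]] * p_group[:, group_cols[g]]
        return scores

    def predict_proba(self, X) -> np.ndarray:
        scores = self.fused_scores(X)
        totals = scores.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return scores / totals

    def predict(self, X) -> np.ndarray:
        scores = self.fused_scores(X)
        # argmax takes the first maximum; classes_ is sorted, so ties
        # resolve in canonical label order.
        return self.classes_[np.argmax(scores, axis=1)]


class MotionOnlyClassifier(BaseEstimator, ClassifierMixin):
    """Single-layer probabilistic classifier for the out-of-view fallback.

    Only the four motion-detectable activities are allowed; fitting with
    any other label set is an error.
    """

    def __init__(self, allowed_labels: tuple[str, ...] = MOTION_ONLY_LABELS,
                 C: float = 1.0, base_estimator=None,
                 random_state: int | None = None):
        self.allowed_labels = allowed_labels
        self.C = C
        self.base_estimator = base_estimator
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        present = set(np.unique(y).tolist())
        expected = set(self.allowed_labels)
        if present != expected:
            raise ValueError(
                f"motion-only model requires exactly the labels {sorted(expected)}; "
                f"got {sorted(present)}"
            )
        clf = clone(self.base_estimator) if self.base_estimator is not None else \
            _default_prob_classifier(self.C, self.random_state)
        self.clf_ = clf.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.clf_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "clf_")
        return self.clf_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "clf_")
        return self.clf_.predict_proba(np.asarray(X, dtype=float))


def make_flat_classifier(C: float = 1.0, random_state: int | None = None):
    """Single-layer baseline: one SVM on concatenated motion+visual rows."""
    return _default_prob_classifier(C, random_state)


def predict_dispatch(
    models: Mapping[str, BaseEstimator],
    motion_row: np.ndarray | None,
    visual_row: np.ndarray | None = None,
) -> dict:
    """Route one window to the hierarchical or motion-only path.

    ``models`` holds ``"hierarchical"`` and/or ``"motion_only"``. With a
    visual row present the hierarchical path is used; without one the
    motion-only fallback is used; with neither row, an error. The path
    taken is recorded in the output.
    """
    if motion_row is None and visual_row is None:
        raise ValueError("at least one of motion_row / visual_row is required")
    if visual_row is not None:
        if motion_row is None:
            raise ValueError("hierarchical path requires the motion row as well")
        model = models["hierarchical"]
        row = np.concatenate([np.asarray(motion_row), np.asarray(visual_row)])[None, :]
        scores = model.fused_scores(row)[0]
        label = model.classes_[int(np.argmax(scores))]
        return {
            "label": str(label),
            "path": "hierarchical",
            "scores": {str(c): float(s) for c, s in zip(model.classes_, scores)},
        }
    model = models["motion_only"]
    row = np.asarray(motion_row)[None, :]
    proba = model.predict_proba(row)[0]
    label = model.classes_[int(np.argmax(proba))]
    return {
        "label": str(label),
        "path": "motion_only",
        "scores": {str(c): float(p) for c, p in zip(model.classes_, proba)},
    }
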
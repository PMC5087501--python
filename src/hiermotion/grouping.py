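"""Greedy refinement search over activity-label partitions.

The first layer of the hierarchical classifier separates *groups* of
activities using motion features only. Which grouping to use is found
automatically: starting from every 2-group partition of the label set,
the search keeps the partition maximizing

    Q(C) = mean_m T(c_m) - 1/M

where T(c_m) is the cross-validated recall of group m under an M-class
SVM and the -1/M term charges each extra group, then repeatedly splits
one group of the incumbent (refinement only — labels separated in an
earlier round are never regrouped) while the best Q keeps strictly
improving and M < N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from hiermotion.config import RunConfig


@dataclass(frozen=True)
class Partition:
    """An ordered list of disjoint non-empty groups covering the labels.

    Stored canonically: labels sorted within each group, groups sorted by
    their smallest member, so equal partitions compare equal.
    """

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("partition must have at least one group")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("groups must be non-empty")
        canonical = tuple(
            sorted((tuple(sorted(g)) for g in self.groups), key=lambda g: g[0])
        )
        object.__setattr__(self, "groups", canonical)
        flat = [lab for g in self.groups for lab in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be disjoint")

    @property
    def m(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(lab for g in self.groups for lab in g))

    def group_of(self, label: str) -> int:
        for i, g in enumerate(self.groups):
            if label in g:
                return i
        raise KeyError(f"label {label!r} not in partition")

    def group_index(self) -> dict[str, int]:
        return {lab: i for i, g in enumerate(self.groups) for lab in g}

    def is_refinement_of(self, other: "Partition") -> bool:
        """True when every group of self lies inside one group of other."""
        membership = other.group_index()
        return all(
            len({membership.get(lab, -1) for lab in g}) == 1 for g in self.groups
        )

    @classmethod
    def singletons(cls, labels) -> "Partition":
        return cls(tuple((lab,) for lab in labels))

    @classmethod
    def single_group(cls, labels) -> "Partition":
        return cls((tuple(labels),))


def _two_way_splits(group: tuple[str, ...]):
    """All unordered splits of a group into two non-empty subsets.

    A group of size s has 2^(s-1) - 1 distinct splits; the first element
    is pinned to one side to avoid double counting.
    """
    head, rest = group[0], list(group[1:])
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            left = (head,) + combo
            right = tuple(x for x in rest if x not in combo)
            if right:
                yield left, right


def refine_candidates(best: Partition) -> list[Partition]:
    """All partitions splitting exactly one group of ``best`` in two.

    Refinement-only: labels placed in different groups by an earlier
    round can never be regrouped together. An all-singleton partition has
    no candidates.
    """
    out: set[Partition] = set()
    for gi, group in enumerate(best.groups):
        if len(group) < 2:
            continue
        others = best.groups[:gi] + best.groups[gi + 1 :]
        for left, right in _two_way_splits(group):
            out.add(Partition(others + (left, right)))
    return sorted(out, key=lambda p: p.groups)


def two_group_partitions(labels) -> list[Partition]:
    """Every partition of the label set into exactly 2 groups
    (2^(N-1) - 1 candidates)."""
    labels = tuple(sorted(labels))
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    return refine_candidates(Partition.single_group(labels))


def _default_classifier(cfg: RunConfig, random_state: int | None):
    return SVC(
        kernel="linear",
        C=cfg.svm_c,
        class_weight="balanced",
        random_state=random_state,
    )


def group_accuracy(
    partition: Partition,
    features: np.ndarray,
    labels: np.ndarray,
    cfg: RunConfig | None = None,
    estimator=None,
    random_state: int | None = None,
) -> np.ndarray:
    """Per-group recall T(c_m) under stratified k-fold cross-validation.

    Samples are relabeled by group id and an M-class classifier is
    cross-validated; T(c_m) is the fraction of group-m samples predicted
    as group m. A single-group partition has T = [1.0] by definition.
    """
    cfg = cfg or RunConfig()
    labels = np.asarray(labels)
    features = np.asarray(features, dtype=float)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must have equal row counts")
    membership = partition.group_index()
    unknown = set(np.unique(labels)) - set(membership)
    if unknown:
        raise ValueError(f"labels outside the partition: {sorted(unknown)}")
    y_group = np.array([membership[lab] for lab in labels])
    if partition.m == 1:
        return np.array([1.0])
    counts = np.bincount(y_group, minlength=partition.m)
    if np.any(counts == 0):
        empty = [partition.groups[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"group(s) with no samples in the data: {empty}")
    if np.any(counts < cfg.cv_folds):
        small = [partition.groups[i] for i in np.flatnonzero(counts < cfg.cv_folds)]
        raise ValueError(
            f"group(s) {small} have fewer samples than cv_folds={cfg.cv_folds}; "
            "reduce cv_folds or supply more data"
        )
    if random_state is None:
        random_state = cfg.random_seed
    clf = clone(estimator) if estimator is not None else _default_classifier(
        cfg, random_state
    )
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=random_state)
    pred = cross_val_predict(clf, features, y_group, cv=cv)
    return np.array(
        [float(np.mean(pred[y_group == m] == m)) for m in range(partition.m)]
    )


def q_score(t_values) -> float:
    """Partition score: mean per-group accuracy minus 1/M."""
    t = np.asarray(t_values, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one group accuracy")
    m = t.size
    return float(t.sum() / m - 1.0 / m)


@dataclass
class RoundRecord:
    m: int
    n_candidates: int
    best_partition: Partition
    e_max: float


@dataclass
class GroupSelectionTrace:
    rounds: list[RoundRecord] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def e_values(self) -> list[float]:
        return [r.e_max for r in self.rounds]


def select_groups(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: RunConfig | None = None,
    estimator=None,
    random_state: int | None = None,
) -> tuple[Partition, GroupSelectionTrace]:
    """Greedy group-selection search.

    Round M=2 scores every 2-group partition; each later round scores
    only the refinements (single-group splits) of the incumbent best.
    The search advances while the round's best Q strictly exceeds the
    previous round's and M < N, and returns the best partition seen.
    """
    cfg = cfg or RunConfig()
    labels = np.asarray(labels)
    label_set = tuple(sorted(np.unique(labels).tolist()))
    n = len(label_set)
    if n < 2:
        raise ValueError("need at least 2 distinct activity labels")

    def evaluate(p: Partition) -> float:
        return q_score(
            group_accuracy(p, features, labels, cfg, estimator, random_state)
        )

    trace = GroupSelectionTrace()
    m = 2
    candidates = two_group_partitions(label_set)
    incumbent: Partition | None = None
    e_incumbent = -np.inf
    e_prev = -np.inf
    while True:
        scores = [evaluate(p) for p in candidates]
        best_i = int(np.argmax(scores))  # first max: canonical-order tie-break
        round_best, e_round = candidates[best_i], scores[best_i]
        trace.rounds.append(RoundRecord(m, len(candidates), round_best, e_round))
        if e_round > e_incumbent:
            incumbent, e_incumbent = round_best, e_round
        improved = m == 2 or e_round > e_prev
        if not improved:
            trace.stop_reason = "no_improvement"
            break
        if m >= n:
            trace.stop_reason = "reached_label_count"
            break
        e_prev = e_round
        candidates = refine_candidates(round_best)
        if not candidates:
            trace.stop_reason = "no_refinements"
            break
        m += 1
    assert incumbent is not None
    return incumbent, trace


class GroupSelector(BaseEstimator):
    """Sklearn-style wrapper around :func:`select_groups`.

    Fitted attributes: ``partition_`` (the selected grouping),
    ``trace_`` (per-round candidate counts and best Q values).
    """

    def __init__(self, cv: int = 5, C: float = 1.0, base_estimator=None,
                 random_state: int | None = None):
        self.cv = cv
        self.C = C
        self.base_estimator = base_estimator
        self.random_state = random_state

    def fit(self, X, y):
        cfg = RunConfig(cv_folds=self.cv, svm_c=self.C,
                        random_seed=self.random_state or 0)
        self.partition_, self.trace_ = select_groups(
            np.asarray(X, dtype=float), np.asarray(y), cfg,
            estimator=self.base_estimator, random_state=self.random_state,
        )
        self.n_groups_ = self.partition_.m
        return self
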
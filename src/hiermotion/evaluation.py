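"""Confusion matrices, per-class precision/recall/F1 and LOSO-CV.

Rows of a confusion matrix are true labels, columns predicted labels.
Per class, precision = TP/(TP+FP), recall = TP/(TP+FN) and F1 is their
harmonic mean (0 when precision + recall = 0); the macro F1 is the
unweighted mean over classes. Leave-one-subject-out cross validation
holds each subject out in turn and sums the per-fold confusion matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Eight-activity benchmark labels: brushing, calling, computer working,
#: drinking, eating, reading, sitting, standing.
BENCHMARK_LABELS = ("BR", "CL", "CW", "DK", "ET", "RD", "ST", "SD")

#: Published summed LOSO confusion matrix for the eight-activity
#: benchmark, kept as a frozen regression fixture for the metric
#: arithmetic (rows true, columns predicted, order BENCHMARK_LABELS).
BENCHMARK_CONFUSION = np.array(
    [
        [301, 66, 0, 10, 0, 0, 1, 22],
        [16, 348, 0, 0, 2, 3, 0, 31],
        [0, 9, 355, 0, 12, 8, 16, 0],
        [1, 1, 18, 321, 37, 12, 7, 3],
        [0, 1, 15, 29, 327, 17, 11, 0],
        [0, 1, 10, 20, 30, 318, 21, 0],
        [2, 5, 14, 13, 11, 11, 335, 9],
        [7, 9, 0, 0, 0, 0, 2, 382],
    ],
    dtype=int,
)


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows = true label, columns = predicted."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for {k} labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus the macro-averaged F1.

    ``undefined_precision`` flags classes never predicted (empty column),
    where precision is taken as 0 by convention.
    """

    labels: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    undefined_precision: np.ndarray

    def rounded(self, decimals: int = 3) -> dict:
        """Reporting copy rounded to ``decimals`` (full precision kept here)."""
        return {
            "per_class": {
                lab: {
                    "precision": round(float(p), decimals),
                    "recall": round(float(r), decimals),
                    "f1": round(float(f), decimals),
                }
                for lab, p, r, f in zip(
                    self.labels, self.precision, self.recall, self.f1
                )
            },
            "macro_f1": round(float(self.macro_f1), decimals),
        }


def confusion(true_labels, pred_labels, label_order) -> ConfusionMatrix:
    """Count matrix: counts[i, j] = #(true = label i, predicted = label j)."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label sequences must have equal length")
    labels = tuple(label_order)
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = (set(true_labels) | set(pred_labels)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside label_order: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class precision, recall and harmonic-mean F1 from counts."""
    if len(cm.labels) < 2:
        raise ValueError("need at least 2 classes")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    undefined = col == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return ClassMetrics(
        labels=cm.labels,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1.mean()),
        undefined_precision=undefined,
    )


def loso_cv(
    dataset: dict,
    model_factory,
    label_order=None,
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Leave-one-subject-out cross validation with summed confusions.

    ``dataset`` maps subject id -> (X, y); ``model_factory()`` returns an
    unfitted classifier with fit/predict. Each subject is held out in
    turn, the model is trained on the rest, and the per-fold confusion
    matrices are summed. Subjects with no data are skipped with a
    warning. Fold count = number of (non-empty) subjects.
    """
    subjects = [s for s in dataset]
    if len(subjects) < 2:
        raise ValueError("LOSO-CV needs at least 2 subjects")
    if label_order is None:
        label_order = sorted(
            {lab for _, y in dataset.values() for lab in np.asarray(y)}
        )
    labels = tuple(label_order)
    total = ConfusionMatrix(np.zeros((len(labels), len(labels)), dtype=int), labels)
    for held_out in subjects:
        X_te, y_te = dataset[held_out]
        if len(np.asarray(y_te)) == 0:
            logger.warning("subject %r has no data; skipped", held_out)
            continue
        X_tr = np.vstack([dataset[s][0] for s in subjects if s != held_out])
        y_tr = np.concatenate(
            [np.asarray(dataset[s][1]) for s in subjects if s != held_out]
        )
        model = model_factory()
        model.fit(X_tr, y_tr)
        pred = model.predict(np.asarray(X_te, dtype=float))
        total = total + confusion(np.asarray(y_te), pred, labels)
    return total, class_metrics(total)
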
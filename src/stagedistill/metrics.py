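"""Confusion matrix and classification metrics with macro averaging.

One-vs-rest per-class precision, recall and F1 are computed from the
confusion matrix and averaged without class weighting (macro), the
appropriate convention for severely imbalanced test sets where minority
class behaviour matters as much as majority class behaviour.

Two macro-F1 variants are reported because they genuinely differ:

* ``macro_f1`` — the unweighted mean of per-class F1 scores (the
  dominant ecosystem convention);
* ``macro_f1_paper`` — the harmonic mean of macro precision and macro
  recall, i.e. the F1 formula applied after averaging. Published
  ablation tables for the reference task are reproducible from their
  printed precision/recall columns only under this reading, hence the
  name.

Classes with an empty prediction column get precision 0 (flagged via
``n_undefined``) rather than NaN, keeping macro averages defined on
small test sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "per_class_report",
    "f1_score",
]


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, transpose: bool = False) -> pd.DataFrame:
        """Tabular view; ``transpose=True`` prints rows = predicted,
        columns = true (the display convention some reports use)."""
        m = self.counts.T if transpose else self.counts
        axis = ("predicted", "true") if transpose else ("true", "predicted")
        frame = pd.DataFrame(m, index=list(self.classes), columns=list(self.classes))
        frame.index.name = axis[0]
        frame.columns.name = axis[1]
        return frame

    def save(self, path: str | Path, transpose: bool = False) -> None:
        self.to_frame(transpose).to_csv(path)


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_f1_paper: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    n_undefined: int
    classes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_f1_paper": self.macro_f1_paper,
            "n_undefined": self.n_undefined,
            "per_class": {
                cls: {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                }
                for cls, p, r, f in zip(
                    self.classes,
                    self.per_class_precision,
                    self.per_class_recall,
                    self.per_class_f1,
                )
            },
        }


def confusion_matrix(
    y_true: Sequence,
    y_pred: Sequence,
    classes: Sequence[str] | int,
) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #(true == i and pred == j)``.

    Labels may be class names (looked up in ``classes``) or integer
    indices; ``classes`` may be the vocabulary or just the class count.
    """
    if isinstance(classes, int):
        vocab = tuple(str(i) for i in range(classes))
    else:
        vocab = tuple(classes)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label sequences differ in length: {len(y_true)} vs {len(y_pred)}"
        )

    def to_index(labels) -> np.ndarray:
        arr = np.asarray(labels)
        if arr.dtype.kind in "iu":
            if np.any((arr < 0) | (arr >= len(vocab))):
                raise ValueError("integer label outside the class range")
            return arr
        lookup = {name: i for i, name in enumerate(vocab)}
        try:
            return np.array([lookup[str(v)] for v in labels])
        except KeyError as exc:
            raise ValueError(f"unknown label {exc.args[0]!r}") from exc

    ti = to_index(y_true)
    pi = to_index(y_pred)
    counts = np.zeros((len(vocab), len(vocab)), dtype=int)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts, vocab)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1.

    Per class c: TP = cm[c, c], FP = column sum minus TP, FN = row sum
    minus TP; macro values are the unweighted means over classes.
    """
    m = cm.counts.astype(float)
    total = m.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    pred_pos = tp + fp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        actual_pos = tp + fn
        recall = np.where(actual_pos > 0, tp / actual_pos, 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=float(f1.mean()),
        macro_f1_paper=f1_score(macro_p, macro_r),
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        n_undefined=int(np.sum(pred_pos == 0)),
        classes=cm.classes,
    )


def per_class_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """One row per class: precision, recall, F1, support, undefined flag."""
    rep = metrics_from_confusion(cm)
    support = cm.counts.sum(axis=1)
    predicted = cm.counts.sum(axis=0)
    return pd.DataFrame(
        {
            "class": list(cm.classes),
            "precision": rep.per_class_precision,
            "recall": rep.per_class_recall,
            "f1": rep.per_class_f1,
            "support": support,
            "undefined_precision": predicted == 0,
        }
    )
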
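"""Confusion matrices and the per-class metric suite.

Rows of the confusion matrix are true classes, columns predicted.  Metrics
are computed one-vs-rest per class from TP/TN/FP/FN: recall (sensitivity),
specificity, precision, F1, and a per-class binarized accuracy, all as
percentages; plus the overall accuracy 100 * trace / total.  A ratio with a
zero denominator is reported as NaN with a warning, never silently 0.  In
any binary task the recall of one class equals the specificity of the
other, since both are TN-of-the-other / all-of-that-class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # C x C, rows true, columns predicted
    class_order: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.class_order):
            raise ValueError("class_order length must match matrix size")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metric table (percent) plus overall accuracy (percent)."""

    per_class: pd.DataFrame  # index: class; columns: accuracy..precision
    overall_accuracy: float

    def to_text(self) -> str:
        """Aligned plain-text table in the report column order."""
        df = self.per_class.round(2)
        lines = [df.to_string()]
        lines.append(f"Overall accuracy: {self.overall_accuracy:.2f}%")
        return "\n".join(lines)


def confusion(
    true_labels, predicted_labels, class_order=None
) -> ConfusionMatrix:
    """Count matrix: counts[i][j] = #{true class_order[i], predicted class_order[j]}."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if class_order is None:
        class_order = tuple(np.unique(np.concatenate([t, p])))
    known = set(class_order)
    bad = [x for x in np.concatenate([t, p]) if x not in known]
    if bad:
        raise ValueError(f"labels not in class_order: {sorted(set(map(str, bad)))}")
    counts = _sk_confusion(t, p, labels=list(class_order))
    return ConfusionMatrix(counts.astype(np.int64), tuple(class_order))


_COLUMNS = ["accuracy", "specificity", "f1", "recall", "precision"]


def _safe_ratio(num: float, den: float, what: str, cls) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls!r} (zero denominator)")
        return float("nan")
    return num / den


def metrics(matrix: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class metrics, in percent, from a confusion matrix."""
    counts = np.asarray(matrix.counts, dtype=np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for i, cls in enumerate(matrix.class_order):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        # percentages are formed as 100*num/den in one expression so the
        # result is bit-identical to the textbook formula evaluated directly
        recall = _safe_ratio(100 * tp, tp + fn, "recall", cls)
        specificity = _safe_ratio(100 * tn, tn + fp, "specificity", cls)
        precision = _safe_ratio(100 * tp, tp + fp, "precision", cls)
        pr = precision * recall
        f1 = (
            float("nan")
            if not np.isfinite(pr) or (precision + recall) == 0
            else 2 * pr / (precision + recall)
        )
        accuracy = 100 * (tp + tn) / total
        rows[cls] = [accuracy, specificity, f1, recall, precision]
    per_class = pd.DataFrame.from_dict(rows, orient="index", columns=_COLUMNS)
    overall = 100.0 * np.trace(counts) / total
    return MetricsReport(per_class, float(overall))
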
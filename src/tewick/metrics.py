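"""Confusion matrix and the classifier evaluation suite.

Per-class precision, recall and F1 plus global accuracy and two
summary averages: the macro average (unweighted mean over classes) and
the support-weighted average,

    F1_w = sum_c F1_c * n_c / N,

where n_c is the number of true members of class c (its support) and N
the total.  Degenerate 0/0 ratios are reported as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise MetricsError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} class names")
        if (self.counts < 0).any():
            raise MetricsError("confusion matrix counts must be nonnegative")

    @classmethod
    def from_pairs(cls, true_idx: Sequence[int], pred_idx: Sequence[int],
                   class_names: Sequence[str]) -> "ConfusionMatrix":
        c = len(class_names)
        counts = np.zeros((c, c), dtype=np.int64)
        np.add.at(counts, (np.asarray(true_idx), np.asarray(pred_idx)), 1)
        return cls(counts, tuple(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=list(self.class_names),
                          columns=list(self.class_names))
        df.to_csv(path, sep="\t", index_label="true\\pred")


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def precision_recall_f1(cm: ConfusionMatrix,
                        class_index: int) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F1 for a class of the matrix.

    P = TP/(TP+FP) over the column, R = TP/(TP+FN) over the row,
    F1 = 2PR/(P+R); all 0/0 cases are 0.
    """
    tp = float(cm.counts[class_index, class_index])
    fp = float(cm.counts[:, class_index].sum()) - tp
    fn = float(cm.counts[class_index, :].sum()) - tp
    p = _safe_ratio(tp, tp + fp)
    r = _safe_ratio(tp, tp + fn)
    f1 = _safe_ratio(2 * p * r, p + r)
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _safe_ratio(2 * precision * recall, precision + recall)


def macro_average(per_class_values: Sequence[float]) -> float:
    """Unweighted mean over classes."""
    values = np.asarray(per_class_values, dtype=np.float64)
    if values.size == 0:
        raise MetricsError("macro average of an empty value list")
    return float(values.mean())


def weighted_average_f1(per_class_precision: Sequence[float],
                        per_class_recall: Sequence[float],
                        supports: Sequence[int]) -> float:
    """Support-weighted mean of per-class F1 computed from P and R."""
    p = np.asarray(per_class_precision, dtype=np.float64)
    r = np.asarray(per_class_recall, dtype=np.float64)
    s = np.asarray(supports, dtype=np.float64)
    if not (len(p) == len(r) == len(s)):
        raise MetricsError("precision/recall/support lengths differ")
    if (s <= 0).any():
        raise MetricsError("supports must be positive")
    f1 = np.array([f1_score(pi, ri) for pi, ri in zip(p, r)])
    return float((f1 * s).sum() / s.sum())


def accuracy(cm: ConfusionMatrix) -> float:
    """trace / total: the fraction of correctly classified sequences."""
    if cm.total == 0:
        raise MetricsError("accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate evaluation metrics of one model run."""

    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    @property
    def n_total(self) -> int:
        return int(self.support.sum())

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricsReport":
        c = len(cm.class_names)
        p = np.empty(c)
        r = np.empty(c)
        f = np.empty(c)
        for i in range(c):
            p[i], r[i], f[i] = precision_recall_f1(cm, i)
        support = cm.counts.sum(axis=1)
        degenerate = [name for name, s in zip(cm.class_names, support)
                      if s == 0]
        if degenerate:
            warnings.warn(f"classes with zero support reported as 0: "
                          f"{degenerate}", stacklevel=2)
        present = support > 0
        w = support[present] / support[present].sum()
        return cls(
            class_names=cm.class_names,
            precision=p, recall=r, f1=f, support=support,
            accuracy=accuracy(cm),
            macro_precision=macro_average(p),
            macro_recall=macro_average(r),
            macro_f1=macro_average(f),
            weighted_precision=float((p[present] * w).sum()),
            weighted_recall=float((r[present] * w).sum()),
            weighted_f1=float((f[present] * w).sum()),
        )

    def to_table(self, decimals: int = 2) -> pd.DataFrame:
        """Human-readable table; rounding applies only here."""
        rows = []
        for i, name in enumerate(self.class_names):
            rows.append([name, round(self.precision[i], decimals),
                         round(self.recall[i], decimals),
                         round(self.f1[i], decimals), int(self.support[i])])
        rows.append(["Accuracy", "", "", round(self.accuracy, decimals),
                     self.n_total])
        rows.append(["Macro avg", round(self.macro_precision, decimals),
                     round(self.macro_recall, decimals),
                     round(self.macro_f1, decimals), self.n_total])
        rows.append(["Weighted avg", round(self.weighted_precision, decimals),
                     round(self.weighted_recall, decimals),
                     round(self.weighted_f1, decimals), self.n_total])
        return pd.DataFrame(rows, columns=["Group", "Precision", "Recall",
                                           "F1-Score", "Support"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                name: {"precision": float(self.precision[i]),
                       "recall": float(self.recall[i]),
                       "f1": float(self.f1[i]),
                       "support": int(self.support[i])}
                for i, name in enumerate(self.class_names)
            },
        }
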
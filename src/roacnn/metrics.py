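"""Confusion matrix and macro-averaged multiclass evaluation metrics."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["MetricsReport", "confusion_matrix", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    sensitivity: float
    specificity: float
    f_measure: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_measure": self.f_measure,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv_line(self) -> str:
        d = self.as_dict()
        return ",".join(f"{d[k]:.6f}" for k in sorted(d))


def confusion_matrix(
    true_labels: Sequence[int], predicted_labels: Sequence[int], n_classes: int
) -> np.ndarray:
    """K x K counts; rows are true classes, columns predicted classes."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    if len(y) and (y.min() < 0 or y.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y, p), 1)
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(cm: np.ndarray, average: str = "macro") -> MetricsReport:
    """One-vs-rest metrics per class, macro-averaged (0/0 counts as 0).

    Sensitivity and recall are both the true-positive rate and therefore
    equal by construction.  ``average="micro"`` pools the per-class counts
    instead.
    """
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix has no observations")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    K = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    if average == "micro":
        precision = _safe_div(tp.sum(), tp.sum() + fp.sum())
        recall = _safe_div(tp.sum(), tp.sum() + fn.sum())
        specificity = _safe_div(tn.sum(), tn.sum() + fp.sum())
    else:
        precision = float(np.mean([_safe_div(tp[c], tp[c] + fp[c]) for c in range(K)]))
        recall = float(np.mean([_safe_div(tp[c], tp[c] + fn[c]) for c in range(K)]))
        specificity = float(np.mean([_safe_div(tn[c], tn[c] + fp[c]) for c in range(K)]))
    f_measure = _safe_div(2.0 * precision * recall, precision + recall)
    return MetricsReport(
        accuracy=float(tp.sum()) / total,
        precision=precision,
        recall=recall,
        sensitivity=recall,
        specificity=specificity,
        f_measure=f_measure,
    )
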
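"""Diagnostic performance metrics.

Caries (label 1) is the positive class. From the 2x2 confusion table:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

A metric whose denominator is zero is reported as None (with a warning),
never silently as 0. The ROC curve sweeps all distinct score thresholds
(ties grouped) and AUC is its trapezoidal area, which equals the
Mann-Whitney concordance probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion",
    "metrics_from_counts",
    "f1_score",
    "roc_auc",
    "per_position_accuracy",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return num / den


def metrics_from_counts(counts: ConfusionCounts) -> Metrics:
    acc = _ratio(counts.tp + counts.tn, counts.total, "accuracy")
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    rec = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    if prec is None or rec is None or prec + rec == 0:
        if prec is not None and rec is not None:
            warnings.warn("F1 undefined: precision + recall is zero", stacklevel=2)
        f1 = None
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return Metrics(accuracy=acc, precision=prec, recall=rec, f1=f1)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        raise ValueError("F1 undefined: precision + recall is zero")
    return 2 * precision * recall / (precision + recall)


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all distinct thresholds, and trapezoidal AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def per_position_accuracy(
    positions: Sequence[str], labels: Sequence[int], predicted: Sequence[int]
) -> dict[str, float]:
    """Accuracy within each FDI position; positions with no teeth are omitted."""
    pos = np.asarray([str(p) for p in positions])
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if not (len(pos) == len(y) == len(p)):
        raise ValueError("positions, labels and predictions must align")
    out: dict[str, float] = {}
    for code in sorted(set(pos.tolist())):
        m = pos == code
        out[str(code)] = float(np.mean(y[m] == p[m]))
    return out


@dataclass
class EvalReport:
    counts: ConfusionCounts
    metrics: Metrics
    roc: np.ndarray
    auc: float
    per_position: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "accuracy": self.metrics.accuracy,
            "precision": self.metrics.precision,
            "recall": self.metrics.recall,
            "f1": self.metrics.f1,
            "auc": self.auc,
            "roc": self.roc.tolist(),
            "per_position": self.per_position,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_predictions(
    labels: Sequence[int],
    scores: Sequence[float],
    positions: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Full report from caries probabilities: counts, metrics, ROC/AUC, per position."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    preds = (s >= threshold).astype(int)
    counts = confusion(y, preds)
    roc, auc = roc_auc(y, s)
    per_pos = (
        per_position_accuracy(positions, y, preds) if positions is not None else {}
    )
    return EvalReport(
        counts=counts,
        metrics=metrics_from_counts(counts),
        roc=roc,
        auc=auc,
        per_position=per_pos,
    )
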
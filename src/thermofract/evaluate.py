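"""Confusion matrix, diagnostic metrics, and ROC/AUC.

Fracture is the positive class throughout.  The five scalar metrics are
reported as percentages:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    accuracy    = (TP + TN) / total

A metric whose denominator is zero is reported as ``None`` ("undefined")
rather than 0 or NaN, so degenerate small-scale runs cannot silently
corrupt a report.  The ROC curve is a threshold sweep over the unique
scores and the AUC equals the Mann-Whitney statistic (ties counted 1/2),
i.e. the probability that a random fracture outscores a random sprain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "roc_auc", "evaluate_scores"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Scalar metrics in percent (None where undefined), ROC points and AUC."""

    confusion: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    roc_points: tuple[tuple[float, float], ...] = ()
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.confusion.tp, "fp": self.confusion.fp,
            "tn": self.confusion.tn, "fn": self.confusion.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "auc": self.auc,
        }
        if self.roc_points:
            d["roc_points"] = [list(p) for p in self.roc_points]
        return d

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    """2x2 tally; labels and predictions are 0 (sprain) / 1 (fracture)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Scalar diagnostic metrics from a confusion matrix, in percent."""
    return MetricsReport(
        confusion=cm,
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        npv=_pct(cm.tn, cm.tn + cm.fn),
        accuracy=_pct(cm.tp + cm.tn, cm.total),
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) by threshold sweep and the Mann-Whitney AUC."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_scores(labels: Sequence[int], fracture_probability: Sequence[float],
                    threshold: float = 0.5) -> MetricsReport:
    """Full report from positive-class probabilities.

    Prediction is fracture iff the probability strictly exceeds the
    threshold (an exact 0.5/0.5 tie resolves to non-fracture).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(fracture_probability, dtype=float)
    cm = confusion(y, (s > threshold).astype(int))
    scalar = metrics(cm)
    points, auc = roc_auc(y, s) if len(np.unique(y)) == 2 else ([], None)
    return MetricsReport(
        confusion=cm,
        sensitivity=scalar.sensitivity,
        specificity=scalar.specificity,
        ppv=scalar.ppv,
        npv=scalar.npv,
        accuracy=scalar.accuracy,
        roc_points=tuple(tuple(p) for p in points),
        auc=auc,
    )


def plot_roc(report: MetricsReport, path: str | Path) -> None:
    """Render the ROC curve to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    if report.roc_points:
        fpr, tpr = zip(*report.roc_points)
        label = f"AUC = {report.auc:.2f}" if report.auc is not None else None
        ax.plot(fpr, tpr, marker=".", label=label)
    ax.plot([0, 1], [0, 1], "--", color="gray", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if report.auc is not None:
        ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
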
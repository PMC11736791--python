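"""Evaluation metrics for regression and classification tasks.

All formulas are implemented directly (RMSE, R^2, confusion-matrix
accuracy/precision/recall, rank-statistic AUC with averaged ties, and the
relative-error curve over the 1% probability-threshold grid); the test
suite cross-checks them against independent references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "rmse", "r_squared", "accuracy", "precision_recall", "relative_error",
    "relative_error_curve", "auc_precision_recall", "MetricReport",
    "compute_report",
]


def rmse(pred, truth) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError(f"length mismatch or empty input: {pred.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def r_squared(pred, truth) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    May be negative when predictions are worse than the constant mean model.
    """
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError(f"length mismatch or empty input: {pred.shape} vs {truth.shape}")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: truth has zero variance")
    return float(1.0 - np.sum((truth - pred) ** 2) / ss_tot)


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("accuracy undefined for zero total count")
    return (tp + tn) / total


def precision_recall(probs, labels, threshold: float = 0.5) -> tuple[float, float]:
    probs, labels = np.asarray(probs, float), np.asarray(labels, float)
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def relative_error(probs, labels, epsilon: float = 0.01) -> float:
    """Pre-threshold relative error: mean |p_i - y_i| / (y_i + epsilon)."""
    probs, labels = np.asarray(probs, float), np.asarray(labels, float)
    if probs.size == 0:
        raise ValueError("relative error undefined for empty input")
    return float(np.mean(np.abs(probs - labels) / (labels + epsilon)))


def relative_error_curve(probs, labels, epsilon: float = 0.01
                         ) -> list[tuple[float, float]]:
    """Relative error on the 1% threshold grid 0.01, 0.02, ..., 1.00.

    At each threshold t the probabilities are binarised (p >= t) before the
    comparison, probing the sensitivity of the decision boundary.
    """
    probs, labels = np.asarray(probs, float), np.asarray(labels, float)
    if probs.size == 0:
        raise ValueError("relative error undefined for empty input")
    curve = []
    for t in np.arange(1, 101) / 100.0:
        hard = (probs >= t).astype(float)
        curve.append((float(t), float(np.mean(np.abs(hard - labels) / (labels + epsilon)))))
    return curve


def auc_precision_recall(probs, labels, threshold: float = 0.5
                         ) -> tuple[float | None, float, float]:
    """AUC by the rank statistic (Mann-Whitney, ties averaged) plus
    precision and recall at the decision threshold.

    AUC is None (reported as missing) when only one class is present.
    """
    probs, labels = np.asarray(probs, float), np.asarray(labels, float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    auc = None
    if n_pos > 0 and n_neg > 0:
        ranks = rankdata(probs)
        auc = float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                    / (n_pos * n_neg))
    precision, recall = precision_recall(probs, labels, threshold)
    return auc, precision, recall


@dataclass
class MetricReport:
    rmse: float | None = None
    r2: float | None = None
    auc: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    re_pre_threshold: float | None = None
    re_curve: list[tuple[float, float]] = field(default_factory=list)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse, "r2": self.r2, "auc": self.auc,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "re_pre_threshold": self.re_pre_threshold,
            "n": self.n,
        }


def compute_report(pred, truth, task: str, threshold: float = 0.5) -> MetricReport:
    """Full metric report; `pred` holds probabilities for classification."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    report = MetricReport(n=pred.size)
    if task == "regression":
        report.rmse = rmse(pred, truth)
        if truth.size > 1 and np.var(truth) > 0:
            report.r2 = r_squared(pred, truth)
    elif task == "classification":
        auc, precision, recall = auc_precision_recall(pred, truth, threshold)
        hard = pred >= threshold
        tp = int(np.sum(hard & (truth == 1)))
        tn = int(np.sum(~hard & (truth == 0)))
        fp = int(np.sum(hard & (truth == 0)))
        fn = int(np.sum(~hard & (truth == 1)))
        report.auc = auc
        report.accuracy = accuracy(tp, tn, fp, fn)
        report.precision, report.recall = precision, recall
        report.re_pre_threshold = relative_error(pred, truth)
        report.re_curve = relative_error_curve(pred, truth)
    else:
        raise ValueError(f"unknown task {task!r}")
    return report
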
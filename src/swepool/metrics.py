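"""Evaluation metrics: AUPR, AUROC, accuracy, Pearson correlation, Fmax.

Conventions are pinned because they differ between toolkits: AUROC is the
Mann-Whitney pairwise statistic (ties receive half credit), AUPR is the
average-precision (step-wise, uninterpolated) convention, and Fmax is the
best F1 over all decision thresholds with prediction rule score >= t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score)

__all__ = ["UndefinedMetricError", "MetricReport", "metric_pcc", "metric_fmax",
           "metric_binary_curves", "accuracy_top1", "make_metric_report"]

METRIC_NAMES = ("AUPR", "AUROC", "PCC", "accuracy", "Fmax")


class UndefinedMetricError(ValueError):
    """The metric is not defined on this input (e.g. a single-class label set)."""


def _binary_arrays(scores, labels):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def metric_pcc(pred, truth) -> float:
    """Pearson correlation between predictions and ground truth."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    if pred.size < 2 or pred.size != truth.size:
        raise ValueError("PCC needs two equal-length vectors of length >= 2")
    if np.std(pred) == 0 or np.std(truth) == 0:
        raise UndefinedMetricError("PCC undefined for zero-variance input")
    return float(pearsonr(pred, truth).statistic)


def metric_fmax(scores, labels) -> float:
    """Maximum F1 over all thresholds of the rule predict-positive iff score >= t.

    The threshold grid is the set of observed scores plus -inf (predict
    everything positive); this covers every achievable confusion matrix.
    """
    scores, labels = _binary_arrays(scores, labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("Fmax undefined without positive labels")
    precision, recall, _ = precision_recall_curve(labels, scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1 = f1[np.isfinite(f1)]
    return float(f1.max()) if f1.size else 0.0


def metric_binary_curves(scores, labels) -> tuple[float, float, float]:
    """(AUPR, AUROC, accuracy at threshold 0.5) for binary scores.

    AUROC equals the fraction of positive-negative pairs ranked correctly
    with half credit for ties; AUPR is step-wise average precision.
    """
    scores, labels = _binary_arrays(scores, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC/AUPR undefined with a single class")
    aupr = float(average_precision_score(labels, scores))
    auroc = float(roc_auc_score(labels, scores))
    acc = float(np.mean((scores >= 0.5).astype(int) == labels))
    return aupr, auroc, acc


def accuracy_top1(logit_rows, labels) -> float:
    """Top-1 accuracy for multiclass logits; argmax ties go to the lowest class index.

    ``labels`` are 1-based class indices.
    """
    logit_rows = np.asarray(logit_rows, dtype=np.float64)
    labels = np.asarray(labels).ravel().astype(int)
    pred = np.argmax(logit_rows, axis=1) + 1
    return float(np.mean(pred == labels))


@dataclass(frozen=True)
class MetricReport:
    """Per-seed values of one metric plus their mean and sample standard deviation."""

    metric_name: str
    per_seed: tuple
    mean: float
    std: float
    single_seed: bool = False

    def as_dict(self) -> dict:
        return {"metric": self.metric_name, "per_seed": list(self.per_seed),
                "mean": self.mean, "std": self.std, "single_seed": self.single_seed}


def make_metric_report(metric_name: str, per_seed) -> MetricReport:
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    vals = [float(v) for v in per_seed]
    if not vals:
        raise ValueError("need at least one per-seed value")
    single = len(vals) == 1
    std = 0.0 if single else float(np.std(vals, ddof=1))
    return MetricReport(metric_name=metric_name, per_seed=tuple(vals),
                        mean=float(np.mean(vals)), std=std, single_seed=single)
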
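"""Evaluation metrics: AUPRC, AUROC (binary and macro one-vs-rest), Brier.

AUPRC is average precision (step-wise interpolation, no precision envelope);
AUROC is the Mann-Whitney rank statistic with ties counted one half. Macro
variants average unweighted over the classes for which both labels occur;
classes with a single label are skipped with a warning. Computation is
delegated to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["auprc", "auroc", "brier", "MetricsReport", "aggregate_runs"]


def _macro(metric, scores: np.ndarray, labels: np.ndarray) -> float:
    values = []
    for j in range(labels.shape[1]):
        col = labels[:, j]
        if len(np.unique(col)) < 2:
            warnings.warn(f"class {j} has a single label; skipped in macro average")
            continue
        values.append(metric(col, scores[:, j]))
    if not values:
        raise ValueError("no class has both labels present")
    return float(np.mean(values))


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels length mismatch")
    return scores, labels


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=int)[labels]


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve.

    Binary: 1-D scores and labels. Multiclass: integer labels with 2-D score
    matrix (one-vs-rest macro). Multilabel: 2-D binary labels with matching
    scores (macro).
    """
    scores, labels = _check(scores, labels)
    if scores.ndim == 1:
        if len(np.unique(labels)) < 2:
            raise ValueError("AUPRC undefined for single-class labels")
        return float(average_precision_score(labels, scores))
    lab = _one_hot(labels.astype(int), scores.shape[1]) if labels.ndim == 1 else labels
    return _macro(average_precision_score, scores, lab)


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; macro one-vs-rest for 2-D)."""
    scores, labels = _check(scores, labels)
    if scores.ndim == 1:
        if len(np.unique(labels)) < 2:
            raise ValueError("AUROC undefined for single-class labels")
        return float(roc_auc_score(labels, scores))
    lab = _one_hot(labels.astype(int), scores.shape[1]) if labels.ndim == 1 else labels
    return _macro(roc_auc_score, scores, lab)


def brier(scores, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    scores, labels = _check(scores, labels)
    return float(np.mean((scores - labels.astype(float)) ** 2))


@dataclass
class MetricsReport:
    """Per-run metric rows plus mean (std) aggregates over seeds."""

    runs: pd.DataFrame  # one row per (seed, arm)
    summary: pd.DataFrame  # mean/std per arm
    n_runs: int

    def mean(self, arm: str, metric: str = "auprc") -> float:
        return float(self.summary.loc[arm, f"{metric}_mean"])

    def std(self, arm: str, metric: str = "auprc") -> float:
        return float(self.summary.loc[arm, f"{metric}_std"])


def aggregate_runs(runs: pd.DataFrame, by: str = "arm") -> MetricsReport:
    """Aggregate per-seed rows into mean/std per arm (ddof 0, as reported)."""
    metrics = [c for c in runs.columns if c not in (by, "seed")]
    agg = runs.groupby(by)[metrics].agg(["mean", lambda s: s.std(ddof=0)])
    agg.columns = [f"{m}_{'std' if name == '<lambda_0>' else name}"
                   for m, name in agg.columns]
    return MetricsReport(runs, agg, n_runs=runs["seed"].nunique())
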
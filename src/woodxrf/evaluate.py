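"""Confusion matrix and the multiclass metric suite.

Per class (one-vs-rest): sensitivity ``TP/(TP+FN)`` and specificity
``TN/(TN+FP)``; "mean" values are unweighted (macro) averages over classes.
Accuracy is ``trace/total``.  All reported as percentages.

"Optimization precision" is a summary that penalises the gap between
sensitivity and specificity; no single standard formula exists, so three
selectable definitions ship (see :data:`OPTIMIZATION_PRECISION_FORMULAS`)
and every report prints the one it used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "EvaluationReport", "confusion", "metrics"]

OPTIMIZATION_PRECISION_FORMULAS = {
    # Youden-style macro index
    "youden": "mean_sensitivity + mean_specificity - 100",
    # optimized precision (accuracy penalised by the Sn/Sp imbalance)
    "optimized_precision": "accuracy - |Sp - Sn| / (Sp + Sn) * 100",
    # per-class Sn - (100 - Sp), macro-averaged over defined classes
    "per_class_youden": "macro mean of [Sn_k - (100 - Sp_k)]",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    vocabulary: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.vocabulary)
        if counts.shape != (k, k):
            raise ConfigurationError(
                f"confusion matrix shape {counts.shape} does not match "
                f"{k}-class vocabulary"
            )
        if np.any(counts < 0):
            raise ConfigurationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Table-2-style metric suite derived from one confusion matrix."""

    accuracy_pct: float
    sensitivity_pct: dict
    specificity_pct: dict
    mean_sensitivity_pct: float
    mean_specificity_pct: float
    optimization_precision_pct: float
    optimization_precision_formula: str
    n_evaluated: int
    excluded_classes: list = field(default_factory=list)

    def per_class_table(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "sensitivity_pct": self.sensitivity_pct.get(c, np.nan),
                "specificity_pct": self.specificity_pct.get(c, np.nan),
            }
            for c in self.sensitivity_pct
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return (
            f"n={self.n_evaluated}  accuracy={self.accuracy_pct:.1f}%  "
            f"mean sensitivity={self.mean_sensitivity_pct:.1f}%  "
            f"mean specificity={self.mean_specificity_pct:.1f}%  "
            f"optimization precision={self.optimization_precision_pct:.1f}% "
            f"[{self.optimization_precision_formula}]"
        )


def confusion(true_labels, predicted_labels, vocabulary) -> ConfusionMatrix:
    """Count (true, predicted) pairs over an ordered vocabulary."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ConfigurationError("true and predicted label lengths differ")
    vocab = list(vocabulary)
    unknown = (set(true_labels.tolist()) | set(predicted_labels.tolist())) - set(vocab)
    if unknown:
        raise ConfigurationError(f"labels outside vocabulary: {sorted(unknown)}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=vocab)
    return ConfusionMatrix(counts=counts, vocabulary=tuple(vocab))


def metrics(cm: ConfusionMatrix,
            optimization_precision: str = "optimized_precision") -> EvaluationReport:
    """Compute the full metric suite from a confusion matrix.

    Classes with zero true instances have undefined sensitivity and are
    excluded from the macro means (with a logged warning).
    """
    if optimization_precision not in OPTIMIZATION_PRECISION_FORMULAS:
        raise ConfigurationError(
            f"unknown optimization-precision definition {optimization_precision!r}; "
            f"choose from {sorted(OPTIMIZATION_PRECISION_FORMULAS)}"
        )
    counts = cm.counts
    total = cm.total
    if total <= 0:
        raise ConfigurationError("empty confusion matrix")
    k = len(cm.vocabulary)
    tp = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)  # true-class totals (TP+FN)
    col = counts.sum(axis=0).astype(float)  # predicted totals (TP+FP)
    fn = row - tp
    fp = col - tp
    tn = total - row - fp

    defined = row > 0
    excluded = [cm.vocabulary[i] for i in range(k) if not defined[i]]
    if excluded:
        logger.warning("classes with no true instances excluded from macro "
                       "means: %s", excluded)

    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(defined, tp / np.where(row > 0, row, 1), np.nan) * 100
        spec = tn / (tn + fp) * 100  # tn+fp == total - row > 0 whenever row < total

    accuracy = float(tp.sum() / total * 100)
    mean_sens = float(np.nanmean(sens[defined])) if defined.any() else float("nan")
    mean_spec = float(np.mean(spec[defined])) if defined.any() else float("nan")

    if optimization_precision == "youden":
        op = mean_sens + mean_spec - 100.0
    elif optimization_precision == "optimized_precision":
        op = accuracy - abs(mean_spec - mean_sens) / (mean_spec + mean_sens) * 100.0
    else:  # per_class_youden
        vals = sens[defined] - (100.0 - spec[defined])
        op = float(np.mean(vals))

    return EvaluationReport(
        accuracy_pct=accuracy,
        sensitivity_pct={cm.vocabulary[i]: float(sens[i]) for i in range(k)
                         if defined[i]},
        specificity_pct={cm.vocabulary[i]: float(spec[i]) for i in range(k)},
        mean_sensitivity_pct=mean_sens,
        mean_specificity_pct=mean_spec,
        optimization_precision_pct=float(op),
        optimization_precision_formula=OPTIMIZATION_PRECISION_FORMULAS[
            optimization_precision
        ],
        n_evaluated=total,
        excluded_classes=excluded,
    )


def evaluate(classifier, dataset,
             optimization_precision: str = "optimized_precision"
             ) -> tuple[ConfusionMatrix, EvaluationReport]:
    """Predict a dataset and derive its confusion matrix and metric suite."""
    predicted = classifier.predict(dataset)
    cm = confusion(dataset.labels, predicted, classifier.vocabulary)
    return cm, metrics(cm, optimization_precision)
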
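"""Confusion-matrix evaluation: accuracy, precision, recall, F1 and kappa.

Scores follow the clinical-reporting convention of this problem area: the
basic scores are expressed on a 0-100 scale.  For two classes they are the
literal TP/TN/FP/FN formulas with class 1 as positive:

    accuracy  = (TP+TN) / (TP+TN+FP+FN) * 100
    recall    = TP / (TP+FN) * 100
    precision = TP / (TP+FP) * 100
    F1        = 2 * recall * precision / (recall + precision)

For K > 2 classes, precision/recall/F1 are computed one-vs-rest per class
and averaged — support-weighted by default (macro selectable) — while
accuracy is the overall fraction of correct predictions, 100*trace/total,
on both paths.  Cohen's kappa is the standard chance-corrected agreement
(p_o - p_e) / (1 - p_e) with p_e taken from the matrix marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "basic_scores",
    "cohen_kappa",
    "evaluate_predictions",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{k}" for k in range(self.n_classes)],
            columns=[f"pred_{k}" for k in range(self.n_classes)],
        )


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float | None = None
    averaging: str = "weighted"
    per_class: pd.DataFrame | None = None
    cm: ConfusionMatrix | None = None

    def to_frame(self, group: str = "", classes: str = "") -> pd.DataFrame:
        """One row in the conventional report layout."""
        row = {
            "Group": group,
            "Class": classes,
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall": self.recall,
            "F1-score": self.f1,
        }
        if self.kappa is not None:
            row["Kappa"] = self.kappa
        return pd.DataFrame([row])


def confusion_matrix(truth, pred, n_classes: int | None = None) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = #samples of true class i predicted j."""
    truth = np.asarray(truth, dtype=int).ravel()
    pred = np.asarray(pred, dtype=int).ravel()
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    if n_classes is None:
        n_classes = int(max(truth.max(initial=-1), pred.max(initial=-1))) + 1
    if truth.size and (truth.min() < 0 or pred.min() < 0 or truth.max() >= n_classes or pred.max() >= n_classes):
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (truth, pred), 1)
    return ConfusionMatrix(counts)


def _one_vs_rest(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    return tp, tn, fp, fn


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    if not ok.all():
        logger.warning("%s undefined for class(es) %s; reported as 0", what, np.nonzero(~ok)[0].tolist())
    out[ok] = num[ok] / den[ok]
    return out


def basic_scores(cm: ConfusionMatrix, averaging: str = "weighted") -> EvaluationReport:
    """Accuracy/precision/recall/F1 on the 0-100 scale.

    Binary matrices use the literal positive-class (class 1) formulas; with
    more classes, precision/recall/F1 are one-vs-rest averages (weighted by
    class support, or unweighted with ``averaging="macro"``).
    """
    if averaging not in ("weighted", "macro"):
        raise ValueError("averaging must be 'weighted' or 'macro'")
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    accuracy = 100.0 * np.trace(counts) / total
    tp, tn, fp, fn = _one_vs_rest(counts)
    prec_k = _safe_div(tp, tp + fp, "precision")
    rec_k = _safe_div(tp, tp + fn, "recall")
    f1_k = _safe_div(2 * prec_k * rec_k, prec_k + rec_k, "F1")
    per_class = pd.DataFrame(
        {
            "class": np.arange(cm.n_classes),
            "support": counts.sum(axis=1),
            "precision": 100.0 * prec_k,
            "recall": 100.0 * rec_k,
            "f1": 100.0 * f1_k,
        }
    )
    if cm.n_classes == 2:
        precision, recall, f1 = 100.0 * prec_k[1], 100.0 * rec_k[1], 100.0 * f1_k[1]
    else:
        if averaging == "weighted":
            w = counts.sum(axis=1) / total
        else:
            w = np.full(cm.n_classes, 1.0 / cm.n_classes)
        precision = 100.0 * float(prec_k @ w)
        recall = 100.0 * float(rec_k @ w)
        f1 = 100.0 * float(f1_k @ w)
    return EvaluationReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        averaging=averaging,
        per_class=per_class,
        cm=cm,
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement from the confusion-matrix marginals."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / total**2
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def evaluate_predictions(
    truth, pred, n_classes: int | None = None, averaging: str = "weighted"
) -> EvaluationReport:
    """Full report (basic scores plus kappa) straight from label arrays."""
    cm = confusion_matrix(truth, pred, n_classes)
    report = basic_scores(cm, averaging=averaging)
    report.kappa = cohen_kappa(cm)
    return report
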
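"""Imbalanced-classification metric suite.

The minority class is the positive class throughout.  From the confusion
counts TP/FP/TN/FN the suite reports precision, recall (minority TPR),
specificity (majority TNR), F1, the geometric mean

    G-mean = sqrt(recall * specificity),

the false-positive rate FP/(TN+FP), and the ROC AUC.  Overall accuracy is
deliberately absent: on imbalanced data a classifier that never predicts the
minority class scores high accuracy while being useless, which is the whole
motivation for this metric set.

Zero-denominator ratios are reported as 0.0 and flagged in ``undefined`` —
never NaN — so that averaging metric reports over many repeated splits stays
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "scalar_metrics",
           "roc_auc", "evaluate"]

METRIC_NAMES = ("precision", "recall", "specificity", "f1", "g_mean", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the minority class as positive."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    specificity: float
    f1: float
    g_mean: float
    fpr: float
    auc: float = None
    undefined: frozenset = field(default_factory=frozenset)
    auc_from_scores: bool = True

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall,
            "specificity": self.specificity, "f1": self.f1,
            "g_mean": self.g_mean, "fpr": self.fpr, "auc": self.auc,
        }


def confusion(y_true, y_pred, minority_label) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with ``minority_label`` as the positive class."""
    yt = np.asarray(y_true, dtype=object).ravel()
    yp = np.asarray(y_pred, dtype=object).ravel()
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = set(yt.tolist())
    if len(classes) > 2:
        raise ValueError("unknown label: more than two classes in y_true")
    if minority_label not in classes:
        raise ValueError(f"unknown label: minority {minority_label!r} absent")
    extra = set(yp.tolist()) - classes
    if extra:
        raise ValueError(f"unknown label in predictions: {extra}")
    pos_t = yt == minority_label
    pos_p = yp == minority_label
    return ConfusionCounts(
        TP=int((pos_t & pos_p).sum()),
        FN=int((pos_t & ~pos_p).sum()),
        FP=int((~pos_t & pos_p).sum()),
        TN=int((~pos_t & ~pos_p).sum()),
    )


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def scalar_metrics(counts: ConfusionCounts) -> MetricReport:
    """Threshold-level metrics from confusion counts (AUC left unset)."""
    undefined: set = set()
    precision = _ratio(counts.TP, counts.TP + counts.FP, "precision", undefined)
    recall = _ratio(counts.TP, counts.TP + counts.FN, "recall", undefined)
    specificity = _ratio(counts.TN, counts.TN + counts.FP, "specificity", undefined)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", undefined)
    g_mean = float(np.sqrt(recall * specificity))
    fpr = _ratio(counts.FP, counts.TN + counts.FP, "fpr", undefined)
    return MetricReport(precision=precision, recall=recall,
                        specificity=specificity, f1=f1, g_mean=g_mean,
                        fpr=fpr, auc=None, undefined=frozenset(undefined))


def roc_auc(y_true, minority_scores, minority_label) -> float:
    """Area under the ROC curve, minority class positive.

    Sweeps all distinct score thresholds (equal scores collapse), area by
    the trapezoidal rule — equivalently the tie-corrected Mann-Whitney
    probability that a random minority sample outscores a random majority
    sample.
    """
    yt = np.asarray(y_true, dtype=object).ravel()
    s = np.asarray(minority_scores, dtype=float).ravel()
    y_bin = (yt == minority_label).astype(int)
    if y_bin.min() == y_bin.max():
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y_bin, s))


def evaluate(y_true, y_pred, minority_label, minority_scores=None) -> MetricReport:
    """Full report.  AUC uses scores when given, else falls back to the hard
    labels (a two-point ROC)."""
    rep = scalar_metrics(confusion(y_true, y_pred, minority_label))
    from_scores = minority_scores is not None
    if minority_scores is None:
        minority_scores = (np.asarray(y_pred, dtype=object).ravel()
                           == minority_label).astype(float)
    try:
        auc = roc_auc(y_true, minority_scores, minority_label)
        undefined = rep.undefined
    except ValueError:
        auc = 0.0
        undefined = frozenset(rep.undefined | {"auc"})
    return MetricReport(precision=rep.precision, recall=rep.recall,
                        specificity=rep.specificity, f1=rep.f1,
                        g_mean=rep.g_mean, fpr=rep.fpr, auc=auc,
                        undefined=undefined, auc_from_scores=from_scores)
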
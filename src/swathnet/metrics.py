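"""Classification metrics: precision / recall / F1 over sample verdicts,
cohort accuracy, and ROC / AUC over pooled per-scan probabilities.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R), with TP counted
against a user-chosen positive class (tumor = 1 by convention; flipping the
positive class swaps TP↔TN and FP↔FN). Cohort accuracy is the fraction of
samples whose majority-vote verdict was correct. Zero denominators yield 0
(logged) rather than NaN. ROC sweeps every distinct score threshold, grouping
ties; AUC is the trapezoidal area, equal to the probability that a random
positive outscores a random negative (ties counted half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "precision_recall_f1",
    "f1_score",
    "cohort_accuracy",
    "roc_auc",
    "compute_report",
    "one_vs_rest_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    positive_class: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    positive_class: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "positive_class": self.positive_class,
        }
        d.update(self.extras)
        return d


def _verdict_pairs(predictions) -> list[tuple[int, int]]:
    pairs = []
    for p in predictions:
        if hasattr(p, "original_label"):
            pairs.append((int(p.original_label), int(p.predicted_label)))
        else:
            orig, pred = p
            pairs.append((int(orig), int(pred)))
    return pairs


def confusion_counts(predictions, positive_class: int) -> ConfusionCounts:
    """Tally TP/FP/FN/TN over (original, predicted) sample labels.

    Accepts SamplePrediction objects or plain (original, predicted) pairs.
    Only binary label sets are handled; multiclass goes through
    :func:`one_vs_rest_reports`.
    """
    pairs = _verdict_pairs(predictions)
    labels = {v for pair in pairs for v in pair}
    if len(labels) > 2:
        raise ValueError(
            f"{len(labels)} distinct labels found; use the one-vs-rest multiclass path"
        )
    tp = sum(o == positive_class and p == positive_class for o, p in pairs)
    fp = sum(o != positive_class and p == positive_class for o, p in pairs)
    fn = sum(o == positive_class and p != positive_class for o, p in pairs)
    tn = sum(o != positive_class and p != positive_class for o, p in pairs)
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn, positive_class=positive_class)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Exact TP/(TP+FP), TP/(TP+FN) and their harmonic mean.

    Zero denominators give 0 with a logged warning rather than NaN.
    """
    if counts.TP + counts.FP == 0:
        logger.warning("precision undefined (no positive predictions); reporting 0")
        precision = 0.0
    else:
        precision = counts.TP / (counts.TP + counts.FP)
    if counts.TP + counts.FN == 0:
        logger.warning("recall undefined (no positive samples); reporting 0")
        recall = 0.0
    else:
        recall = counts.TP / (counts.TP + counts.FN)
    return precision, recall, f1_score(precision, recall)


def cohort_accuracy(result) -> float:
    """N_predicted / N_total: fraction of samples with a correct verdict."""
    if result.n_total == 0:
        raise ValueError("empty cohort")
    return result.n_predicted / result.n_total


def roc_auc(
    scores, probs=None, positive_class: int | None = None
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) and trapezoidal AUC from per-scan scores.

    ``scores`` is either an iterable of (true_label, positive-class
    probability) pairs or an array of labels with ``probs`` given separately.
    Both classes must be present.
    """
    if probs is None:
        pairs = [(int(l), float(s)) for l, s in scores]
        y = np.array([l for l, _ in pairs])
        p = np.array([s for _, s in pairs])
    else:
        y = np.asarray(scores)
        p = np.asarray(probs, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite scores")
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    pos = int(positive_class) if positive_class is not None else int(np.max(y))
    fpr, tpr, _ = _sk_roc_curve(y, p, pos_label=pos, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def compute_report(result, positive_class: int | None = None) -> MetricsReport:
    """Full binary report for a cohort result.

    Precision/recall/F1 are computed at *sample* granularity (one verdict per
    run); ROC/AUC at *scan* granularity over the pooled per-scan
    probabilities of the positive class.
    """
    classes = np.asarray(result.classes)
    if classes.size != 2:
        raise ValueError("compute_report is binary; see one_vs_rest_reports")
    pos = int(positive_class) if positive_class is not None else int(classes.max())
    counts = confusion_counts(result.predictions, positive_class=pos)
    precision, recall, f1 = precision_recall_f1(counts)
    pos_col = int(np.flatnonzero(classes == pos)[0])
    roc_points, auc = roc_auc(result.pooled_true,
                              result.pooled_probs[:, pos_col], positive_class=pos)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=cohort_accuracy(result),
        auc=auc,
        roc_points=roc_points,
        positive_class=pos,
        extras={"n_total": result.n_total, "n_predicted": result.n_predicted,
                "counts": {"TP": counts.TP, "FP": counts.FP,
                           "FN": counts.FN, "TN": counts.TN}},
    )


def one_vs_rest_reports(result) -> dict:
    """Per-class one-vs-rest precision/recall/F1 plus macro averages.

    Sample verdicts are binarized per class; scan-level ROC uses that class's
    probability column against all others pooled.
    """
    classes = np.asarray(result.classes)
    pairs = _verdict_pairs(result.predictions)
    out: dict = {"per_class": {}, "macro": {}}
    per = []
    for j, cls in enumerate(classes):
        bin_pairs = [
            (1 if o == cls else 0, 1 if p == cls else 0) for o, p in pairs
        ]
        counts = confusion_counts(bin_pairs, positive_class=1)
        precision, recall, f1 = precision_recall_f1(counts)
        y_bin = (result.pooled_true == cls).astype(int)
        try:
            _, auc = roc_auc(y_bin, result.pooled_probs[:, j], positive_class=1)
        except ValueError:
            auc = None
        out["per_class"][int(cls)] = {
            "precision": precision, "recall": recall, "f1": f1, "auc": auc,
        }
        per.append((precision, recall, f1))
    out["macro"] = {
        "precision": float(np.mean([p for p, _, _ in per])),
        "recall": float(np.mean([r for _, r, _ in per])),
        "f1": float(np.mean([f for _, _, f in per])),
    }
    out["accuracy"] = cohort_accuracy(result)
    return out
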
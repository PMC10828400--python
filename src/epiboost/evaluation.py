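"""Binary classification metric suite and cross-dataset evaluation harness.

Thresholded metrics follow the standard confusion-matrix closed forms:

    Sn  = TP / (TP + FN)                      (sensitivity / recall)
    Pre = TP / (TP + FP)                      (precision)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any zero denominator defines that metric as 0 with an explicit warning flag
(never NaN, so batch tables stay clean). The decision rule is score >=
threshold, threshold 0.5 by default.

AUROC is the Mann–Whitney rank statistic with midrank (half-credit) tie
handling: the probability a random positive outscores a random negative.
The ROC curve itself is standard plumbing delegated to scikit-learn; its
trapezoid area agrees with the rank statistic to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from epiboost.peptide_data import EpitopeDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics_from_counts",
    "auroc",
    "roc_curve",
    "score_predictions",
    "evaluate_cross_dataset",
    "METRIC_COLUMNS",
]

# Canonical column order for printed tables (precision first).
METRIC_COLUMNS = ("pre", "sn", "f1", "acc", "mcc", "auroc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sn: float
    pre: float
    acc: float
    f1: float
    mcc: float
    auroc: float = math.nan
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_COLUMNS}


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 1 or labels.ndim != 1:
        raise ValueError("scores and labels must be 1-D")
    if len(scores) != len(labels):
        raise ValueError(
            f"length mismatch: {len(scores)} scores vs {len(labels)} labels"
        )
    if len(scores) == 0:
        raise ValueError("empty score/label vectors")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores (>= threshold is positive) and count the four cells."""
    scores, labels = _as_arrays(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, defined as 0")
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Thresholded metric closed forms from confusion counts (AUROC left NaN)."""
    if c.total <= 0:
        raise ValueError("confusion counts sum to zero")
    flags: list[str] = []
    sn = _safe_div(c.tp, c.tp + c.fn, "sn", flags)
    pre = _safe_div(c.tp, c.tp + c.fp, "pre", flags)
    acc = (c.tp + c.tn) / c.total
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1", flags)
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc", flags)
    return MetricsReport(sn=sn, pre=pre, acc=acc, f1=f1, mcc=mcc, flags=tuple(flags))


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the midrank Mann–Whitney statistic."""
    scores, labels = _as_arrays(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)  # midranks for ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points over all distinct thresholds, from (0,0) to (1,1)."""
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC curve needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr


def score_predictions(
    scores, labels, threshold: float = 0.5
) -> MetricsReport:
    """Full metric suite (thresholded metrics + AUROC) for one score vector."""
    report = metrics_from_counts(confusion(scores, labels, threshold))
    report.auroc = auroc(scores, labels)
    return report


def evaluate_cross_dataset(model, test: EpitopeDataset, provider) -> MetricsReport:
    """Score a trained model on an independent labeled set at threshold 0.5.

    Predictions use the model's *stored* antigenicity scales — nothing is
    rebuilt from the test data, mirroring honest independent validation.
    """
    from epiboost.classifier import predict  # local import to avoid a cycle

    test.require_labeled()
    scores = predict(model, test, provider)
    return score_predictions(scores, test.labels(), threshold=0.5)
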
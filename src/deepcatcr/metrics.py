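"""Binary-classification metrics for sequence- and repertoire-level evaluation.

Confusion-based metrics (accuracy, sensitivity, specificity, precision,
recall, F1, MCC) are computed directly from their defining formulas, with an
explicit convention for degenerate denominators: any ratio with a zero
denominator is reported as 0 (including MCC when any of its four factors
vanishes).  ROC curves and AUC are delegated to scikit-learn, whose AUC is
the Mann-Whitney probability of concordance with ties counted 1/2.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["compute_metrics", "roc_auc", "sensitivity_at_specificity",
           "confusion_counts"]


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_counts(labels: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> dict[str, int]:
    """TP/TN/FP/FN at the rule ``predict positive iff score >= threshold``."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(
            f"labels and scores length mismatch: {labels.shape} vs {scores.shape}")
    pred = scores >= threshold
    pos = labels == 1
    return {
        "TP": int(np.sum(pred & pos)),
        "TN": int(np.sum(~pred & ~pos)),
        "FP": int(np.sum(pred & ~pos)),
        "FN": int(np.sum(~pred & pos)),
    }


def metrics_from_counts(TP: int, TN: int, FP: int, FN: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, recall, F1 and MCC."""
    total = TP + TN + FP + FN
    acc = _ratio(TP + TN, total)
    sen = _ratio(TP, TP + FN)
    spe = _ratio(TN, TN + FP)
    precision = _ratio(TP, TP + FP)
    recall = sen
    f1 = _ratio(2.0 * precision * recall, precision + recall)
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(denom) if denom > 0 else 0.0
    return {"acc": acc, "sen": sen, "spe": spe, "precision": precision,
            "recall": recall, "f1": f1, "mcc": mcc}


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """Full metric report at a threshold, plus AUC and the confusion counts."""
    counts = confusion_counts(labels, scores, threshold)
    report = metrics_from_counts(**counts)
    labels = np.asarray(labels, dtype=int)
    report["auc"] = (roc_auc(labels, scores)[0]
                     if np.unique(labels).size == 2 else float("nan"))
    report.update(counts)
    return report


def roc_auc(labels, scores):
    """AUC plus ROC points at every distinct threshold.

    Returns ``(auc, points)`` with points as an array of
    ``(threshold, fpr, tpr)`` rows.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC analysis needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return auc, np.column_stack([thresholds, fpr, tpr])


def sensitivity_at_specificity(labels, scores, spec_floor: float) -> float:
    """Best sensitivity among thresholds whose specificity exceeds the floor.

    Screening-style operating point: the maximum sensitivity over all score
    thresholds with specificity strictly greater than ``spec_floor``
    (e.g. 0.98, 0.95, 0.90); 0.0 when no threshold qualifies.
    """
    if not 0.0 < spec_floor < 1.0:
        raise ValueError("spec_floor must be in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("needs both classes present")
    _, points = roc_auc(labels, scores)
    fpr, tpr = points[:, 1], points[:, 2]
    ok = (1.0 - fpr) > spec_floor
    return float(tpr[ok].max()) if np.any(ok) else 0.0
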
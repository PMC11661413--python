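"""Metric panel: confusion matrices, per-class metrics, AUROC, merging.

All confusion matrices are 3x3 with rows = true class and columns =
predicted class, in the fixed order (NSR, AF, PAC/PVC).  Per-class
metrics use the one-vs-rest reduction; metrics with a zero denominator
are reported as NaN ("undefined") and excluded from averages rather
than imputed.  AUROC is computed by the rank statistic (Mann-Whitney,
ties counted one half), which equals trapezoidal ROC integration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .records import Rhythm

__all__ = ["MetricReport", "confusion_from_predictions", "per_class_metrics",
           "binary_auroc", "macro_auroc", "micro_auroc", "merge_and_average",
           "collapse_to_binary_af", "report_from_predictions"]

CLASS_NAMES = ("NSR", "AF", "PACPVC")
_METRICS = ("sensitivity", "specificity", "precision", "npv", "accuracy")


@dataclass
class MetricReport:
    """Per-class metric table plus averaged AUROC values."""

    per_class: pd.DataFrame          # index = class name, columns = _METRICS
    macro_auroc: float = np.nan
    micro_auroc: float = np.nan
    n_segments: int = 0

    def class_metric(self, cls: str, metric: str) -> float:
        return float(self.per_class.loc[cls, metric])


def confusion_from_predictions(true_labels: np.ndarray,
                               probabilities: np.ndarray) -> np.ndarray:
    """3x3 counts from argmax decisions; ties break toward the lower class index."""
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] != y.size:
        raise ValueError("probabilities must be (n, 3) matching true_labels")
    pred = p.argmax(axis=1)  # numpy argmax returns the first (lowest) max index
    cm = np.zeros((3, 3), dtype=np.int64)
    np.add.at(cm, (y, pred), 1)
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity/precision/NPV/accuracy per class."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (3, 3) or (cm < 0).any():
        raise ValueError("cm must be a nonnegative 3x3 count matrix")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for i, name in enumerate(CLASS_NAMES):
        tp = int(cm[i, i])
        fn = int(cm[i].sum()) - tp
        fp = int(cm[:, i].sum()) - tp
        tn = total - tp - fn - fp
        rows[name] = {
            "sensitivity": _safe_div(tp, tp + fn),
            "specificity": _safe_div(tn, tn + fp),
            "precision": _safe_div(tp, tp + fp),
            "npv": _safe_div(tn, tn + fn),
            "accuracy": _safe_div(tp + tn, total),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(_METRICS))


def binary_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUROC with ties counted one half."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def macro_auroc(true_labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Unweighted mean of the three one-vs-rest AUROCs.

    A class with no positive or no negative examples is excluded with a
    warning (its one-vs-rest area is undefined).
    """
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=float)
    parts = []
    for cls in range(3):
        auc = binary_auroc(y == cls, p[:, cls])
        if np.isnan(auc):
            warnings.warn(f"class {CLASS_NAMES[cls]} has no positives or no "
                          "negatives; excluded from macro-AUROC", stacklevel=2)
        else:
            parts.append(auc)
    return float(np.mean(parts)) if parts else np.nan


def micro_auroc(true_labels: np.ndarray, probabilities: np.ndarray) -> float:
    """AUROC of the flattened one-vs-rest indicator/score pairs."""
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=float)
    indicators = np.concatenate([(y == cls) for cls in range(3)])
    scores = np.concatenate([p[:, cls] for cls in range(3)])
    return binary_auroc(indicators, scores)


def merge_and_average(cm_fold1: np.ndarray, cm_fold2: np.ndarray,
                      cm_nsr_pool: np.ndarray | None = None) -> dict:
    """Combine fold matrices, then average metric values with the NSR pool.

    The two fold matrices are summed entrywise and metrics computed on
    the sum; the NSR-pool matrix keeps its own metrics; the final report
    is the unweighted mean of the two metric tables wherever both are
    defined (NaNs are skipped, not imputed).  All three tables are
    returned so either reading of "averaged" stays recoverable.
    """
    merged = np.asarray(cm_fold1) + np.asarray(cm_fold2)
    merged_metrics = per_class_metrics(merged)
    out = {"cm_merged": merged, "metrics_merged": merged_metrics}
    if cm_nsr_pool is None or np.asarray(cm_nsr_pool).sum() == 0:
        out["metrics_final"] = merged_metrics
        return out
    pool_metrics = per_class_metrics(cm_nsr_pool)
    stacked = np.stack([merged_metrics.to_numpy(dtype=float),
                        pool_metrics.to_numpy(dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        final = np.nanmean(stacked, axis=0)
    out["metrics_nsr_pool"] = pool_metrics
    out["metrics_final"] = pd.DataFrame(final, index=merged_metrics.index,
                                        columns=merged_metrics.columns)
    return out


def collapse_to_binary_af(cm: np.ndarray | None = None, *,
                          true_labels: np.ndarray | None = None,
                          probabilities: np.ndarray | None = None) -> dict:
    """Fold PAC/PVC into NSR and report binary AF/non-AF performance.

    Accepts a 3x3 matrix, or labels+probabilities (which also yields the
    binary AUROC from the AF probability column).  Rows/columns of the
    2x2 result are (non-AF, AF); the AF counts are untouched by folding.
    """
    if cm is None:
        cm = confusion_from_predictions(true_labels, probabilities)
    cm = np.asarray(cm, dtype=np.int64)
    nonaf = [0, 2]
    b = np.zeros((2, 2), dtype=np.int64)
    b[0, 0] = cm[np.ix_(nonaf, nonaf)].sum()
    b[0, 1] = cm[nonaf, 1].sum()
    b[1, 0] = cm[1, nonaf].sum()
    b[1, 1] = cm[1, 1]
    tp, fn = int(b[1, 1]), int(b[1, 0])
    fp, tn = int(b[0, 1]), int(b[0, 0])
    total = tp + tn + fp + fn
    metrics = {
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "precision": _safe_div(tp, tp + fp),
        "npv": _safe_div(tn, tn + fn),
        "accuracy": _safe_div(tp + tn, total),
    }
    out = {"cm_binary": b, "metrics": metrics}
    if true_labels is not None and probabilities is not None:
        out["auroc"] = binary_auroc(np.asarray(true_labels) == Rhythm.AF,
                                    np.asarray(probabilities)[:, 1])
    return out


def report_from_predictions(predictions: pd.DataFrame) -> dict:
    """Full panel from a cross-fold prediction table.

    Expects columns segment_id, true_label, p_nsr, p_af, p_pacpvc, pool
    (fold1/fold2/nsr_only).  Fold matrices are combined, NSR-pool
    predictions from both models are summed into one pool matrix, and
    AUROCs are computed over all pooled test predictions.
    """
    prob_cols = ["p_nsr", "p_af", "p_pacpvc"]

    def cm_for(pool: str) -> np.ndarray:
        part = predictions[predictions["pool"] == pool]
        if part.empty:
            return np.zeros((3, 3), dtype=np.int64)
        return confusion_from_predictions(part["true_label"].to_numpy(),
                                          part[prob_cols].to_numpy())

    merged = merge_and_average(cm_for("fold1"), cm_for("fold2"), cm_for("nsr_only"))
    y = predictions["true_label"].to_numpy()
    p = predictions[prob_cols].to_numpy()
    report = MetricReport(per_class=merged["metrics_final"],
                          macro_auroc=macro_auroc(y, p),
                          micro_auroc=micro_auroc(y, p),
                          n_segments=int(len(predictions)))
    return {"report": report, **merged,
            "binary_af": collapse_to_binary_af(true_labels=y, probabilities=p)}
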
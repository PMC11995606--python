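"""Error metrics and classification diagnostics for PRI predictions.

Two error families are reported separately and must not be conflated:

* vector-level MAE — the mean absolute deviation between predicted and
  ground-truth per-indicator probability vectors (the training loss);
* PRI-level errors — signed per-sample differences between predicted and
  calculated PRI, summarised by the maximum absolute error, the
  peak-to-valley (PV) error (max minus min of the signed errors) and the
  mean absolute error.

Classification diagnostics treat PE as the positive class: ROC curve and
trapezoidal AUC over the per-sample PRI scores, and precision/recall/F1 at
a resolved threshold (Youden's J by default; the midpoint of the two group
means and fixed thresholds are alternatives). ROC and the confusion-based
scores are computed with scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import ValidationError

logger = logging.getLogger(__name__)

POSITIVE = "PE"

LOWER_IS_BETTER = {"vector_mae", "max_abs_error", "pv_error", "mean_abs_error"}
HIGHER_IS_BETTER = {"auc", "precision", "recall", "f1"}


def vector_mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute deviation over all samples x indicators."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValidationError("empty input")
    return float(np.abs(y - y_hat).mean())


def error_metrics(
    pri_truth: np.ndarray, pri_pred: np.ndarray
) -> tuple[float, float, float]:
    """(max absolute, peak-to-valley, mean absolute) of signed PRI errors."""
    t = np.asarray(pri_truth, dtype=float)
    p = np.asarray(pri_pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValidationError("PRI vectors must be 1-D and equal length")
    if t.size == 0:
        raise ValidationError("empty PRI vectors")
    e = p - t
    return (
        float(np.abs(e).max()),
        float(e.max() - e.min()),
        float(np.abs(e).mean()),
    )


def _binary_labels(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    y = (arr == POSITIVE).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes must be present")
    return y


def roc(labels: Sequence[str], pri: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) over the score thresholds and trapezoidal AUC."""
    y = _binary_labels(labels)
    scores = np.asarray(pri, dtype=float)
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def classify_at_threshold(
    labels: Sequence[str],
    pri: np.ndarray,
    threshold_rule: str | float = "youden",
) -> tuple[float, float, float, float]:
    """(precision, recall, f1, threshold) with PE as the positive class.

    ``threshold_rule`` is ``"youden"`` (maximise TPR - FPR; smallest
    threshold on ties), ``"midpoint"`` (mean of the two group mean PRIs) or
    a fixed numeric threshold. A sample is called positive when its score
    is >= the threshold. When no positive calls are made, precision is 0
    by convention (logged).
    """
    y = _binary_labels(labels)
    scores = np.asarray(pri, dtype=float)
    if isinstance(threshold_rule, str) and threshold_rule == "youden":
        fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
        j = tpr - fpr
        best = j.max()
        # thresholds are descending; the last maximiser is the smallest one
        threshold = float(thresholds[np.where(j == best)[0][-1]])
        threshold = min(threshold, float(scores.max()))  # strip the +inf sentinel
    elif isinstance(threshold_rule, str) and threshold_rule == "midpoint":
        threshold = float(
            0.5 * (scores[y == 1].mean() + scores[y == 0].mean())
        )
    elif isinstance(threshold_rule, (int, float)) and not isinstance(threshold_rule, bool):
        threshold = float(threshold_rule)
    else:
        raise ValidationError(f"unknown threshold rule {threshold_rule!r}")

    calls = scores >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    if tp + fp == 0:
        logger.info("no positive calls at threshold %.4g; precision set to 0", threshold)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return float(precision), float(recall), float(f1), threshold


@dataclass
class EvalReport:
    """Full error/classification summary for one model on one cohort."""

    vector_mae: float | None
    pri_errors: np.ndarray
    max_abs_error: float
    pv_error: float
    mean_abs_error: float
    roc_points: list[tuple[float, float]]
    auc: float
    precision: float
    recall: float
    f1: float
    threshold: float
    group_means: dict[str, float]
    n_samples: int
    sample_ids: list[str] | None = None
    arch: str | None = None

    def __post_init__(self) -> None:
        self.pri_errors = np.asarray(self.pri_errors, dtype=float)
        if self.pv_error < 0 or not (0.0 <= self.auc <= 1.0):
            raise ValidationError("invalid report values")
        if self.max_abs_error < self.mean_abs_error:
            raise ValidationError("max abs error cannot be below mean abs error")

    def metrics(self) -> dict[str, float]:
        out = {
            "max_abs_error": self.max_abs_error,
            "pv_error": self.pv_error,
            "mean_abs_error": self.mean_abs_error,
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.vector_mae is not None:
            out["vector_mae"] = self.vector_mae
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pri_errors"] = self.pri_errors.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        d = dict(d)
        d["roc_points"] = [tuple(p) for p in d["roc_points"]]
        return cls(**d)


def evaluate(
    labels: Sequence[str],
    pri_truth: np.ndarray,
    pri_pred: np.ndarray,
    y_truth: np.ndarray | None = None,
    y_pred: np.ndarray | None = None,
    threshold_rule: str | float = "youden",
    sample_ids: Sequence[str] | None = None,
    arch: str | None = None,
) -> EvalReport:
    """Assemble the full report from PRI vectors (and optionally the
    underlying probability matrices for the vector-level MAE)."""
    labels = np.asarray(labels, dtype=object)
    pri_truth = np.asarray(pri_truth, dtype=float)
    pri_pred = np.asarray(pri_pred, dtype=float)
    max_abs, pv, mean_abs = error_metrics(pri_truth, pri_pred)
    roc_points, auc_value = roc(labels, pri_pred)
    precision, recall, f1, threshold = classify_at_threshold(
        labels, pri_pred, threshold_rule
    )
    vmae = (
        vector_mae(y_truth, y_pred)
        if y_truth is not None and y_pred is not None
        else None
    )
    group_means = {
        label: float(pri_pred[labels == label].mean())
        for label in ("NP", "PE")
        if np.any(labels == label)
    }
    return EvalReport(
        vector_mae=vmae,
        pri_errors=pri_pred - pri_truth,
        max_abs_error=max_abs,
        pv_error=pv,
        mean_abs_error=mean_abs,
        roc_points=roc_points,
        auc=auc_value,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
        group_means=group_means,
        n_samples=int(len(pri_truth)),
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        arch=arch,
    )


def compare_models(reports: Mapping[str, EvalReport]) -> pd.DataFrame:
    """One row per architecture with every metric; best values flagged.

    All reports must score the same evaluation samples. Lower is better
    for the error family, higher for AUC/precision/recall/F1.
    """
    if not reports:
        raise ValidationError("no reports to compare")
    items = list(reports.items())
    ref = items[0][1]
    for name, rep in items[1:]:
        same_n = rep.n_samples == ref.n_samples
        same_ids = (
            rep.sample_ids == ref.sample_ids
            if rep.sample_ids is not None and ref.sample_ids is not None
            else True
        )
        if not (same_n and same_ids):
            raise ValidationError(
                f"report {name!r} scores a different sample set than "
                f"{items[0][0]!r}"
            )
    rows = {name: rep.metrics() for name, rep in items}
    table = pd.DataFrame(rows).T
    table.index.name = "arch"
    flags = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col in table.columns:
        if col in LOWER_IS_BETTER:
            flags[col] = table[col] == table[col].min()
        elif col in HIGHER_IS_BETTER:
            flags[col] = table[col] == table[col].max()
    flagged = table.copy()
    for col in table.columns:
        flagged[col] = [
            f"{v:.4g}*" if best else f"{v:.4g}"
            for v, best in zip(table[col], flags[col])
        ]
    flagged.attrs["best_flags"] = flags
    return flagged
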
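"""Evaluation metric suite.

Classification: F1 at a fixed threshold, best-F1 over a threshold scan,
AUC, MCC and accuracy.  Regression: Pearson r, Spearman rho (average
ranks), and R^2.  Undefined quantities (AUC on single-class labels,
correlations on zero-variance targets) are reported as ``None`` rather
than a sentinel number; the MCC 0/0 case is defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)

__all__ = ["MetricReport", "classification_metrics", "regression_metrics", "best_f1_scan"]


@dataclass
class MetricReport:
    f1: Optional[float] = None
    best_f1: Optional[float] = None
    auc: Optional[float] = None
    mcc: Optional[float] = None
    accuracy: Optional[float] = None
    pearson_r: Optional[float] = None
    spearman_rho: Optional[float] = None
    r2: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("f1", "best_f1", "auc", "accuracy"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("mcc", "pearson_r", "spearman_rho"):
            v = getattr(self, name)
            if v is not None and not (-1.0 - 1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.r2 is not None and self.r2 > 1.0 + 1e-12:
            raise ValueError(f"r2={self.r2} exceeds 1")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("f1", "best_f1", "auc", "mcc", "accuracy", "pearson_r", "spearman_rho", "r2")
            if getattr(self, k) is not None
        }


def best_f1_scan(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Max F1 over thresholds: midpoints of sorted unique scores plus +/-inf."""
    uniq = np.unique(y_score)
    thresholds = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else [], [np.inf])
    )
    best = 0.0
    for t in thresholds:
        pred = (y_score > t).astype(int)
        best = max(best, f1_score(y_true, pred, zero_division=0))
    return float(best)


def classification_metrics(
    y_true: Sequence[float], y_score: Sequence[float], threshold: float = 0.5
) -> MetricReport:
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("length mismatch")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be 0/1")
    pred = (y_score >= threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y_true, pred))  # 0/0 convention -> 0
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, y_score))
    return MetricReport(
        f1=float(f1_score(y_true, pred, zero_division=0)),
        best_f1=best_f1_scan(y_true, y_score),
        auc=auc,
        mcc=mcc,
        accuracy=float(accuracy_score(y_true, pred)),
    )


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if len(y_true) < 3:
        raise ValueError("need at least 3 points")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    if ss_tot == 0.0:
        return MetricReport(pearson_r=None, spearman_rho=None, r2=None)
    r2 = 1.0 - ss_res / ss_tot
    if np.std(y_pred) == 0.0:
        r = rho = None
    else:
        r = float(pearsonr(y_true, y_pred).statistic)
        rho = float(spearmanr(y_true, y_pred).statistic)
    return MetricReport(pearson_r=r, spearman_rho=rho, r2=min(r2, 1.0))
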
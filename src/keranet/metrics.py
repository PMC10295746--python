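"""Binary classification metrics and k-fold aggregation.

AK (the disease class) is the positive class everywhere: ``y = 1`` means
AK and ``p`` is the predicted AK probability. The implemented quantities
are accuracy, binary cross-entropy, sensitivity (true positive rate),
specificity (true negative rate), the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the ROC curve with its area computed in the Mann–Whitney pair-counting
form (ties between a positive and a negative score count 0.5). Fold-level
values are aggregated as mean ± 95% confidence-interval half-width using
the Student-t quantile on k−1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

EPS = 1e-7


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero (e.g. no positives)."""


@dataclass(frozen=True)
class PredictionRecord:
    """One validation prediction: true label and predicted AK probability."""

    y: int
    p: float

    def __post_init__(self):
        if self.y not in (0, 1):
            raise ValueError("y must be 0 (NAK) or 1 (AK)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSummary:
    """Per-fold values of one metric with mean and 95% CI half-width."""

    name: str
    values: tuple[float, ...]
    mean: float
    ci_half_width: float


def _as_arrays(y, p=None):
    if p is None:  # sequence of PredictionRecord
        records = list(y)
        y = np.array([r.y for r in records], dtype=int)
        p = np.array([r.p for r in records], dtype=float)
    else:
        y = np.asarray(y, dtype=int)
        p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise ValueError("no predictions given")
    return y, p


def confusion(y, p=None, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities (p ≥ threshold → predicted AK) and count."""
    y, p = _as_arrays(y, p)
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero total")
    return (c.TP + c.TN) / c.total


def cross_entropy(y, p=None) -> float:
    """Mean binary cross-entropy −[y ln p̃ + (1−y) ln(1−p̃)], p̃ ε-clipped."""
    y, p = _as_arrays(y, p)
    pt = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(pt) + (1 - y) * np.log(1.0 - pt)))


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN): fraction of actual AK cases identified."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): fraction of actual NAK cases identified."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    return c.TN / (c.TN + c.FP)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty."""
    if c.total == 0:
        raise UndefinedMetricError("MCC undefined for zero total")
    tp, fp, tn, fn = (float(c.TP), float(c.FP), float(c.TN), float(c.FN))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom_sq)


def roc_auc(y, p=None) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    Returns ``(points, auc)`` where ``points`` is an array of (FPR, TPR)
    pairs at every distinct threshold (including the endpoints (0,0) and
    (1,1)) and ``auc`` is the Mann–Whitney statistic: the fraction of
    (positive, negative) pairs where the positive outscores the negative,
    ties counted one half. The trapezoidal area under the returned points
    equals this value.
    """
    y, p = _as_arrays(y, p)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC/AUC needs both classes present")

    ranks = stats.rankdata(p)  # average ranks handle ties as 0.5
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    # cumulative counts at each distinct threshold (descending scores)
    distinct = np.nonzero(np.diff(p_sorted))[0]
    cuts = np.concatenate([distinct, [len(p_sorted) - 1]])
    tp = np.cumsum(y_sorted == 1)[cuts]
    fp = np.cumsum(y_sorted == 0)[cuts]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


def aggregate_folds(values: Sequence[float], name: str = "metric") -> MetricSummary:
    """Mean ± 95% CI half-width (Student-t, k−1 df, sample sd) over folds."""
    values = tuple(float(v) for v in values)
    k = len(values)
    if k < 2:
        raise ValueError("aggregation needs at least two fold values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    t = float(stats.t.ppf(0.975, k - 1))
    return MetricSummary(name=name, values=values, mean=mean,
                         ci_half_width=t * sd / np.sqrt(k))


def evaluate_predictions(y, p=None, threshold: float = 0.5) -> dict[str, float]:
    """All scalar metrics of one prediction set, as a flat dict."""
    y, p = _as_arrays(y, p)
    c = confusion(y, p, threshold=threshold)
    _, auc = roc_auc(y, p)
    return {
        "accuracy": accuracy(c),
        "loss": cross_entropy(y, p),
        "auc": auc,
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "mcc": mcc(c),
    }
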
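"""ROC construction and threshold metrics for binary pathogenicity labels.

Conventions
-----------
* Predict positive iff score >= tau (scores already oriented higher = positive).
* The ROC has one vertex per distinct score value plus (0,0) and (1,1)
  sentinels; a tie group therefore appears as a single vertex and the segment
  across it is a diagonal chord. With that convention the trapezoidal area
  under the curve equals the Mann-Whitney statistic with half credit for ties,
  AUC = P(s(X+) > s(X-)) + 0.5 P(s(X+) = s(X-)), exactly.
* The truncated AUC integrates the curve over FPR in [0, cap] (linear
  interpolation at the cap) and normalizes by the cap, the maximum possible
  area in that strip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import LabeledScores

__all__ = [
    "RocCurve",
    "ThresholdMetrics",
    "roc_curve",
    "auc",
    "truncated_auc",
    "threshold_metrics",
]


@dataclass(frozen=True)
class RocCurve:
    """Ordered (fpr, tpr, threshold) triples, (0,0) first and (1,1) last.

    The first point is a (0,0) sentinel at threshold +inf; every distinct
    score value contributes one vertex (threshold = the smallest score still
    called positive there), and the vertex at the minimum score is always
    (1,1), closing the curve.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fpr", "tpr", "thresholds"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.fpr) == len(self.tpr) == len(self.thresholds)):
            raise ValueError("fpr, tpr, thresholds must have equal length")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def interpolate_tpr(self, fpr_value: float) -> float:
        """TPR of the polyline at a given FPR (linear between vertices)."""
        return float(np.interp(fpr_value, self.fpr, self.tpr))


def roc_curve(scores: LabeledScores) -> RocCurve:
    """Empirical ROC swept over every distinct score value."""
    scores.require_both_classes()
    s, y = scores.scores, scores.labels
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]

    # vertex at the end of each tie group (last occurrence of a distinct score)
    distinct_end = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    n_pos = tp_cum[-1]
    n_neg = fp_cum[-1]

    # (0,0) sentinel at +inf; the vertex at the minimum score is always (1,1)
    tpr = np.r_[0.0, tp_cum[distinct_end] / n_pos]
    fpr = np.r_[0.0, fp_cum[distinct_end] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct_end]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(scores: LabeledScores) -> float:
    """Tie-aware Mann-Whitney AUC via mid-ranks.

    Equals the trapezoidal area under :func:`roc_curve` to numerical
    precision (the chord convention makes the two identical).
    """
    scores.require_both_classes()
    ranks = stats.rankdata(scores.scores)  # average ranks handle ties
    n_pos = scores.n_positive
    n_neg = scores.n_negative
    rank_sum_pos = float(ranks[scores.labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def truncated_auc(scores: LabeledScores, fpr_cap: float = 0.2) -> float:
    """Normalized area under the ROC restricted to FPR in [0, fpr_cap]."""
    if not 0.0 < fpr_cap <= 1.0:
        raise ValueError("fpr_cap must be in (0, 1]")
    curve = roc_curve(scores)
    inside = curve.fpr <= fpr_cap
    fpr = np.r_[curve.fpr[inside], fpr_cap]
    tpr = np.r_[curve.tpr[inside], curve.interpolate_tpr(fpr_cap)]
    return float(np.trapezoid(tpr, fpr)) / fpr_cap


def _mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        warnings.warn("degenerate confusion matrix (zero row/column); MCC set to 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion-matrix rates and likelihood ratios at a fixed threshold.

    lr_plus = TPR/FPR and lr_minus = (1-TPR)/(1-FPR); a zero denominator
    yields +inf (flagged by :attr:`has_infinite`), never an exception.
    DOR = lr_plus/lr_minus is the diagnostic odds ratio.
    """

    tau: float
    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    mcc: float
    lr_plus: float
    lr_minus: float
    dor: float

    @property
    def has_infinite(self) -> bool:
        return any(math.isinf(v) for v in (self.lr_plus, self.lr_minus, self.dor))


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.inf if num > 0 else (math.nan if num == 0 else math.inf)
    return num / den


def threshold_metrics(scores: LabeledScores, tau: float) -> ThresholdMetrics:
    """Confusion matrix and derived rates for the rule score >= tau."""
    scores.require_both_classes()
    pred = scores.scores >= tau
    y = scores.labels == 1
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))

    tpr = tp / (tp + fn)
    fpr = fp / (fp + tn)
    lr_plus = _ratio(tpr, fpr)
    lr_minus = _ratio(1.0 - tpr, 1.0 - fpr)
    if math.isnan(lr_minus):
        lr_minus = 0.0  # TPR = FPR = 1: no negative predictions at all
    if lr_minus == 0.0:
        dor = math.inf if lr_plus > 0 else math.nan
    else:
        dor = lr_plus / lr_minus
    return ThresholdMetrics(
        tau=tau, tp=tp, fp=fp, fn=fn, tn=tn,
        tpr=tpr, fpr=fpr, tnr=1.0 - fpr, fnr=1.0 - tpr,
        mcc=_mcc_from_counts(tp, fp, fn, tn),
        lr_plus=lr_plus, lr_minus=lr_minus, dor=dor,
    )
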
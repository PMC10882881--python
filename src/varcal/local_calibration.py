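"""Windowed estimation of the local posterior and local likelihood ratio.

The local positive likelihood ratio lr+(s) = p(s|pathogenic)/p(s|benign) is
the slope of the ROC curve at score s. It cannot be read off a finite sample
directly, so the posterior P(Y=1 | score = s) is estimated as the pathogenic
fraction inside a window [s - eps, s + eps], with

* eps = 5% of the score range, the range taken as the 5th-95th percentile
  interval to blunt the influence of outliers, and
* a stability floor: each window must hold at least min(ceil(0.10 n), 50)
  items; windows short of that are grown outward by nearest neighbors.

The lr+ at each grid point then follows from the posterior-odds identity
lr+(s) = [P/(1-P)] * [(1-alpha_D)/alpha_D] under the test-set prior alpha_D;
lr+ is class-prior independent, the posterior is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .data_io import AnalysisConfig, LabeledScores

__all__ = [
    "LocalCalibrationCurve",
    "required_window_count",
    "local_posterior",
    "local_lr_plus",
    "smooth_curve",
]


@dataclass(frozen=True)
class LocalCalibrationCurve:
    """Per-grid-point local posterior and lr+, with the windows actually used."""

    grid: np.ndarray
    posterior_test: np.ndarray
    lr_plus: np.ndarray
    window_halfwidth: np.ndarray
    window_count: np.ndarray
    test_prior: float
    epsilon: float

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name in ("posterior_test", "lr_plus", "window_halfwidth", "window_count"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match grid")
        if not 0.0 < self.test_prior < 1.0:
            raise ValueError("test_prior must be in (0, 1)")

    def __len__(self) -> int:
        return len(self.grid)


def required_window_count(n: int, config: AnalysisConfig) -> int:
    """Minimum items per window: at least 10% of the set, capped at 50."""
    return min(math.ceil(config.window_min_fraction * n), config.window_max_count)


def local_lr_plus(posterior_test, test_prior: float) -> np.ndarray:
    """Posterior odds divided by test-prior odds; posterior 1 maps to +inf.

    Accepts either a :class:`LocalCalibrationCurve` (its ``posterior_test``
    is used) or an array of posterior values.
    """
    if isinstance(posterior_test, LocalCalibrationCurve):
        posterior_test = posterior_test.posterior_test
    if not 0.0 < test_prior < 1.0:
        raise ValueError("test prior alpha_D must be in the open interval (0, 1)")
    p = np.asarray(posterior_test, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("posterior values must lie in [0, 1]")
    prior_odds = test_prior / (1.0 - test_prior)
    with np.errstate(divide="ignore"):
        out = np.where(p < 1.0, p / (1.0 - p), np.inf) / prior_odds
    return out


def local_posterior(
    scores: LabeledScores,
    grid: Optional[np.ndarray] = None,
    config: Optional[AnalysisConfig] = None,
) -> LocalCalibrationCurve:
    """Windowed local posterior (and lr+) at each grid point.

    The default grid is the sorted distinct observed scores, so that
    evidence-level thresholds land on reachable score values.
    """
    config = config or AnalysisConfig()
    scores.require_both_classes()
    n = len(scores)
    if n < 10:
        raise ValueError("local calibration needs n >= 10")
    required = required_window_count(n, config)

    order = np.argsort(scores.scores, kind="mergesort")
    s_sorted = scores.scores[order]
    y_sorted = scores.labels[order].astype(float)
    label_prefix = np.r_[0.0, np.cumsum(y_sorted)]

    p5, p95 = np.percentile(s_sorted, [5.0, 95.0])
    eps = config.window_fraction * (p95 - p5)

    if grid is None:
        grid = np.unique(s_sorted)
    else:
        grid = np.asarray(grid, dtype=float)

    lo = np.searchsorted(s_sorted, grid - eps, side="left")
    hi = np.searchsorted(s_sorted, grid + eps, side="right")

    counts = hi - lo
    halfwidth = np.full(len(grid), eps, dtype=float)
    for k in np.nonzero(counts < required)[0]:
        a, b = int(lo[k]), int(hi[k])  # expand [a, b) by nearest neighbors
        g = grid[k]
        while b - a < required:
            left_d = g - s_sorted[a - 1] if a > 0 else np.inf
            right_d = s_sorted[b] - g if b < n else np.inf
            if left_d <= right_d:  # ties broken toward the lower score
                a -= 1
            else:
                b += 1
        lo[k], hi[k] = a, b
        counts[k] = b - a
        halfwidth[k] = max(eps, g - s_sorted[a], s_sorted[b - 1] - g)

    posterior = (label_prefix[hi] - label_prefix[lo]) / counts
    test_prior = (config.test_prior_override
                  if config.test_prior_override is not None
                  else scores.test_prior)
    return LocalCalibrationCurve(
        grid=grid,
        posterior_test=posterior,
        lr_plus=local_lr_plus(posterior, test_prior),
        window_halfwidth=halfwidth,
        window_count=counts.astype(int),
        test_prior=test_prior,
        epsilon=float(eps),
    )


def _pava_nondecreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares isotonic (non-decreasing) fit by pool-adjacent-violators."""
    n = len(y)
    level = list(y.astype(float))
    weight = list(w.astype(float))
    size = [1] * n
    i = 0
    while i < len(level) - 1:
        if level[i] <= level[i + 1]:
            i += 1
            continue
        tw = weight[i] + weight[i + 1]
        level[i] = (level[i] * weight[i] + level[i + 1] * weight[i + 1]) / tw
        weight[i] = tw
        size[i] += size[i + 1]
        del level[i + 1], weight[i + 1], size[i + 1]
        if i > 0:
            i -= 1
    return np.repeat(level, size)


def smooth_curve(curve: LocalCalibrationCurve, method: str = "isotonic") -> LocalCalibrationCurve:
    """Smoothed copy of a calibration curve for display.

    ``isotonic`` enforces a non-decreasing lr+ in score (window counts used
    as weights); ``moving_average`` applies a centered 5-point mean;
    ``none`` returns an identical curve. The raw curve is never modified.
    """
    if method == "none":
        return replace(curve)
    if method == "isotonic":
        finite = np.isfinite(curve.lr_plus)
        lr = curve.lr_plus.copy()
        lr[finite] = _pava_nondecreasing(curve.lr_plus[finite],
                                         curve.window_count[finite].astype(float))
        # re-impose monotonicity across saturated (+inf) points
        lr = np.maximum.accumulate(lr)
    elif method == "moving_average":
        k = 5
        pad = k // 2
        padded = np.r_[np.repeat(curve.lr_plus[0], pad), curve.lr_plus,
                       np.repeat(curve.lr_plus[-1], pad)]
        lr = np.convolve(padded, np.ones(k) / k, mode="valid")
    else:
        raise ValueError("method must be one of {'isotonic', 'moving_average', 'none'}")

    prior_odds = curve.test_prior / (1.0 - curve.test_prior)
    odds = lr * prior_odds
    with np.errstate(invalid="ignore"):
        posterior = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
    return replace(curve, lr_plus=lr, posterior_test=posterior)
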
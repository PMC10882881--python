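"""Bootstrap confidence intervals and permutation p-values.

Case resampling with replacement (n out of n), percentile intervals at the
configured level, 1000 iterations by default. Binary-metric resamples that
lose a class are redrawn (capped) and counted. The "random model" null for
p-values is a permutation null: labels are shuffled for binary data, the
observed values for continuous data, which centers AUC at 0.5 and
correlations at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .data_io import ContinuousPairs, LabeledScores

__all__ = ["BootstrapResult", "bootstrap_metric", "null_pvalue"]

Dataset = Union[LabeledScores, ContinuousPairs]


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    level: float
    iterations: int
    seed: int
    n_degenerate: int = 0
    p_value: Optional[float] = None

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low


def _needs_both_classes(data: Dataset) -> bool:
    return isinstance(data, LabeledScores)


def _is_degenerate(data: Dataset, idx: np.ndarray) -> bool:
    if isinstance(data, LabeledScores):
        labels = data.labels[idx]
        return labels.min() == labels.max()
    return False


def _stratified_indices(data: LabeledScores, rng: np.random.Generator) -> np.ndarray:
    pos = np.nonzero(data.labels == 1)[0]
    neg = np.nonzero(data.labels == 0)[0]
    return np.r_[rng.choice(pos, size=len(pos), replace=True),
                 rng.choice(neg, size=len(neg), replace=True)]


def bootstrap_metric(
    data: Dataset,
    metric: Callable[[Dataset], float],
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    *,
    stratified: bool = False,
    max_redraw: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap CI for any metric defined on the data.

    Plain case resampling by default; ``stratified=True`` resamples within
    each label class (binary data only), which never produces a degenerate
    resample. Deterministic for a given seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    point = float(metric(data))

    values = np.empty(iterations)
    n_degenerate = 0
    for b in range(iterations):
        if stratified and isinstance(data, LabeledScores):
            idx = _stratified_indices(data, rng)
        else:
            idx = rng.integers(0, n, size=n)
            if _needs_both_classes(data):
                redraws = 0
                while _is_degenerate(data, idx) and redraws < max_redraw:
                    idx = rng.integers(0, n, size=n)
                    redraws += 1
                n_degenerate += redraws
                if redraws == max_redraw:
                    raise ValueError(
                        "could not draw a resample containing both classes; "
                        "use stratified=True"
                    )
        values[b] = metric(data.take(idx))

    if n_degenerate > 0.5 * iterations:
        raise ValueError(
            f"{n_degenerate} degenerate resamples over {iterations} iterations; "
            "use stratified=True"
        )
    tail = (1.0 - level) / 2.0
    ci_low, ci_high = np.quantile(values, [tail, 1.0 - tail])
    if not ci_low <= point <= ci_high:
        warnings.warn("percentile interval excludes the point estimate",
                      RuntimeWarning, stacklevel=2)
    return BootstrapResult(point=point, ci_low=float(ci_low), ci_high=float(ci_high),
                           level=level, iterations=iterations, seed=seed,
                           n_degenerate=n_degenerate)


def _permute(data: Dataset, rng: np.random.Generator) -> Dataset:
    if isinstance(data, LabeledScores):
        return LabeledScores(data.item_ids, data.scores,
                             rng.permutation(data.labels), flipped=data.flipped)
    return ContinuousPairs(data.item_ids, data.predicted,
                           rng.permutation(data.observed))


def null_pvalue(
    data: Dataset,
    metric: Callable[[Dataset], float],
    iterations: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value against the random-model null.

    p = (1 + #{null >= observed}) / (iterations + 1); the add-one keeps the
    p-value achievable and strictly positive.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(metric(data))
    exceed = 0
    for _ in range(iterations):
        if float(metric(_permute(data, rng))) >= observed:
            exceed += 1
    return (1 + exceed) / (iterations + 1)
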
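"""Agreement metrics for continuous targets.

R-squared here is the fraction of target variance explained relative to the
trivial mean predictor (it can be negative and is not the square of Pearson's
r unless the predictor is the least-squares fit). Kendall's tau uses the
tau-b tie correction: the raw concordant-minus-discordant sign sum divided by
the geometric mean of the tie-corrected pair counts on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ContinuousPairs

__all__ = [
    "ContinuousMetricSet",
    "r_squared",
    "rmse",
    "pearson",
    "spearman",
    "kendall_tau_b",
    "compute_all",
]


@dataclass(frozen=True)
class ContinuousMetricSet:
    r_squared: float
    rmse: float
    pearson_r: float
    spearman: float
    kendall_tau_b: float

    def as_dict(self) -> dict:
        return {
            "r2": self.r_squared,
            "rmse": self.rmse,
            "pearson": self.pearson_r,
            "spearman": self.spearman,
            "kendall_tau_b": self.kendall_tau_b,
        }


def r_squared(pairs: ContinuousPairs) -> float:
    """1 - SS_res/SS_tot; negative when worse than predicting the mean."""
    y = pairs.observed
    f = pairs.predicted
    if len(y) < 2:
        raise ValueError("r_squared needs n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical; R^2 undefined")
    ss_res = float(np.sum((f - y) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(pairs: ContinuousPairs) -> float:
    return float(np.sqrt(np.mean((pairs.predicted - pairs.observed) ** 2)))


def _check_corr_input(pairs: ContinuousPairs) -> None:
    if len(pairs) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(pairs.predicted) == 0 or np.ptp(pairs.observed) == 0:
        raise ValueError("correlation undefined when one side is constant")


def pearson(pairs: ContinuousPairs) -> float:
    _check_corr_input(pairs)
    return float(stats.pearsonr(pairs.predicted, pairs.observed).statistic)


def spearman(pairs: ContinuousPairs) -> float:
    """Pearson correlation of mid-ranks (average ranks for ties)."""
    _check_corr_input(pairs)
    return float(stats.spearmanr(pairs.predicted, pairs.observed).statistic)


def kendall_tau_b(pairs: ContinuousPairs) -> float:
    """Tie-corrected Kendall rank correlation.

    Equals the plain concordance statistic when there are no ties; raises
    when either side is fully tied (zero denominator).
    """
    f, y = pairs.predicted, pairs.observed
    if len(f) < 2:
        raise ValueError("kendall_tau_b needs n >= 2")
    if np.ptp(f) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall_tau_b undefined when one side is fully tied")
    return float(stats.kendalltau(f, y, variant="b").statistic)


def compute_all(pairs: ContinuousPairs) -> ContinuousMetricSet:
    return ContinuousMetricSet(
        r_squared=r_squared(pairs),
        rmse=rmse(pairs),
        pearson_r=pearson(pairs),
        spearman=spearman(pairs),
        kendall_tau_b=kendall_tau_b(pairs),
    )
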
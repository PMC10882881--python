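"""Correction of class-prior-dependent measures to a target-population prior.

TPR, FPR and the local lr+ depend only on the class-conditional score
distributions and transfer between populations unchanged. PPV, PPP, the
posterior rho(s) and the relative risk RR(s) depend on the class prior and
must be recomputed at the target prior alpha:

    PPV(tau) = alpha*TPR / (alpha*TPR + (1-alpha)*FPR)
    rho(s)   = alpha*lr+(s) / (alpha*(lr+(s) - 1) + 1)
    RR(s)    = lr+(s) / (alpha*(lr+(s) - 1) + 1)      (= rho(s)/alpha)

The correction is exact under the assumption that test set and target
population share class-conditional score distributions and differ only in
their priors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import LabeledScores
from .evidence_model import EvidenceModel, evidence_thresholds
from .local_calibration import LocalCalibrationCurve

__all__ = [
    "PriorSpec",
    "ppv_at_threshold",
    "posterior_at_score",
    "relative_risk",
    "transfer_report",
]


@dataclass(frozen=True)
class PriorSpec:
    """Target-population prior alpha and test-set prior alpha_D."""

    alpha_target: float
    alpha_test: float

    def __post_init__(self) -> None:
        for name in ("alpha_target", "alpha_test"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in the open interval (0, 1)")

    @classmethod
    def for_scores(cls, scores: LabeledScores, alpha_target: float,
                   alpha_test: Optional[float] = None) -> "PriorSpec":
        """Default alpha_test to the observed positive fraction of the set."""
        return cls(alpha_target=alpha_target,
                   alpha_test=scores.test_prior if alpha_test is None else alpha_test)


def ppv_at_threshold(tpr: float, fpr: float, prior: PriorSpec) -> float:
    """Positive predictive value at the target prior."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    a = prior.alpha_target
    denom = a * tpr + (1.0 - a) * fpr
    if denom == 0.0:
        raise ValueError("PPV undefined when TPR = FPR = 0")
    return a * tpr / denom


def posterior_at_score(lr_plus, prior: PriorSpec):
    """Local posterior rho(s) at the target prior from a local lr+."""
    lr = np.asarray(lr_plus, dtype=float)
    if np.any(lr < 0):
        raise ValueError("lr+ must be non-negative")
    a = prior.alpha_target
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(lr), 1.0, a * lr / (a * (lr - 1.0) + 1.0))
    return float(out) if np.isscalar(lr_plus) else out


def relative_risk(lr_plus, prior: PriorSpec):
    """Fold-change in pathogenicity probability relative to the population
    average; equals posterior_at_score / alpha_target exactly."""
    lr = np.asarray(lr_plus, dtype=float)
    if np.any(lr < 0):
        raise ValueError("lr+ must be non-negative")
    a = prior.alpha_target
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(lr), 1.0 / a, lr / (a * (lr - 1.0) + 1.0))
    return float(out) if np.isscalar(lr_plus) else out


def transfer_report(curve: LocalCalibrationCurve, scores: LabeledScores,
                    prior: PriorSpec,
                    model: Optional[EvidenceModel] = None) -> pd.DataFrame:
    """Per-grid-point table of prior-corrected clinical quantities.

    Columns: score, lr_plus, posterior (rho at alpha_target), relative_risk,
    ppp, ppv, and the strongest evidence level met at or above each score
    when an :class:`EvidenceModel` is given.
    """
    a = prior.alpha_target
    rho = posterior_at_score(curve.lr_plus, prior)
    rr = relative_risk(curve.lr_plus, prior)

    # empirical TPR/FPR at every grid threshold, via sorted per-class scores
    pos = np.sort(scores.scores[scores.labels == 1])
    neg = np.sort(scores.scores[scores.labels == 0])
    tpr = (len(pos) - np.searchsorted(pos, curve.grid, side="left")) / len(pos)
    fpr = (len(neg) - np.searchsorted(neg, curve.grid, side="left")) / len(neg)
    ppp = a * tpr + (1.0 - a) * fpr
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(ppp > 0, a * tpr / ppp, np.nan)

    table = pd.DataFrame({
        "score": curve.grid,
        "lr_plus": curve.lr_plus,
        "posterior": rho,
        "relative_risk": rr,
        "ppp": ppp,
        "ppv": ppv,
    })
    if model is not None:
        thresholds = evidence_thresholds(curve, model)
        level_col = np.full(len(curve), "", dtype=object)
        for level in ("supporting", "moderate", "strong", "very_strong"):
            tau = thresholds[level]
            if tau is not None:
                level_col[curve.grid >= tau] = level
        table["evidence_level"] = level_col
    return table
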
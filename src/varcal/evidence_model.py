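"""Exponential ACMG/AMP evidence-combination model.

One Very Strong line of evidence carries a positive likelihood ratio of c;
Strong, Moderate and Supporting lines carry c^(1/2), c^(1/4) and c^(1/8), so
that one Very Strong line equals two Strong, four Moderate or eight
Supporting lines. Combined evidence multiplies:

    LR_T = c ** (n_su/8 + n_mo/4 + n_st/2 + n_vs)

The posterior probability of pathogenicity given a likelihood ratio LR and a
class prior alpha is the odds-form Bayes update

    P = LR * alpha / ((LR - 1) * alpha + 1).

Score thresholds per evidence level are defined with a universal quantifier:
tau for a level is the smallest score above which *every* local lr+ estimate
meets the level's requirement, not the first upward crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .data_io import LabeledScores
from .local_calibration import LocalCalibrationCurve

__all__ = [
    "LEVELS",
    "EvidenceCounts",
    "EvidenceModel",
    "level_requirements",
    "combine_evidence",
    "posterior_from_lr",
    "lr_from_posterior",
    "evidence_thresholds",
    "fraction_reaching",
    "solve_c",
]

#: Evidence strength levels, weakest first.
LEVELS: Tuple[str, ...] = ("supporting", "moderate", "strong", "very_strong")

_LEVEL_EXPONENT = {"supporting": 1 / 8, "moderate": 1 / 4, "strong": 1 / 2,
                   "very_strong": 1.0}


@dataclass(frozen=True)
class EvidenceCounts:
    """Counts of evidence lines at each strength level."""

    n_su: int = 0
    n_mo: int = 0
    n_st: int = 0
    n_vs: int = 0

    def __post_init__(self) -> None:
        if min(self.n_su, self.n_mo, self.n_st, self.n_vs) < 0:
            raise ValueError("evidence counts must be non-negative")

    @property
    def exponent(self) -> float:
        return self.n_su / 8 + self.n_mo / 4 + self.n_st / 2 + self.n_vs

    def __add__(self, other: "EvidenceCounts") -> "EvidenceCounts":
        return EvidenceCounts(self.n_su + other.n_su, self.n_mo + other.n_mo,
                              self.n_st + other.n_st, self.n_vs + other.n_vs)


def level_requirements(c: float) -> Dict[str, float]:
    """Per-level lr+ requirements {c^(1/8), c^(1/4), c^(1/2), c}."""
    if c <= 1.0:
        raise ValueError("evidence constant c must be > 1")
    return {level: c ** exp for level, exp in _LEVEL_EXPONENT.items()}


def combine_evidence(counts: EvidenceCounts, c: float) -> float:
    """Combined likelihood ratio for a set of evidence lines."""
    if c <= 1.0:
        raise ValueError("evidence constant c must be > 1")
    return c ** counts.exponent


def posterior_from_lr(lr: float, prior: float) -> float:
    """Odds-form Bayes update; lr = 1 returns the prior unchanged."""
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    if lr < 0:
        raise ValueError("likelihood ratio must be non-negative")
    if math.isinf(lr):
        return 1.0
    return lr * prior / ((lr - 1.0) * prior + 1.0)


def lr_from_posterior(posterior: float, prior: float) -> float:
    """Inverse of :func:`posterior_from_lr` (posterior odds / prior odds)."""
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    if not 0.0 <= posterior <= 1.0:
        raise ValueError("posterior must be in [0, 1]")
    if posterior == 1.0:
        return math.inf
    return (posterior / (1.0 - posterior)) * ((1.0 - prior) / prior)


@dataclass(frozen=True)
class EvidenceModel:
    """Evidence constant c, class prior, and the derived per-level machinery."""

    c: float = 351.0
    prior: float = 0.10
    level_requirements: Dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must be in (0, 1)")
        object.__setattr__(self, "level_requirements", level_requirements(self.c))

    def combined_lr(self, counts: EvidenceCounts) -> float:
        return combine_evidence(counts, self.c)

    def combined_posterior(self, counts: EvidenceCounts) -> float:
        return posterior_from_lr(self.combined_lr(counts), self.prior)


def evidence_thresholds(curve: LocalCalibrationCurve,
                        model: EvidenceModel) -> Dict[str, Optional[float]]:
    """Smallest grid score above which every lr+ meets each level's requirement.

    Returns normalized-orientation score thresholds (higher = positive);
    ``None`` marks a level never reached. An interior dip below a requirement
    pushes that level's threshold above the dip (the for-all semantics).
    """
    # suffix minimum of lr+ along the grid: min over all s >= grid[i]
    suffix_min = np.minimum.accumulate(curve.lr_plus[::-1])[::-1]
    out: Dict[str, Optional[float]] = {}
    for level in LEVELS:
        req = model.level_requirements[level]
        ok = np.nonzero(suffix_min >= req)[0]
        out[level] = float(curve.grid[ok[0]]) if len(ok) else None
    return out


def fraction_reaching(scores: LabeledScores,
                      thresholds: Dict[str, Optional[float]],
                      target_prior: float) -> Dict[str, Optional[float]]:
    """Prior-corrected fraction of the reference population at or above each
    level's threshold: PPP(tau) = alpha*TPR(tau) + (1-alpha)*FPR(tau)."""
    if not 0.0 < target_prior < 1.0:
        raise ValueError("target prior must be in (0, 1)")
    scores.require_both_classes()
    pos = scores.scores[scores.labels == 1]
    neg = scores.scores[scores.labels == 0]
    out: Dict[str, Optional[float]] = {}
    for level, tau in thresholds.items():
        if tau is None:
            out[level] = None
            continue
        tpr = float(np.mean(pos >= tau))
        fpr = float(np.mean(neg >= tau))
        out[level] = target_prior * tpr + (1.0 - target_prior) * fpr
    return out


def solve_c(prior: float,
            rules: Sequence[Tuple[EvidenceCounts, str]],
            targets: Optional[Dict[str, float]] = None,
            *, cap: float = 1e9, tol: float = 1e-6) -> int:
    """Smallest integer c for which every combining rule meets its posterior target.

    ``rules`` pairs an :class:`EvidenceCounts` with the asserted class,
    ``"pathogenic"`` or ``"likely_pathogenic"``; the default posterior
    targets are 0.99 and 0.90. The rule list itself must be supplied by the
    caller. Smaller priors demand larger c.
    """
    targets = targets or {"pathogenic": 0.99, "likely_pathogenic": 0.90}
    if not rules:
        raise ValueError("at least one combining rule is required")
    for counts, klass in rules:
        if klass not in targets:
            raise ValueError(f"unknown rule class {klass!r}")
        if counts.exponent <= 0:
            raise ValueError("each rule needs at least one line of evidence")

    def satisfied(c: float) -> bool:
        return all(
            posterior_from_lr(combine_evidence(counts, c), prior) >= targets[klass]
            for counts, klass in rules
        )

    lo, hi = 1.0 + tol, float(cap)
    if not satisfied(hi):
        raise ValueError(f"no satisfying c below cap {cap:g}")
    if satisfied(lo):
        return 2  # any evidence suffices; smallest admissible integer c > 1
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if satisfied(mid):
            hi = mid
        else:
            lo = mid
    c_int = math.ceil(hi)
    while c_int > 2 and satisfied(float(c_int - 1)):
        c_int -= 1
    return c_int
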
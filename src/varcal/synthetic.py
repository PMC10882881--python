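"""Synthetic score generators with analytically known truth.

The binormal model draws labels Bernoulli(alpha) and scores from
class-conditional normals N(mu0, sigma0^2) / N(mu1, sigma1^2). It is the
canonical fixture because every quantity the toolkit estimates has a closed
form there:

    AUC      = Phi((mu1 - mu0) / sqrt(sigma0^2 + sigma1^2))
    lr+(s)   = phi1(s) / phi0(s)
    rho(s)   = alpha*lr+(s) / (alpha*(lr+(s)-1) + 1)   at any prior alpha

A beta-mixture variant covers bounded [0, 1] scores (metapredictor-like
output), and a bivariate-normal generator with optional monotone transforms
exercises the continuous metrics (Pearson r = rho, Kendall tau =
(2/pi)*arcsin(rho)).

Defaults: mu0 = 0, mu1 = sqrt(2), unit sigmas, alpha = 0.5, giving analytic
AUC = Phi(1) ~ 0.841, a separation typical of well-performing pathogenicity
predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import stats

from .data_io import ContinuousPairs, LabeledScores

__all__ = [
    "BinormalSpec",
    "BetaMixtureSpec",
    "BivariateSpec",
    "BinaryTruth",
    "ContinuousTruth",
    "generate_binary",
    "generate_continuous",
    "generate_tied",
    "MONOTONE_TRANSFORMS",
]

MONOTONE_TRANSFORMS: dict = {
    "exp": np.exp,
    "cube": lambda x: x ** 3,
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


@dataclass(frozen=True)
class BinormalSpec:
    """Binormal class-conditional score model."""

    mu0: float = 0.0
    sigma0: float = 1.0
    mu1: float = math.sqrt(2.0)
    sigma1: float = 1.0
    alpha: float = 0.5
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def auc(self) -> float:
        delta = self.mu1 - self.mu0
        return float(stats.norm.cdf(delta / math.hypot(self.sigma0, self.sigma1)))

    def lr_plus(self, s) -> np.ndarray:
        return (stats.norm.pdf(s, self.mu1, self.sigma1)
                / stats.norm.pdf(s, self.mu0, self.sigma0))

    def posterior(self, s, alpha: Optional[float] = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        lr = self.lr_plus(s)
        return a * lr / (a * (lr - 1.0) + 1.0)


@dataclass(frozen=True)
class BetaMixtureSpec:
    """Beta class-conditionals on [0, 1] for bounded-score predictors."""

    a0: float = 1.0
    b0: float = 3.0
    a1: float = 3.0
    b1: float = 1.0
    alpha: float = 0.5
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a0, self.b0, self.a1, self.b1) <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def lr_plus(self, s) -> np.ndarray:
        return (stats.beta.pdf(s, self.a1, self.b1)
                / stats.beta.pdf(s, self.a0, self.b0))

    def posterior(self, s, alpha: Optional[float] = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        lr = self.lr_plus(s)
        return a * lr / (a * (lr - 1.0) + 1.0)


@dataclass(frozen=True)
class BinaryTruth:
    """Analytic truth record attached to a generated binary score set."""

    auc: float
    alpha: float
    lr_plus: Callable
    posterior: Callable


@dataclass(frozen=True)
class BivariateSpec:
    """Bivariate-normal predicted/observed pairs with correlation rho."""

    rho: float = 0.5
    n: int = 1000
    monotone_transform: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if (self.monotone_transform is not None
                and self.monotone_transform not in MONOTONE_TRANSFORMS):
            raise ValueError(f"unknown transform {self.monotone_transform!r}; "
                             f"choose from {sorted(MONOTONE_TRANSFORMS)}")

    @property
    def pearson(self) -> float:
        return self.rho

    @property
    def kendall_tau(self) -> float:
        """Greiner's relation for the bivariate normal."""
        return (2.0 / math.pi) * math.asin(self.rho)


@dataclass(frozen=True)
class ContinuousTruth:
    pearson: float
    kendall_tau: float


def generate_binary(spec: Union[BinormalSpec, BetaMixtureSpec]):
    """Draw a labeled score set; returns (LabeledScores, BinaryTruth)."""
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.alpha).astype(np.int8)
    if isinstance(spec, BinormalSpec):
        mu = np.where(labels == 1, spec.mu1, spec.mu0)
        sigma = np.where(labels == 1, spec.sigma1, spec.sigma0)
        scores = rng.normal(mu, sigma)
        auc = spec.auc
    else:
        a = np.where(labels == 1, spec.a1, spec.a0)
        b = np.where(labels == 1, spec.b1, spec.b0)
        scores = rng.beta(a, b)
        # AUC = P(S1 > S0) by quadrature over the positive-class density
        grid = np.linspace(1e-9, 1 - 1e-9, 4001)
        auc = float(np.trapezoid(
            stats.beta.pdf(grid, spec.a1, spec.b1)
            * stats.beta.cdf(grid, spec.a0, spec.b0), grid))
    ids = np.array([f"v{i}" for i in range(spec.n)], dtype=object)
    truth = BinaryTruth(auc=auc, alpha=spec.alpha,
                        lr_plus=spec.lr_plus, posterior=spec.posterior)
    return LabeledScores(ids, scores, labels), truth


def generate_continuous(spec: BivariateSpec):
    """Draw predicted/observed pairs; returns (ContinuousPairs, ContinuousTruth)."""
    rng = np.random.default_rng(spec.seed)
    z1 = rng.standard_normal(spec.n)
    z2 = rng.standard_normal(spec.n)
    predicted = z1
    observed = spec.rho * z1 + math.sqrt(1.0 - spec.rho ** 2) * z2
    if spec.monotone_transform is not None:
        observed = MONOTONE_TRANSFORMS[spec.monotone_transform](observed)
    ids = np.array([f"v{i}" for i in range(spec.n)], dtype=object)
    return (ContinuousPairs(ids, predicted, observed),
            ContinuousTruth(pearson=spec.pearson, kendall_tau=spec.kendall_tau))


def generate_tied(base: Union[LabeledScores, ContinuousPairs],
                  quantization: int):
    """Quantize scores to bin midpoints, injecting ties; labels unchanged."""
    if quantization < 2:
        raise ValueError("quantization must use at least 2 bins")
    values = base.scores if isinstance(base, LabeledScores) else base.predicted
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, quantization + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0,
                  quantization - 1)
    quantized = mids[idx]
    if isinstance(base, LabeledScores):
        return LabeledScores(base.item_ids, quantized, base.labels,
                             flipped=base.flipped)
    return ContinuousPairs(base.item_ids, quantized, base.observed)
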
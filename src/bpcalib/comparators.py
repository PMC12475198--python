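"""Quantile-based probability conversion (Pain et al.-style) and variants.

The quantile approach models the PGS Z-value distribution (standardized
against a population reference panel) as a mixture of two unit-variance
normals separated by ``d = sqrt(2) * Phi^{-1}(AUC)``, with the AUC derived
from an R^2 estimate.  The mixture range is cut into quantiles and every
individual receives the Bayes posterior probability evaluated at the midpoint
of the quantile containing their Z-value.

Two positioning conventions are implemented:

- *faithful*: the mixture is centered using the target-sample mixing weights
  (the prior), but Z-values are standardized against the full population.  In
  a case-enriched target sample the population standardization overstates the
  Z-values and hence the probabilities — the documented source of
  miscalibration of this approach.
- *adjusted*: component means are placed so the population mixture (weights
  ``K``, ``1-K``) is centered, while the prior only enters the Bayes weights;
  this removes the ascertainment bias while keeping the equal-variance
  assumption (which the exact truncated-normal treatment in
  :mod:`bpcalib.bpc` does not make).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .liability_core import auc_from_r2

__all__ = ["PainConfig", "pain_probability", "pain_adjusted", "continuous_equal_variance_posterior"]


@dataclass(frozen=True)
class PainConfig:
    """Settings for the quantile conversion.

    ``reference_mean``/``reference_sd`` standardize target PGSs against the
    population reference panel.  ``n_quantiles=0`` selects the continuous
    (infinitely many quantiles) limit.
    """

    reference_mean: float = 0.0
    reference_sd: float = 1.0
    n_quantiles: int = 1000
    equal_variances: bool = True  # the approach's defining assumption

    def __post_init__(self) -> None:
        if self.n_quantiles != 0 and self.n_quantiles < 10:
            raise ValueError("n_quantiles must be 0 (continuous) or >= 10")
        if self.reference_sd <= 0:
            raise ValueError("reference_sd must be positive")


def continuous_equal_variance_posterior(
    z_values: np.ndarray, prior, mu1: float, mu0: float
) -> np.ndarray:
    """Bayes posterior for unit-variance normal components at given means."""
    f1 = norm.pdf(z_values, loc=mu1, scale=1.0)
    f0 = norm.pdf(z_values, loc=mu0, scale=1.0)
    prior = np.asarray(prior, dtype=float)
    num = prior * f1
    return num / (num + (1.0 - prior) * f0)


def _mixture_quantiles(qs: np.ndarray, prior: float, mu1: float, mu0: float) -> np.ndarray:
    """Quantiles of the two-component unit-variance normal mixture.

    Inverts the mixture CDF by interpolation on a grid built from the
    component quantiles (log-dense in the tails), accurate far into the tails.
    """
    p = np.concatenate([np.geomspace(1e-12, 0.5, 1500),
                        1.0 - np.geomspace(1e-12, 0.5, 1500)[::-1]])
    base = norm.ppf(p)
    grid = np.unique(np.concatenate([mu1 + base, mu0 + base]))
    cdf = prior * norm.cdf(grid, loc=mu1) + (1.0 - prior) * norm.cdf(grid, loc=mu0)
    return np.interp(qs, cdf, grid)


def _quantile_posterior(
    z: np.ndarray, prior: float, mu1: float, mu0: float, n_quantiles: int
) -> np.ndarray:
    if n_quantiles == 0:
        return continuous_equal_variance_posterior(z, prior, mu1, mu0)
    Q = n_quantiles
    edges = _mixture_quantiles(np.arange(1, Q) / Q, prior, mu1, mu0)
    mids = _mixture_quantiles((np.arange(Q) + 0.5) / Q, prior, mu1, mu0)
    probs = continuous_equal_variance_posterior(mids, prior, mu1, mu0)
    bins = np.searchsorted(edges, z, side="right")
    return probs[bins]


def _separation(r2_liability: float, K: float) -> float:
    if not (0.0 <= r2_liability <= 1.0):
        raise ValueError("r2_liability must lie in [0, 1]")
    auc = auc_from_r2(r2_liability, K)
    return float(np.sqrt(2.0) * norm.ppf(auc))


def pain_probability(
    pgs, prior: float, r2_liability: float, cfg: PainConfig, K: float
) -> np.ndarray:
    """Faithful quantile conversion (population standardization, prior centering).

    The case/control means are ``mu1 = (1-prior) d`` and ``mu0 = -prior d``
    (mixture centered at zero under the *target* weights), while individual
    Z-values are standardized against the population reference — the
    combination that overestimates probabilities in case-enriched samples.
    """
    pgs = np.asarray(pgs, dtype=float)
    z = (pgs - cfg.reference_mean) / cfg.reference_sd
    if r2_liability == 0.0:
        return np.full(z.shape, prior, dtype=float)
    d = _separation(r2_liability, K)
    mu1 = (1.0 - prior) * d
    mu0 = -prior * d
    return _quantile_posterior(z, prior, mu1, mu0, cfg.n_quantiles)


def pain_adjusted(
    pgs, prior: float, r2_liability: float, cfg: PainConfig, K: float
) -> np.ndarray:
    """Prevalence-aware variant: population centering, prior only in Bayes weights.

    Component means are placed so the *population* mixture (weights ``K`` and
    ``1-K``) has mean zero, matching the population standardization of the
    Z-values; identical to the faithful mode when ``prior == K``.
    """
    pgs = np.asarray(pgs, dtype=float)
    z = (pgs - cfg.reference_mean) / cfg.reference_sd
    if r2_liability == 0.0:
        return np.full(z.shape, prior, dtype=float)
    d = _separation(r2_liability, K)
    mu1 = (1.0 - K) * d
    mu0 = -K * d
    return _quantile_posterior(z, prior, mu1, mu0, cfg.n_quantiles)
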
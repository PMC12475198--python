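"""Bayesian conversion of liability-scale polygenic scores to probabilities.

The core conversion takes an individual's liability-scale PGS and returns the
posterior probability of the disorder via Bayes' theorem over a two-component
normal mixture:

    P(case | PGS) = prior * N(PGS; mu1, s1^2)
                    / [prior * N(PGS; mu1, s1^2) + (1-prior) * N(PGS; mu0, s0^2)]

where the case/control component moments come either from normal theory
(:func:`bpcalib.liability_core.casecontrol_pgs_moments` driven by the
reference-panel variance estimate of R^2_liability) or from a phenotyped
tuning sample.  The prior is the disorder probability for the individual's
context (e.g. the case fraction of the clinic population), not the population
prevalence.

Also here: the reference-panel R^2 estimator (the variance of a
well-calibrated liability-scale PGS *is* its R^2), the linear-rescaling
alternative, the logistic-regression tuning approach, and the dispersion of
the per-individual likelihood ratio P(PGS | case) / P(PGS) that measures how
much the posterior moves away from the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .liability_core import (
    LiabilityConfig,
    PgsDistribution,
    casecontrol_pgs_moments,
    r2_observed_from_liability,
)

__all__ = [
    "BpcModel",
    "estimate_r2_liability",
    "bpc_model_from_reference",
    "bpc_posterior",
    "likelihood_ratio_sd",
    "bpc_tuned",
    "linear_rescale",
    "logit_tuned",
]


@dataclass(frozen=True)
class BpcModel:
    """A fitted conversion model: disorder config, R^2 estimate, PGS mixture."""

    config: LiabilityConfig
    r2_liability_hat: float
    dist: PgsDistribution
    prior: float | np.ndarray
    source_tag: str  # "theory" or "tuned"

    def __post_init__(self) -> None:
        pr = np.asarray(self.prior, dtype=float)
        if np.any((pr <= 0.0) | (pr >= 1.0)):
            raise ValueError("prior must lie strictly in (0, 1)")
        if not (0.0 <= self.r2_liability_hat <= 1.0):
            raise ValueError("r2_liability_hat must lie in [0, 1]")


def estimate_r2_liability(reference_pgs: np.ndarray) -> float:
    """R^2_liability as the variance of the PGS in a population reference panel.

    A PGS that is well-calibrated on the (unit-variance) liability scale
    satisfies ``var(PGS) = R^2_liability``, so the sample variance
    (denominator ``n - 1``) of the reference-panel PGS estimates R^2 with no
    phenotype data at all.  The panel must be a population (non-ascertained)
    sample scored with liability-scale betas.
    """
    pgs = np.asarray(reference_pgs, dtype=float)
    if pgs.size < 2:
        raise ValueError("need at least 2 reference individuals")
    return float(np.var(pgs, ddof=1))


def bpc_model_from_reference(
    reference_pgs: np.ndarray, K: float, prior: float | np.ndarray
) -> BpcModel:
    """Theory-path model: estimate R^2 from the panel, derive the mixture."""
    r2_hat = estimate_r2_liability(reference_pgs)
    r2_hat = min(r2_hat, 1.0)
    cfg = LiabilityConfig(K=K, r2_liability=None)
    dist = casecontrol_pgs_moments(r2_hat, K)
    return BpcModel(
        config=cfg, r2_liability_hat=r2_hat, dist=dist, prior=prior, source_tag="theory"
    )


def _mixture_densities(pgs: np.ndarray, model: BpcModel):
    d = model.dist
    if d.var_case <= 0 or d.var_control <= 0:
        raise ValueError("degenerate (zero-variance) PGS mixture")
    f1 = norm.pdf(pgs, loc=d.mu_case, scale=np.sqrt(d.var_case))
    f0 = norm.pdf(pgs, loc=d.mu_control, scale=np.sqrt(d.var_control))
    return f1, f0


def bpc_posterior(pgs, model: BpcModel) -> np.ndarray:
    """Posterior disorder probability for each PGS value (Bayes update).

    With an uninformative score (R^2 -> 0) the posterior equals the prior for
    everyone; otherwise it lies strictly inside (0, 1).
    """
    pgs = np.atleast_1d(np.asarray(pgs, dtype=float))
    if model.r2_liability_hat == 0.0:
        return np.broadcast_to(
            np.asarray(model.prior, dtype=float), pgs.shape
        ).copy()
    f1, f0 = _mixture_densities(pgs, model)
    prior = np.asarray(model.prior, dtype=float)
    num = prior * f1
    post = num / (num + (1.0 - prior) * f0)
    return post


def likelihood_ratio_sd(testing_pgs, model: BpcModel) -> float:
    """SD over individuals of P(PGS | case) / P(PGS).

    ``P(PGS)`` is the prior-weighted mixture density.  A value near 0 means
    the posterior barely moves from the prior; large dispersion means the PGS
    is informative for this population.
    """
    pgs = np.asarray(testing_pgs, dtype=float)
    if model.r2_liability_hat == 0.0:
        return 0.0
    f1, f0 = _mixture_densities(pgs, model)
    prior = np.asarray(model.prior, dtype=float)
    mix = prior * f1 + (1.0 - prior) * f0
    return float(np.std(f1 / mix, ddof=0))


def bpc_tuned(
    tuning_pgs, tuning_status, prior: float | np.ndarray, K: float | None = None
) -> BpcModel:
    """Empirical-moments model from a phenotyped tuning sample.

    Uses sample means/variances of the PGS by case status instead of normal
    theory, skipping the scale-conversion and R^2-estimation steps entirely.
    """
    pgs = np.asarray(tuning_pgs, dtype=float)
    y = np.asarray(tuning_status)
    cases = pgs[y == 1]
    controls = pgs[y == 0]
    if cases.size < 2 or controls.size < 2:
        raise ValueError("tuning sample needs at least 2 cases and 2 controls")
    dist = PgsDistribution(
        mu_case=float(cases.mean()),
        var_case=float(cases.var(ddof=1)),
        mu_control=float(controls.mean()),
        var_control=float(controls.var(ddof=1)),
        p_case=float(y.mean()),
    )
    cfg = LiabilityConfig(K=K if K is not None else float(y.mean()))
    # implied R^2: mixture variance of a calibrated liability-scale PGS
    r2 = min(max(dist.mixture_var(), 0.0), 1.0)
    return BpcModel(
        config=cfg, r2_liability_hat=r2, dist=dist, prior=prior, source_tag="tuned"
    )


def linear_rescale(
    pgs, prior: float, model: BpcModel, truncate: bool = True
) -> np.ndarray:
    """Affine map of the liability-scale PGS to the 0/1 probability scale.

    The PGS is scaled so that its variance in the ascertained target sample
    (mixture with case weight ``prior``) equals the observed-scale R^2 of the
    Lee transformation at case fraction ``prior``, then shifted to the 0/1
    scale: ``prob = PGS' * sqrt(prior (1-prior)) + prior``.  Values outside
    [0, 1] can occur (mostly at low prevalence and large R^2) and are
    truncated by default.
    """
    pgs = np.asarray(pgs, dtype=float)
    d = model.dist
    K = model.config.K
    asc = PgsDistribution(
        mu_case=d.mu_case,
        var_case=d.var_case,
        mu_control=d.mu_control,
        var_control=d.var_control,
        p_case=prior,
    )
    var_asc = asc.mixture_var()
    if var_asc <= 0:
        return np.full_like(pgs, prior)
    r2_obs = r2_observed_from_liability(model.r2_liability_hat, K, prior)
    centred = pgs - asc.mixture_mean()
    pgs_prime = centred * np.sqrt(r2_obs / var_asc)
    prob = pgs_prime * np.sqrt(prior * (1.0 - prior)) + prior
    if truncate:
        prob = np.clip(prob, 0.0, 1.0)
    return prob


def logit_tuned(tuning_pgs, tuning_status, testing_pgs) -> np.ndarray:
    """Probabilities from a logistic regression fitted in a tuning sample.

    Fits ``status ~ PGS`` by maximum likelihood, applies the fitted intercept
    and slope to the testing PGS, and inverse-logit transforms.  A constant
    PGS degrades to the intercept-only model (all probabilities equal to the
    tuning case fraction); perfect separation raises with guidance.
    """
    tune = np.asarray(tuning_pgs, dtype=float)
    y = np.asarray(tuning_status, dtype=float)
    test = np.asarray(testing_pgs, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("tuning sample must contain both classes")
    if np.ptp(tune) == 0:
        p = float(y.mean())
        return np.full(test.shape, p)
    X = sm.add_constant(tune)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(
            "logistic fit failed (possibly perfect separation in the tuning "
            "sample; use a larger or noisier tuning sample)"
        ) from exc
    if not np.all(np.isfinite(fit.params)):
        raise ValueError("logistic fit diverged (perfect separation?)")
    logits = fit.params[0] + fit.params[1] * test
    return 1.0 / (1.0 + np.exp(-logits))
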
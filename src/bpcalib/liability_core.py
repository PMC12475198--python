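"""Closed-form liability-threshold mathematics.

Under the liability threshold model a binary disorder with population lifetime
prevalence ``K`` arises when a latent standard-normal liability exceeds the
threshold ``T = Phi^{-1}(1 - K)``.  A polygenic score (PGS) that is
well-calibrated on the liability scale explains a fraction ``r2_liability`` of
the liability variance, and its distribution conditional on case/control
status follows from truncating the bivariate normal (liability, PGS)
distribution at ``T``.  This module collects those closed forms: threshold and
density height, effect-size scale conversions, observed/liability R^2
conversions for ascertained case-control samples, case/control PGS moments,
and the normal-theory R^2 -> AUC map.

Everything here is pure scalar/broadcast math on top of ``scipy.stats.norm``;
no data handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "LiabilityConfig",
    "PgsDistribution",
    "threshold_and_height",
    "beta_liability",
    "beta_scale_factor",
    "r2_observed_from_liability",
    "r2_liability_from_observed",
    "casecontrol_pgs_moments",
    "auc_from_r2",
]


def _check_prob(x: float, name: str) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {x!r}")


def threshold_and_height(K: float) -> tuple[float, float]:
    """Liability threshold ``T = Phi^{-1}(1-K)`` and density height ``z = phi(T)``.

    Parameters
    ----------
    K : float
        Population lifetime prevalence, in (0, 1).

    Returns
    -------
    (T, z) : tuple of floats
        Threshold on the standard-normal liability scale and the standard
        normal density evaluated there.
    """
    _check_prob(K, "K")
    T = norm.isf(K)
    z = norm.pdf(T)
    return float(T), float(z)


@dataclass(frozen=True)
class LiabilityConfig:
    """Scalar disorder model: prevalence plus derived threshold quantities.

    ``T`` and ``z`` are always recomputed from ``K`` so they can never be
    stored inconsistently.
    """

    K: float
    h2: float | None = None
    r2_liability: float | None = None
    T: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        _check_prob(self.K, "K")
        if self.h2 is not None and not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 must lie in [0, 1]; got {self.h2!r}")
        if self.r2_liability is not None:
            hi = self.h2 if self.h2 is not None else 1.0
            if not (0.0 <= self.r2_liability <= hi + 1e-12):
                raise ValueError(
                    f"r2_liability must lie in [0, {hi}]; got {self.r2_liability!r}"
                )
        T, z = threshold_and_height(self.K)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class PgsDistribution:
    """Means/variances of a liability-scale PGS conditional on disorder status.

    ``p_case`` is the mixing proportion of cases in the target sample (which
    may differ from the population prevalence under ascertainment).
    """

    mu_case: float
    var_case: float
    mu_control: float
    var_control: float
    p_case: float

    def __post_init__(self) -> None:
        if self.var_case < 0 or self.var_control < 0:
            raise ValueError("conditional variances must be nonnegative")
        _check_prob(self.p_case, "p_case")

    def mixture_mean(self) -> float:
        return self.p_case * self.mu_case + (1.0 - self.p_case) * self.mu_control

    def mixture_var(self) -> float:
        m = self.mixture_mean()
        return (
            self.p_case * (self.var_case + self.mu_case**2)
            + (1.0 - self.p_case) * (self.var_control + self.mu_control**2)
            - m**2
        )


def beta_scale_factor(K: float, p: float = 0.5) -> float:
    """Multiplier taking standardized-observed-scale betas to the liability scale.

    For betas estimated on the standardized observed scale in a sample with
    case fraction ``p``, the liability-scale effect is
    ``beta_liability = beta_obs * K(1-K) / (z * p)``, with ``z`` the normal
    density height at the threshold for prevalence ``K``.
    """
    _check_prob(p, "p")
    T, z = threshold_and_height(K)
    return K * (1.0 - K) / (z * p)


def beta_liability(beta_5050, K: float, p: float = 0.5):
    """Convert standardized observed-scale (50/50) betas to the liability scale.

    Element-wise linear map; preserves zeros and ordering.
    """
    return np.asarray(beta_5050, dtype=float) * beta_scale_factor(K, p)


def _lee_constants(K: float, P: float) -> tuple[float, float]:
    """C and theta of the ascertainment-aware observed<->liability R^2 map."""
    T, z = threshold_and_height(K)
    m = z / K  # mean liability of cases
    C = (K * (1.0 - K)) ** 2 / (z**2 * P * (1.0 - P))
    d = m * (P - K) / (1.0 - K)
    theta = d * (d - T)
    return C, theta


def r2_liability_from_observed(r2_observed: float, K: float, P: float) -> float:
    """Observed-scale (0/1 regression) R^2 -> liability-scale R^2.

    Uses the ascertainment-corrected transformation for a case-control sample
    with case fraction ``P`` drawn from a population with prevalence ``K``.
    """
    _check_prob(P, "P")
    C, theta = _lee_constants(K, P)
    r2l = C * r2_observed / (1.0 + C * theta * r2_observed)
    if not (-1e-12 <= r2l <= 1.0 + 1e-12):
        raise ValueError(f"converted r2_liability {r2l!r} outside [0, 1]")
    return float(min(max(r2l, 0.0), 1.0))


def r2_observed_from_liability(r2_liability: float, K: float, P: float) -> float:
    """Liability-scale R^2 -> observed-scale R^2 in an ascertained sample.

    Exact inverse of :func:`r2_liability_from_observed`.
    """
    _check_prob(P, "P")
    if not (0.0 <= r2_liability <= 1.0):
        raise ValueError(f"r2_liability must lie in [0, 1]; got {r2_liability!r}")
    C, theta = _lee_constants(K, P)
    denom = C * (1.0 - theta * r2_liability)
    if denom <= 0:
        raise ValueError("conversion degenerate: C*(1 - theta*r2) <= 0")
    r2o = r2_liability / denom
    if not (-1e-12 <= r2o <= 1.0 + 1e-12):
        raise ValueError(f"converted r2_observed {r2o!r} outside [0, 1]")
    return float(min(max(r2o, 0.0), 1.0))


def casecontrol_pgs_moments(
    r2_liability: float, K: float, p_case: float | None = None
) -> PgsDistribution:
    """Normal-theory case/control moments of a liability-scale PGS.

    The PGS has population variance ``r2_liability`` and is jointly normal
    with the liability (correlation ``sqrt(r2_liability)``); truncating the
    liability at the threshold gives, with ``i1 = z/K`` and ``i0 = z/(1-K)``:

    - ``mu_case = r2 * i1``; ``mu_control = -r2 * i0``
    - ``var_case = r2 * (1 - r2 * i1 * (i1 - T))``
    - ``var_control = r2 * (1 - r2 * i0 * (i0 + T))``

    For ``K < 0.5`` the case variance is the smaller one: case liabilities are
    squeezed into the upper tail.

    ``p_case`` defaults to ``K`` (population mixture).
    """
    if not (0.0 <= r2_liability <= 1.0):
        raise ValueError(f"r2_liability must lie in [0, 1]; got {r2_liability!r}")
    T, z = threshold_and_height(K)
    i1 = z / K
    i0 = z / (1.0 - K)
    r2 = r2_liability
    return PgsDistribution(
        mu_case=r2 * i1,
        var_case=r2 * (1.0 - r2 * i1 * (i1 - T)),
        mu_control=-r2 * i0,
        var_control=r2 * (1.0 - r2 * i0 * (i0 + T)),
        p_case=K if p_case is None else p_case,
    )


def auc_from_r2(r2_liability: float, K: float) -> float:
    """Normal-theory AUC of a PGS explaining ``r2_liability`` of liability.

    Standardizes the case-control mean difference by the average of the two
    conditional variances, ``d = (mu_case - mu_control) / sqrt((v1 + v0)/2)``,
    and returns ``Phi(d / sqrt(2))`` — the exact AUC of two normals with those
    means when both have the average variance.
    """
    if r2_liability == 0.0:
        return 0.5
    dist = casecontrol_pgs_moments(r2_liability, K)
    pooled = 0.5 * (dist.var_case + dist.var_control)
    d = (dist.mu_case - dist.mu_control) / np.sqrt(pooled)
    return float(norm.cdf(d / np.sqrt(2.0)))
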
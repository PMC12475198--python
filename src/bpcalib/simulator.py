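"""Liability-threshold simulation of case-control cohorts with LE SNPs.

The generative model: ``M`` SNPs in linkage equilibrium with allele
frequencies ``f_j ~ Uniform(0.05, 0.5)``; standardized-scale effects
``beta_j ~ N(0, h2/M)``; liability ``L_i = sum_j beta_j g*_ij + e_i`` with
``e ~ N(0, 1 - h2)`` so ``var(L) = 1`` in the population; disorder status
``1{L > T(K)}``.  Per run, three (or four) independent samples share one draw
of effects and frequencies: a case-control training sample for the GWAS, a
population reference sample (R^2 estimation, no phenotypes), an ascertained
testing sample, and optionally a tuning sample.

Genotypes are drawn by comparing one uniform variate per genotype against the
cumulative Hardy-Weinberg class probabilities (identical in distribution to
``Binomial(2, f)`` but much faster); ascertained cohorts are collected by
blockwise rejection sampling from the population so the exact requested
case/control counts are met without holding the whole population in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .liability_core import threshold_and_height
from .shrinkage import SummaryStats

__all__ = [
    "SimCondition",
    "CohortSample",
    "simulate_population",
    "simulate_ascertained",
    "ascertain",
    "gwas_obs5050",
    "expected_pgs_r2",
    "required_training_n",
    "run_condition",
]


@dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation grid.

    Defaults follow the design of the study this simulator emulates:
    SNP heritability 0.2, 1000 LE SNPs, a 503-individual population reference
    panel, a 1000/1000 case-control testing sample and 100 replicates.
    """

    K: float
    r2_target: float
    h2: float = 0.2
    M: int = 1000
    n_reference: int = 503
    n_test_cases: int = 1000
    n_test_controls: int = 1000
    n_runs: int = 100
    prior: float = 0.5
    seed: int = 0
    freq_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0):
            raise ValueError("K must lie in (0, 1)")
        if self.r2_target > self.h2 + 1e-12:
            raise ValueError("r2_target cannot exceed h2")


@dataclass
class CohortSample:
    """Genotypes, liabilities and status for one simulated cohort."""

    role: str  # training / reference / tuning / testing / population
    dosages: np.ndarray  # N x M allele counts, int8
    liability: np.ndarray
    status: np.ndarray  # int8 0/1
    freqs: np.ndarray
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def std_dosages(self) -> np.ndarray:
        """Genotypes standardized by the generating allele frequencies."""
        f = self.freqs
        return (self.dosages - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))

    def case_fraction(self) -> float:
        return float(np.mean(self.status))


def draw_effects(rng: np.random.Generator, M: int, h2: float) -> np.ndarray:
    """Standardized-genotype-scale liability effects, beta_j ~ N(0, h2/M)."""
    return rng.normal(0.0, np.sqrt(h2 / M), size=M)


def draw_freqs(rng: np.random.Generator, M: int, lo: float = 0.05, hi: float = 0.5) -> np.ndarray:
    return rng.uniform(lo, hi, size=M)


def _draw_dosages(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    """n x M allele counts, one uniform per genotype vs cumulative HWE probs."""
    p_hom_ref = ((1.0 - freqs) ** 2).astype(np.float32)
    p_not_hom_alt = (p_hom_ref + 2.0 * freqs * (1.0 - freqs)).astype(np.float32)
    u = rng.random((n, freqs.size), dtype=np.float32)
    g = (u > p_hom_ref).astype(np.int8)
    g += u > p_not_hom_alt
    return g


def _liability(
    dosages: np.ndarray,
    effects: np.ndarray,
    freqs: np.ndarray,
    env: np.ndarray,
) -> np.ndarray:
    scale = np.sqrt(2.0 * freqs * (1.0 - freqs))
    w = (effects / scale).astype(np.float32)
    genetic = dosages @ w - 2.0 * float(freqs @ (effects / scale))
    return genetic.astype(float) + env


def simulate_population(
    cond: SimCondition,
    n: int,
    effects: np.ndarray,
    freqs: np.ndarray,
    rng: np.random.Generator,
    role: str = "population",
) -> CohortSample:
    """Random (population) sample of ``n`` individuals under the condition."""
    if n <= 0:
        raise ValueError("sample size must be positive")
    T, _ = threshold_and_height(cond.K)
    g = _draw_dosages(rng, n, freqs)
    env = rng.normal(0.0, np.sqrt(1.0 - cond.h2), size=n)
    liab = _liability(g, effects, freqs, env)
    status = (liab > T).astype(np.int8)
    return CohortSample(role=role, dosages=g, liability=liab, status=status, freqs=freqs)


def ascertain(sample: CohortSample, n_cases: int, n_controls: int,
              rng: np.random.Generator | None = None, role: str | None = None) -> CohortSample:
    """Draw exact case/control counts uniformly without replacement."""
    rng = rng or np.random.default_rng()
    cases = np.flatnonzero(sample.status == 1)
    controls = np.flatnonzero(sample.status == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"cannot ascertain {n_cases}/{n_controls} from a sample with "
            f"{len(cases)} cases and {len(controls)} controls"
        )
    keep = np.concatenate([
        rng.choice(cases, size=n_cases, replace=False),
        rng.choice(controls, size=n_controls, replace=False),
    ])
    return CohortSample(
        role=role or sample.role,
        dosages=sample.dosages[keep],
        liability=sample.liability[keep],
        status=sample.status[keep],
        freqs=sample.freqs,
    )


def simulate_ascertained(
    cond: SimCondition,
    n_cases: int,
    n_controls: int,
    effects: np.ndarray,
    freqs: np.ndarray,
    rng: np.random.Generator,
    role: str = "testing",
    block: int | None = None,
) -> CohortSample:
    """Blockwise rejection sampling until the requested counts are met.

    Equivalent to simulating an arbitrarily large population and ascertaining
    uniformly, but only genotypes of retained individuals are kept; the block
    size adapts to the expected case yield to bound memory.
    """
    if n_cases < 0 or n_controls < 0 or n_cases + n_controls == 0:
        raise ValueError("requested counts must be nonnegative and not both zero")
    T, _ = threshold_and_height(cond.K)
    if block is None:
        # expect ~a quarter of the needed cases per block, capped for memory
        block = int(min(max(n_cases / max(cond.K, 1e-3) / 4, 20_000), 200_000))
    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    liab_c: list[np.ndarray] = []
    liab_n: list[np.ndarray] = []
    have_c = have_n = 0
    while have_c < n_cases or have_n < n_controls:
        pop = simulate_population(cond, block, effects, freqs, rng)
        is_case = pop.status == 1
        if have_c < n_cases:
            idx = np.flatnonzero(is_case)[: n_cases - have_c]
            got_cases.append(pop.dosages[idx])
            liab_c.append(pop.liability[idx])
            have_c += len(idx)
        if have_n < n_controls:
            idx = np.flatnonzero(~is_case)[: n_controls - have_n]
            got_controls.append(pop.dosages[idx])
            liab_n.append(pop.liability[idx])
            have_n += len(idx)
    dosages = np.concatenate(got_cases + got_controls)
    liability = np.concatenate(liab_c + liab_n)
    status = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    # shuffle so downstream code cannot rely on block structure
    perm = rng.permutation(n_cases + n_controls)
    return CohortSample(
        role=role,
        dosages=dosages[perm],
        liability=liability[perm],
        status=status[perm],
        freqs=freqs,
    )


def gwas_obs5050(training: CohortSample, n_eff: float | None = None) -> SummaryStats:
    """Marginal GWAS on the standardized observed scale.

    Per SNP, ``z = corr(status_std, genotype_std) * sqrt(N)`` with both
    variables standardized within the sample, and ``beta = z / sqrt(N_eff)``.
    For the balanced 50/50 design ``N_eff = N``; for other case fractions pass
    ``n_eff`` explicitly (e.g. ``4 N P (1-P)`` or simply ``N`` to stay on the
    sample's own observed scale).  Monomorphic SNPs get ``z = 0`` with a
    warning.
    """
    g = training.dosages
    y = training.status.astype(float)
    n = g.shape[0]
    y_c = y - y.mean()
    sy = y.std()
    if sy == 0:
        raise ValueError("training sample has a single phenotype class")
    g_mean = g.mean(axis=0)
    g_sd = g.std(axis=0)
    mono = g_sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs; their z set to 0")
    cov = (y_c @ g) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(mono, 0.0, cov / (sy * np.where(mono, 1.0, g_sd)))
    z = corr * np.sqrt(n)
    if n_eff is None:
        n_eff = float(n)
    af = g_mean / 2.0
    tab = pd.DataFrame(
        {
            "snp": [f"snp{j}" for j in range(g.shape[1])],
            "a1": "A",
            "a2": "G",
            "z": z,
            "beta": z / np.sqrt(n_eff),
            "af": af,
        }
    )
    return SummaryStats(table=tab, scale_tag="obs5050", n_eff=n_eff)


def _obs_scale_factor(K: float, ascertainment: str) -> float:
    """Liability->observed beta scale factor ``1/c`` denominator constant ``c``.

    ``c`` multiplies observed-scale betas to give liability-scale betas:
    ``c = K(1-K)/(z p)`` with ``p = 0.5`` for 50/50 ascertainment and
    ``p = sqrt(K(1-K))`` for random (population) sampling of a standardized
    0/1 phenotype.
    """
    T, z = threshold_and_height(K)
    if ascertainment == "5050":
        return 2.0 * K * (1.0 - K) / z
    if ascertainment == "random":
        return np.sqrt(K * (1.0 - K)) / z
    raise ValueError(f"unknown ascertainment {ascertainment!r}")


def expected_pgs_r2(
    n_training: float, K: float, h2: float, M: int, ascertainment: str = "5050"
) -> float:
    """Closed-form expected liability-scale R^2 of the posterior-mean PGS.

    With LE markers and an infinitesimal prior the posterior-mean PGS explains
    ``h2 * (h2/M) / (h2/M + c^2 / N)`` of liability variance, where ``c`` is
    the observed->liability beta conversion factor of the training design
    (sampling noise of one observed-scale beta is ``1/N``, i.e. ``c^2/N`` on
    the liability scale).
    """
    c = _obs_scale_factor(K, ascertainment)
    s = h2 / M
    return h2 * s / (s + c * c / n_training)


def required_training_n(
    r2_target: float,
    K: float,
    h2: float = 0.2,
    M: int = 1000,
    ascertainment: str = "5050",
) -> int:
    """Training GWAS size whose expected PGS R^2_liability hits the target.

    Inverts :func:`expected_pgs_r2` in closed form,
    ``N = c^2 M r2 / (h2 (h2 - r2))``, and truncates to an integer (the
    sub-individual remainder is immaterial; the truncated value reproduces the
    conventional power-calculator output).  Diverges as ``r2_target -> h2``.
    """
    if not (0.0 < r2_target < h2):
        raise ValueError("r2_target must lie strictly between 0 and h2")
    c = _obs_scale_factor(K, ascertainment)
    n = c * c * M * r2_target / (h2 * (h2 - r2_target))
    return max(int(n), 2)


# ---------------------------------------------------------------------------
# one simulation run / condition driver


@dataclass
class RunData:
    """Everything one replicate produces before method evaluation."""

    condition: SimCondition
    effects: np.ndarray
    freqs: np.ndarray
    n_training: int
    sumstats: SummaryStats  # posterior-mean betas, obs5050 scale
    reference_pgs_liability: np.ndarray
    testing: CohortSample
    testing_pgs_liability: np.ndarray
    r2_hat: float  # reference-panel variance estimate of R^2_liability
    tuning: CohortSample | None = None
    tuning_pgs_liability: np.ndarray | None = None


def simulate_run(
    cond: SimCondition,
    rng: np.random.Generator,
    with_tuning: bool = False,
    n_tuning_cases: int = 1000,
    n_tuning_controls: int = 1000,
) -> RunData:
    """Simulate one replicate: train GWAS, shrink, score reference + testing.

    Training is a 50/50 case-control sample sized by
    :func:`required_training_n`; posterior-mean betas come from the
    infinitesimal no-LD shrinkage; scoring uses standardized genotypes and
    liability-scale betas.
    """
    from .shrinkage import bpred_posterior_means  # local import to avoid cycle

    from .liability_core import beta_scale_factor

    effects = draw_effects(rng, cond.M, cond.h2)
    freqs = draw_freqs(rng, cond.M, *cond.freq_range)
    n_train = required_training_n(cond.r2_target, cond.K, cond.h2, cond.M)
    half = n_train // 2
    training = simulate_ascertained(
        cond, half, n_train - half, effects, freqs, rng, role="training"
    )
    stats = gwas_obs5050(training)
    c = _obs_scale_factor(cond.K, "5050")
    h2_obs = cond.h2 / (c * c)
    post = bpred_posterior_means(stats, M=cond.M, h2=h2_obs)
    beta_liab = post.betas() * beta_scale_factor(cond.K, 0.5)

    reference = simulate_population(cond, cond.n_reference, effects, freqs, rng, "reference")
    ref_pgs = reference.std_dosages @ beta_liab
    r2_hat = float(np.var(ref_pgs, ddof=1))

    testing = simulate_ascertained(
        cond, cond.n_test_cases, cond.n_test_controls, effects, freqs, rng, "testing"
    )
    test_pgs = testing.std_dosages @ beta_liab

    tuning = tuning_pgs = None
    if with_tuning:
        tuning = simulate_ascertained(
            cond, n_tuning_cases, n_tuning_controls, effects, freqs, rng, "tuning"
        )
        tuning_pgs = tuning.std_dosages @ beta_liab

    return RunData(
        condition=cond,
        effects=effects,
        freqs=freqs,
        n_training=n_train,
        sumstats=post,
        reference_pgs_liability=ref_pgs,
        testing=testing,
        testing_pgs_liability=test_pgs,
        r2_hat=r2_hat,
        tuning=tuning,
        tuning_pgs_liability=tuning_pgs,
    )


def run_condition(
    cond: SimCondition, methods: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates of one condition and aggregate metric means/SEMs.

    ``methods`` defaults to ``["bpc", "pain"]``; see
    :func:`bpcalib.cli_io.evaluate_run` for the method registry.  Returns the
    aggregate long-format frame (method, metric, mean, sem, n_runs) plus the
    per-run wide frame.
    """
    from .cli_io import evaluate_run  # method registry lives with the runner

    methods = methods or ["bpc", "pain"]
    rows = []
    master = np.random.default_rng(cond.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=cond.n_runs)
    needs_tuning = any(m in ("bpc_tuned", "logit_tuned") for m in methods)
    for run_idx, s in enumerate(child_seeds):
        rng = np.random.default_rng(int(s))
        data = simulate_run(cond, rng, with_tuning=needs_tuning)
        res = evaluate_run(data, methods)
        for r in res:
            r["run"] = run_idx
            rows.append(r)
    per_run = pd.DataFrame(rows)
    long = per_run.melt(
        id_vars=["method", "run"], var_name="metric", value_name="value"
    ).dropna(subset=["value"])
    agg = (
        long.groupby(["method", "metric"])["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n_runs="count")
        .reset_index()
    )
    return agg, per_run
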
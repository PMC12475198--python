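"""GWAS summary-statistic handling and no-LD Bayesian posterior-mean betas.

Covers the path from raw GWAS output to liability-scale scoring weights:

- effective sample size, either summed over cohorts
  (``N_eff = 4 / (1/N_case + 1/N_control)`` per cohort) or analytically from
  allele frequency and standard error with a percentile guard against
  outliers;
- conversion of Z-scores to the standardized observed scale with 50% case
  ascertainment (``beta_5050 = z / sqrt(N_eff)``);
- closed-form posterior-mean effects under a point-normal prior in linkage
  equilibrium (the "Bpred" special case of LDpred) — the infinitesimal prior
  ``p_causal = 1`` reduces to a single shrinkage factor
  ``h2 / (h2 + M/N_eff)``;
- PLINK ``--score ... sum center`` scoring of dosage matrices.

Summary statistics travel as a :class:`SummaryStats`: a pandas DataFrame with
canonical column names plus a declared effect-size scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .liability_core import beta_scale_factor

__all__ = [
    "SummaryStats",
    "neff_from_cohorts",
    "neff_analytic",
    "bpred_posterior_means",
    "score_individuals",
    "align_to",
    "read_sumstats",
    "write_sumstats",
]

#: canonical name -> accepted aliases (case-insensitive) in input files
COLUMN_ALIASES = {
    "snp": ("snp", "id", "rsid", "variant_id", "markername"),
    "a1": ("a1", "ea", "effect_allele", "allele1"),
    "a2": ("a2", "oa", "other_allele", "allele2", "nea"),
    "z": ("z", "zscore", "z_score"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "stderr", "standard_error"),
    "af": ("af", "frq", "freq", "eaf", "maf"),
    "n_eff": ("n_eff", "neff", "n"),
    "chr": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position"),
    "info": ("info", "imputation_info", "r2hat"),
}

VALID_SCALES = ("z", "obs5050", "liability")


@dataclass(frozen=True)
class SummaryStats:
    """Per-SNP GWAS results on a declared effect-size scale.

    ``table`` holds canonical columns (``snp, a1, a2`` and whichever of
    ``z, beta, se, af, n_eff, chr, pos, info`` are known); ``scale_tag``
    declares the scale of ``beta`` and transitions only via the conversion
    functions in this module and :mod:`bpcalib.liability_core`.
    """

    table: pd.DataFrame
    scale_tag: str
    n_eff: float | None = None  # study-wide N_eff; per-SNP column wins if present

    def __post_init__(self) -> None:
        if self.scale_tag not in VALID_SCALES:
            raise ValueError(f"scale_tag must be one of {VALID_SCALES}")
        if "snp" not in self.table.columns:
            raise ValueError("summary statistics need an 'snp' column")

    def effective_n(self) -> np.ndarray:
        """Per-SNP effective sample size (column if present, else scalar)."""
        if "n_eff" in self.table.columns:
            return self.table["n_eff"].to_numpy(dtype=float)
        if self.n_eff is None:
            raise ValueError("no effective sample size available")
        return np.full(len(self.table), float(self.n_eff))

    def betas(self) -> np.ndarray:
        if self.scale_tag == "z":
            raise ValueError("betas undefined on the z scale; convert first")
        return self.table["beta"].to_numpy(dtype=float)

    def to_obs5050(self) -> "SummaryStats":
        """Z-scores -> standardized observed scale with 50% case ascertainment."""
        if self.scale_tag == "obs5050":
            return self
        if self.scale_tag != "z":
            raise ValueError(f"cannot convert from scale {self.scale_tag!r}")
        n = self.effective_n()
        tab = self.table.copy()
        tab["beta"] = tab["z"].to_numpy(dtype=float) / np.sqrt(n)
        return replace(self, table=tab, scale_tag="obs5050")

    def to_liability(self, K: float, p: float = 0.5) -> "SummaryStats":
        """Observed-scale (case fraction ``p``) betas -> liability scale."""
        base = self.to_obs5050() if self.scale_tag == "z" else self
        if base.scale_tag != "obs5050":
            raise ValueError(f"cannot convert from scale {base.scale_tag!r}")
        tab = base.table.copy()
        tab["beta"] = tab["beta"].to_numpy(dtype=float) * beta_scale_factor(K, p)
        return replace(base, table=tab, scale_tag="liability")


def neff_from_cohorts(case_counts, control_counts) -> float:
    """Total effective sample size of a meta-analysis.

    ``sum_c 4 / (1/N_case_c + 1/N_control_c)`` over contributing cohorts; a
    balanced cohort contributes its total N.
    """
    cases = np.asarray(case_counts, dtype=float)
    controls = np.asarray(control_counts, dtype=float)
    if cases.size == 0 or cases.shape != controls.shape:
        raise ValueError("need equal-length, non-empty case and control counts")
    if np.any(cases <= 0) or np.any(controls <= 0):
        raise ValueError("cohort counts must be positive")
    return float(np.sum(4.0 / (1.0 / cases + 1.0 / controls)))


def neff_analytic(af, se, quantile: float = 0.90, per_snp: bool = False):
    """Effective sample size from allele frequency and standard error.

    Per SNP, ``N_eff = 4 / (2 * AF * (1-AF) * SE^2)``.  Because this estimate
    can produce large outliers, the study-wide value returned is a percentile
    (default 90th, linear interpolation between order statistics) across SNPs
    rather than the maximum.  Set ``per_snp=True`` to get the per-SNP values.
    """
    af = np.asarray(af, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any((af <= 0) | (af >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    n = 4.0 / (2.0 * af * (1.0 - af) * se**2)
    if per_snp:
        return n
    return float(np.quantile(n, quantile))


def bpred_posterior_means(
    stats: SummaryStats, M: int, h2: float, p_causal: float = 1.0
) -> SummaryStats:
    """Posterior-mean betas under a point-normal prior in linkage equilibrium.

    The marginal estimate for SNP j is ``beta_hat_j ~ N(beta_j, 1/N_j)`` with
    prior ``beta_j ~ N(0, h2/(M p_causal))`` w.p. ``p_causal``, else 0.  The
    posterior mean is

        E[beta_j | beta_hat_j] = pbar_j * v/(v + 1/N_j) * beta_hat_j,

    with ``v = h2/(M p_causal)`` and ``pbar_j`` the posterior causal
    probability from the two marginal Gaussian likelihoods.  With
    ``p_causal = 1`` this is the infinitesimal shrinkage
    ``h2/(h2 + M/N_j) * beta_hat_j``.

    ``h2`` must be on the same (observed 50/50) scale as the betas.
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    if not (0.0 < p_causal <= 1.0):
        raise ValueError("p_causal must lie in (0, 1]")
    base = stats.to_obs5050()
    bhat = base.betas()
    n = base.effective_n()
    v = h2 / (M * p_causal)
    shrink = v / (v + 1.0 / n)
    if p_causal < 1.0:
        # posterior causal probability from the two marginal likelihoods
        s1 = np.sqrt(v + 1.0 / n)
        s0 = np.sqrt(1.0 / n)
        log_l1 = -0.5 * (bhat / s1) ** 2 - np.log(s1)
        log_l0 = -0.5 * (bhat / s0) ** 2 - np.log(s0)
        logits = np.log(p_causal / (1.0 - p_causal)) + log_l1 - log_l0
        pbar = 1.0 / (1.0 + np.exp(-logits))
    else:
        pbar = 1.0
    tab = base.table.copy()
    tab["beta"] = pbar * shrink * bhat
    return replace(base, table=tab)


def score_individuals(
    dosages: np.ndarray,
    betas: np.ndarray,
    freqs: np.ndarray | None = None,
    standardized: bool = False,
) -> np.ndarray:
    """Per-individual PGS with PLINK ``--score ... sum center`` semantics.

    ``PGS_i = sum_j beta_j * (g_ij - 2 f_j)`` for allele-count dosages, or
    ``sum_j beta_j * g_ij`` when ``standardized=True`` and the matrix already
    holds standardized genotypes.  Columns must be aligned to ``betas`` rows.
    """
    dosages = np.asarray(dosages)
    betas = np.asarray(betas, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != betas.shape[0]:
        raise ValueError(
            f"dosage matrix has {dosages.shape[1] if dosages.ndim == 2 else '?'} "
            f"columns but {betas.shape[0]} betas were given"
        )
    if standardized:
        return dosages @ betas
    if freqs is None:
        raise ValueError("allele frequencies required for centered scoring")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != betas.shape[0]:
        raise ValueError("freqs and betas must align")
    # sum of beta*(g - 2f) = G@beta - constant, avoids materializing centered G
    return dosages @ betas - 2.0 * float(freqs @ betas)


def align_to(stats: SummaryStats, snp_ids) -> SummaryStats:
    """Reorder summary statistics to a target SNP-id sequence.

    Raises with the offending identifiers when the target contains SNPs the
    statistics do not cover (dosage columns must never be scored against
    betas for different variants).
    """
    idx = pd.Index(stats.table["snp"])
    target = pd.Index(snp_ids)
    missing = target.difference(idx)
    if len(missing):
        raise ValueError(f"SNPs absent from summary statistics: {list(missing)[:10]}")
    order = idx.get_indexer(target)
    tab = stats.table.iloc[order].reset_index(drop=True)
    return replace(stats, table=tab)


# ---------------------------------------------------------------------------
# I/O: whitespace/tab-delimited summary statistics with header aliases


def _canonical_columns(columns) -> dict[str, str]:
    mapping = {}
    for col in columns:
        low = col.lower()
        for canon, aliases in COLUMN_ALIASES.items():
            if low in aliases and canon not in mapping.values():
                mapping[col] = canon
                break
    return mapping


def read_sumstats(
    path_or_buf, scale_tag: str = "z", n_eff: float | None = None
) -> SummaryStats:
    """Read whitespace/tab-delimited GWAS summary statistics.

    Header names are matched case-insensitively against common aliases
    (SNP/ID, A1/EA, Z, BETA, SE, FRQ/AF, N_EFF, ...).
    """
    df = pd.read_csv(path_or_buf, sep=r"\s+")
    df = df.rename(columns=_canonical_columns(df.columns))
    return SummaryStats(table=df, scale_tag=scale_tag, n_eff=n_eff)


def write_sumstats(stats: SummaryStats, path_or_buf) -> None:
    """Write summary statistics as tab-delimited text with canonical headers."""
    stats.table.to_csv(path_or_buf, sep="\t", index=False)


def write_score_file(stats: SummaryStats, path_or_buf) -> None:
    """Write a PLINK ``--score``-compatible file: variant id, effect allele, beta."""
    cols = ["snp", "a1", "beta"]
    missing = [c for c in cols if c not in stats.table.columns]
    if missing:
        raise ValueError(f"missing columns for score file: {missing}")
    stats.table[cols].to_csv(path_or_buf, sep="\t", index=False, header=True)


def read_score_file(path_or_buf, scale_tag: str = "liability") -> SummaryStats:
    df = pd.read_csv(path_or_buf, sep=r"\s+")
    df = df.rename(columns=_canonical_columns(df.columns))
    return SummaryStats(table=df, scale_tag=scale_tag)
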
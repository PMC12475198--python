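# Methods

## Model and assumptions

The package works under the liability threshold model: a binary disorder with
population lifetime prevalence `K` arises when a latent liability
`L ~ N(0, 1)` exceeds `T = Φ⁻¹(1 − K)`; `z = φ(T)` denotes the normal density
at the threshold. A polygenic score on the liability scale is assumed jointly
normal with `L`, with population variance equal to the variance it explains
(`R²_liability`). Everything downstream is exact normal-mixture arithmetic:

- **Case/control PGS moments.** Truncating the bivariate (L, PGS) normal at
  `T` gives `μ_case = R²·z/K`, `μ_control = −R²·z/(1−K)`,
  `var_case = R²(1 − R²·i₁(i₁ − T))` with `i₁ = z/K`, and
  `var_control = R²(1 − R²·i₀(i₀ + T))` with `i₀ = z/(1−K)`. These are not
  transcribed from anywhere: they are derived from the standard
  truncated-normal results and certified in the test suite against numerical
  integration to 1e−8 on a grid of `K` and `R²`, together with the mixture
  identity `K(var₁ + μ₁²) + (1−K)(var₀ + μ₀²) − mean² = R²`. For `K < 0.5`
  the case variance is strictly the smaller one; the Bayes conversion keeps
  that asymmetry while the quantile comparator assumes it away.
- **Scale conversions.** Betas estimated on the standardized observed scale in
  a sample with case fraction `p` map linearly to the liability scale by
  `K(1−K)/(z·p)`. The observed↔liability `R²` conversion for ascertained
  case-control samples uses the exact ascertainment-aware transformation
  (constants `C = [K(1−K)]²/(z²·P(1−P))` and
  `θ = m(P−K)/(1−K)·(m(P−K)/(1−K) − T)`, `m = z/K`); both directions are
  implemented and round-trip to 1e−10.
- **Bayes update.** `P(case|PGS)` follows from the prior and the two
  conditional normal densities. The prior is the case probability of the
  individual's context (e.g. the clinic's case mix), a free input distinct
  from `K`; per-individual prior vectors are accepted for context-specific
  priors. The posterior integrates back to the prior over the prior-weighted
  mixture (law of total probability; tested to 1e−8) and is invariant to any
  affine rescaling applied consistently to the PGS and the mixture
  parameters.

Normality of the PGS within cases and controls is an assumption, not a
theorem; it holds to good accuracy for polygenic architectures at realistic
`R²_liability` and fails in the presence of outlying large-effect variants,
which should be excluded before use (the QC path drops the MHC for this
reason).

## Posterior-mean effect sizes (no-LD)

GWAS Z-scores are placed on the standardized observed scale with 50% case
ascertainment via `β₅₀/₅₀ = z/√N_eff`. The effective sample size is taken, in
order of preference: from a per-SNP column; as `Σ_c 4/(1/N_case,c +
1/N_ctrl,c)` over cohorts; or analytically as `4/(2·AF(1−AF)·SE²)` using the
90th percentile across SNPs (linear-interpolation quantile, configurable)
because the analytic form produces large outliers.

Shrinkage assumes linkage equilibrium with a point-normal prior: causal with
probability `p_causal`, effect variance `h²/(M·p_causal)`. The posterior mean
has the closed form `p̄ⱼ · v/(v + 1/Nⱼ) · β̂ⱼ`, quadrature-tested, and the
default is the infinitesimal prior `p_causal = 1` (the simulation draws every
SNP's effect from a normal, so the infinitesimal model is the matched prior;
the causal fraction used by the original no-LD shrinkage in the emulated
study is not stated, and `p_causal` is exposed for sensitivity analysis).
`h²` must be supplied on the same observed scale as the betas; the simulator
converts its liability-scale `h² = 0.2` by the squared beta-scale factor.

## Simulator: what it emulates and what it does not

Each replicate draws `M = 1000` LE SNPs with frequencies
`f ~ Uniform(0.05, 0.5)` (the emulated design does not state a frequency
distribution; this range matches the MAF ≥ 10% QC regime while exercising
frequency variation and is configurable), standardized-scale effects
`β ~ N(0, h²/M)` with `h² = 0.2`, and three independent cohorts sharing those
draws: a 50/50 case-control training sample whose size comes from the power
solver below, a population reference panel of `N = 503`, and a testing sample
of 1000 cases/1000 controls (configurable, e.g. 1500/500 for a 0.75 case
ratio). Genotypes are `Binomial(2, f)` draws implemented as one uniform
variate against the cumulative Hardy–Weinberg probabilities; ascertained
cohorts are collected by blockwise rejection sampling with adaptive block
sizes, so exact counts are met at bounded memory even at `K = 0.01`. The
GWAS is the marginal correlation `z = corr(status, g)·√N` with both variables
standardized within the sample.

Not emulated: linkage disequilibrium (by design — LD does not change the
scale of a score that sums all SNP effects), covariates, age structure,
non-normal effect-size distributions, imputation error. Passing tests
therefore certify the probability machinery and its calibration under the
stated generative model, not robustness to real-data artifacts such as LD
mismatch or stratification.

**Training-size solver.** The expected liability-scale `R²` of the
posterior-mean PGS under this design is `h²·s/(s + c²/N)` with `s = h²/M` and
`c` the observed→liability beta factor (`2K(1−K)/z` for 50/50 training,
`√(K(1−K))/z` for random ascertainment). Inverting gives
`N = c²·M·R²/(h²(h² − R²))`, truncated to an integer — reproducing the
conventional power-calculator output (2759 at `R² = 0.10`, `K = 0.01`); the
solver is also verified against the simulator itself.

## Comparator conventions

The quantile comparator converts `R²` to AUC via the normal-theory moments
(pooling the two conditional variances with equal weight, so the AUC is exact
for the unequal-variance normal model), places two unit-variance normals
`d = √2·Φ⁻¹(AUC)` apart, and assigns each individual the Bayes posterior at
the mass midpoint of the mixture quantile containing its reference-
standardized Z-value. `n_quantiles` defaults to 1000 (the emulated method's
bin count is not published; convergence to the continuous Bayes formula is
the correctness anchor, and `n_quantiles = 0` selects the continuous limit).
The faithful mode centers the mixture by the *target* weights while
standardizing by the *population* — the documented bias mechanism — whereas
the adjusted mode centers by the population weights.

The external lassosum `R²` estimator used by the original quantile method is
out of scope; the comparator takes `R²` as an input, and the experiment
driver feeds it the reference-panel variance estimate. Consequence: the
published worst-case miscalibration of the faithful method (driven by the
population-standardization bias) reproduces, but its published *best*-case
ICI of ≈0.04 does not — that figure is partly lassosum estimation noise at
`R² = 0.01`, and with an accurate `R²` input the faithful method's best
condition sits near the ICI noise floor (≈0.02) instead.

The linear rescaling alternative maps the liability PGS affinely to the 0/1
scale (variance matched to the observed-scale `R²` at the target case
fraction, then `PGS'·√(P(1−P)) + P`); out-of-range values are truncated to
[0, 1] *after* the probabilities are formed and before calibration is
evaluated. Tuning-sample variants: empirical case/control moments
(`bpc_tuned`, needing ≥2 per class) and univariate logistic regression
(`logit_tuned`).

## Metrics

The Integrated Calibration Index smooths the binary outcome on the predicted
probabilities with a local polynomial regression in the R `loess` dialect —
tricube weights over the nearest `⌈0.75·n⌉` points, degree 2, gaussian
family, exact (direct) evaluation — and averages `|smooth(pᵢ) − pᵢ|` over
observations, which weights by the density of the predictions. The smoother
is written in-package (no installed Python smoother offers degree-2 loess)
and is tested against R's `loess(..., surface="direct")` to 1e−6. Span and
degree are configurable; a grid-averaged ICI variant exists for sensitivity.
Degenerate constant predictions fall back to `|mean(y) − p|` with a warning.
A small ridge (1e−10 relative) keeps near-singular local fits solvable;
fitted values are not clipped to [0, 1].

Calibration slope/intercept are OLS of the outcome on the prediction —
evaluated on probabilities for converted methods and on the raw PGS for the
untransformed score. AUC is the midrank Mann–Whitney statistic. The
regression-based `R²_liability` converts the observed-scale squared
correlation through the ascertainment-aware transformation.

## Problem sizes and numerical choices

The emulated study uses 100 replicates per condition. The acceptance script
runs the grid at 32 replicates per condition, the doubled-M robustness check
at 20, the random-ascertainment experiment and the high-prior
likelihood-ratio analysis at 25 each; the test suite uses 5–10 replicates
with 3-standard-error sampling bands. These sizes keep a full desk-scale
reproduction around a quarter hour on one CPU; measured standard errors at
these counts are small relative to the quantities compared (e.g. ≈0.001 for
mean ICIs near 0.015).

Other fixed choices: reference-panel variance uses the `n − 1` denominator
(immaterial at N = 503); per-run child seeds are drawn from a master
generator so every report is bit-reproducible given the master seed; the
random-ascertainment experiment regresses the within-sample standardized
status on the PGS (slope 1 is the calibration target on that scale) with a
testing sample of 2000; monomorphic SNPs get `z = 0` with a warning;
harmonization drops ambiguous-strand SNPs unconditionally rather than
attempting frequency-based strand inference.
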
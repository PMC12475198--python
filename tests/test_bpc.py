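"""Bayes conversion, tuning variants, linear rescaling."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from bpcalib.bpc import (
    BpcModel,
    bpc_model_from_reference,
    bpc_posterior,
    bpc_tuned,
    estimate_r2_liability,
    likelihood_ratio_sd,
    linear_rescale,
    logit_tuned,
)
from bpcalib.liability_core import (
    LiabilityConfig,
    PgsDistribution,
    casecontrol_pgs_moments,
)


def theory_model(K, r2, prior):
    return BpcModel(
        config=LiabilityConfig(K=K),
        r2_liability_hat=r2,
        dist=casecontrol_pgs_moments(r2, K),
        prior=prior,
        source_tag="theory",
    )


class TestR2Estimator:
    def test_constant_pgs(self):
        assert estimate_r2_liability(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-30)

    def test_too_few(self):
        with pytest.raises(ValueError):
            estimate_r2_liability(np.array([1.0]))

    def test_known_generating_variance(self, rng):
        pgs = rng.normal(0, np.sqrt(0.07), 503)
        est = estimate_r2_liability(pgs)
        # chi-square sampling band for a variance at n=503
        assert est == pytest.approx(0.07, abs=3 * 0.07 * np.sqrt(2 / 502))


class TestPosterior:
    def test_null_r2_returns_prior(self):
        m = theory_model(0.15, 0.0, 0.37)
        np.testing.assert_allclose(bpc_posterior(np.linspace(-1, 1, 9), m), 0.37)

    def test_equal_density_point(self):
        # symmetric case: K = 0.5 makes the mixture symmetric around 0
        m = theory_model(0.5, 0.1, 0.5)
        assert bpc_posterior(0.0, m)[0] == pytest.approx(0.5, abs=1e-12)

    def test_hand_evaluated_example(self):
        K, r2, prior = 0.01, 0.05, 0.5
        d = casecontrol_pgs_moments(r2, K)
        m = theory_model(K, r2, prior)
        x = d.mu_case
        f1 = norm.pdf(x, d.mu_case, np.sqrt(d.var_case))
        f0 = norm.pdf(x, d.mu_control, np.sqrt(d.var_control))
        expected = prior * f1 / (prior * f1 + (1 - prior) * f0)
        assert bpc_posterior(x, m)[0] == pytest.approx(expected, rel=1e-12)
        assert 0.5 < expected < 1.0  # a case-mean PGS raises the probability

    @pytest.mark.parametrize("prior", [0.25, 0.5, 0.75])
    def test_posterior_averages_to_prior(self, prior):
        """Law of total probability over the prior-weighted mixture."""
        m = theory_model(0.01, 0.15, prior)
        d = m.dist

        def mix(x):
            return prior * norm.pdf(x, d.mu_case, np.sqrt(d.var_case)) + (
                1 - prior
            ) * norm.pdf(x, d.mu_control, np.sqrt(d.var_control))

        val = quad(lambda x: bpc_posterior(x, m)[0] * mix(x), -3, 3, epsabs=1e-12)[0]
        assert val == pytest.approx(prior, abs=1e-8)

    def test_affine_invariance(self, rng):
        """Rescaling PGS and mixture parameters together leaves posteriors fixed."""
        K, r2, prior = 0.15, 0.1, 0.4
        m = theory_model(K, r2, prior)
        pgs = rng.normal(0, 0.3, 50)
        a, b = 2.7, -0.4
        d = m.dist
        m2 = BpcModel(
            config=m.config,
            r2_liability_hat=r2,
            dist=PgsDistribution(
                mu_case=a * d.mu_case + b,
                var_case=a**2 * d.var_case,
                mu_control=a * d.mu_control + b,
                var_control=a**2 * d.var_control,
                p_case=d.p_case,
            ),
            prior=prior,
            source_tag="theory",
        )
        np.testing.assert_allclose(
            bpc_posterior(pgs, m), bpc_posterior(a * pgs + b, m2), rtol=1e-10
        )

    def test_strictly_inside_unit_interval(self, rng):
        m = theory_model(0.01, 0.15, 0.5)
        p = bpc_posterior(rng.normal(0, 0.5, 1000), m)
        assert np.all((p > 0) & (p < 1))


class TestLikelihoodRatio:
    def test_null_r2_zero_sd(self, rng):
        m = theory_model(0.15, 0.0, 0.5)
        assert likelihood_ratio_sd(rng.normal(size=100), m) == 0.0

    def test_dispersion_grows_with_r2(self, rng):
        draws = rng.normal(0, 0.3, 2000)
        sds = [likelihood_ratio_sd(draws, theory_model(0.15, r2, 0.5))
               for r2 in (0.01, 0.05, 0.15)]
        assert sds[0] < sds[1] < sds[2]


class TestTuned:
    def test_moment_recovery(self, rng):
        mu1, s1, mu0, s0 = 0.2, 0.25, -0.05, 0.3
        n = 100_000
        pgs = np.concatenate([rng.normal(mu1, s1, n), rng.normal(mu0, s0, n)])
        y = np.repeat([1, 0], n)
        m = bpc_tuned(pgs, y, prior=0.5)
        assert m.dist.mu_case == pytest.approx(mu1, abs=3 * s1 / np.sqrt(n))
        assert m.dist.var_case == pytest.approx(s1**2, rel=0.02)
        assert m.dist.mu_control == pytest.approx(mu0, abs=3 * s0 / np.sqrt(n))
        assert m.source_tag == "tuned"

    def test_identical_classes_return_prior(self, rng):
        x = rng.normal(0, 1, 1000)
        pgs = np.concatenate([x, x])
        y = np.repeat([1, 0], 1000)
        m = bpc_tuned(pgs, y, prior=0.3)
        np.testing.assert_allclose(bpc_posterior(np.linspace(-2, 2, 7), m), 0.3, atol=1e-12)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            bpc_tuned(rng.normal(size=10), np.ones(10), 0.5)

    def test_agrees_with_theory_on_simulated_data(self, rng):
        """Large tuning sample: empirical and normal-theory posteriors agree."""
        K, r2, prior = 0.15, 0.10, 0.5
        d = casecontrol_pgs_moments(r2, K)
        n = 20_000
        tune_pgs = np.concatenate([
            rng.normal(d.mu_case, np.sqrt(d.var_case), n),
            rng.normal(d.mu_control, np.sqrt(d.var_control), n),
        ])
        tune_y = np.repeat([1, 0], n)
        tuned = bpc_tuned(tune_pgs, tune_y, prior)
        theory = theory_model(K, r2, prior)
        test_pgs = rng.normal(0, np.sqrt(r2), 2000)
        diff = np.abs(bpc_posterior(test_pgs, tuned) - bpc_posterior(test_pgs, theory))
        assert diff.mean() < 0.02


class TestLinearRescale:
    def test_null_r2(self, rng):
        m = theory_model(0.15, 0.0, 0.4)
        np.testing.assert_allclose(linear_rescale(rng.normal(size=20), 0.4, m), 0.4)

    def test_centering(self):
        """Outputs centered at the prior when the sample mean sits at the mixture mean."""
        K, r2, prior = 0.15, 0.1, 0.4
        m = theory_model(K, r2, prior)
        d = m.dist
        mix_mean = prior * d.mu_case + (1 - prior) * d.mu_control
        pgs = mix_mean + np.linspace(-0.2, 0.2, 11)  # symmetric around mixture mean
        out = linear_rescale(pgs, prior, m, truncate=False)
        assert out.mean() == pytest.approx(prior, abs=1e-12)

    def test_truncation_at_low_prevalence_high_r2(self, rng):
        K, r2, prior = 0.01, 0.15, 0.5
        m = theory_model(K, r2, prior)
        d = m.dist
        pgs = np.concatenate([
            rng.normal(d.mu_case, np.sqrt(d.var_case), 1000),
            rng.normal(d.mu_control, np.sqrt(d.var_control), 1000),
        ])
        raw = linear_rescale(pgs, prior, m, truncate=False)
        assert np.sum((raw < 0) | (raw > 1)) > 0
        clipped = linear_rescale(pgs, prior, m)
        assert clipped.min() >= 0.0 and clipped.max() <= 1.0


class TestLogitTuned:
    def test_coefficient_recovery(self, rng):
        b0, b1 = -0.5, 2.0
        n = 50_000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(b0 + b1 * x)))
        y = (rng.random(n) < p).astype(float)
        test_x = np.array([(0.5 - b0) / b1])  # the fitted 50% point if recovery is exact
        probs = logit_tuned(x, y, test_x)
        # recovery within sampling error shows up as prob near the true model's value
        assert probs[0] == pytest.approx(1 / (1 + np.exp(-0.5)), abs=0.02)

    def test_fitted_midpoint_is_half(self, rng):
        x = rng.normal(0, 1, 5000)
        y = (rng.random(5000) < 1 / (1 + np.exp(-x))).astype(float)
        import statsmodels.api as sm

        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        mid = -fit.params[0] / fit.params[1]
        assert logit_tuned(x, y, np.array([mid]))[0] == pytest.approx(0.5, abs=1e-9)

    def test_constant_pgs_intercept_only(self, rng):
        y = (rng.random(200) < 0.3).astype(float)
        probs = logit_tuned(np.full(200, 1.7), y, np.array([1.7, 0.0]))
        np.testing.assert_allclose(probs, y.mean())

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            logit_tuned(rng.normal(size=20), np.zeros(20), np.zeros(3))


class TestModelFromReference:
    def test_calibration_in_the_large(self, rng):
        """Mean posterior matches the case fraction when the prior is correct."""
        K, r2 = 0.15, 0.1
        d = casecontrol_pgs_moments(r2, K)
        n1, n0 = 600, 600
        pgs = np.concatenate([
            rng.normal(d.mu_case, np.sqrt(d.var_case), n1),
            rng.normal(d.mu_control, np.sqrt(d.var_control), n0),
        ])
        ref = rng.normal(0, np.sqrt(r2), 503)
        model = bpc_model_from_reference(ref, K, prior=0.5)
        post = bpc_posterior(pgs, model)
        assert post.mean() == pytest.approx(0.5, abs=0.03)
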
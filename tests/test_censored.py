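"""Bayesian censored-lognormal model: likelihood, sampler, posterior mean."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from bpdrisk import (
    CensoredCount,
    InsufficientDataError,
    McmcSettings,
    PosteriorDraws,
    PriorSpec,
    ResidueScenario,
    ValidationError,
    censoring_probability,
    expected_concentration,
    fit_mcmc,
    generate_residues,
    log_posterior,
    posterior_mean_concentration,
    sample_concentration,
)
from bpdrisk.censored import split_rhat


class TestCensoringProbability:
    def test_pure_zero_inflation_gives_one(self):
        assert censoring_probability(1.0, 5.0, 0.3, 0.01) == pytest.approx(1.0)

    def test_lod_at_median_gives_half_the_positives(self):
        # mu = ln(lod) makes Phi(alpha) = 0.5
        assert censoring_probability(0.2, math.log(2.0), 0.7, 2.0) == pytest.approx(0.6)

    def test_matches_quadrature_of_mixture_cdf(self):
        p0, mu, sigma, lod = 0.1, 1.0, 0.5, 1.0
        # mixture CDF at lod: p0 (atom at zero) + (1-p0) * integral of lognormal pdf
        dens = lambda c: stats.lognorm.pdf(c, s=sigma, scale=np.exp(mu))
        integral, _ = integrate.quad(dens, 0, lod)
        expected = p0 + (1 - p0) * integral
        assert censoring_probability(p0, mu, sigma, lod) == pytest.approx(expected, rel=1e-8)

    def test_nondecreasing_in_lod_and_p0_with_limits(self):
        mu, sigma = 1.0, 0.5
        lods = np.logspace(-4, 4, 40)
        probs = [censoring_probability(0.3, mu, sigma, l) for l in lods]
        assert np.all(np.diff(probs) >= 0)
        assert probs[0] == pytest.approx(0.3, abs=1e-6)  # lod -> 0: only true zeros
        assert probs[-1] == pytest.approx(1.0, abs=1e-6)  # lod -> inf: everything censored
        p0s = np.linspace(0, 1, 20)
        probs_p = [censoring_probability(p, mu, sigma, 1.0) for p in p0s]
        assert np.all(np.diff(probs_p) >= 0)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValidationError):
            censoring_probability(0.1, 0.0, 0.0, 1.0)


class TestLogPosterior:
    def test_no_data_equals_sum_of_log_priors(self):
        data = CensoredCount(n_total=0, observed_log_values=np.empty(0), lods=np.empty(0))
        pr = PriorSpec()
        p0, mu, sigma = 0.3, 1.0, 0.8
        expected = (
            stats.beta.logpdf(p0, 1, 1)
            + stats.norm.logpdf(mu, 0, 0.01**-0.5)
            + stats.gamma.logpdf(sigma**-2, 0.1, scale=10.0)
        )
        assert log_posterior((p0, mu, sigma), data, pr) == pytest.approx(expected)

    def test_all_detected_censoring_terms_vanish_as_p0_to_zero(self):
        data = CensoredCount.from_values([1.0, 2.0, 3.0], 0, 0.001)
        pr = PriorSpec()
        # as p0 -> 0 the detected-data terms converge to the plain lognormal likelihood
        lp_small = log_posterior((1e-12, 0.5, 0.7), data, pr)
        plain = float(np.sum(stats.norm.logpdf(np.log([1.0, 2.0, 3.0]), 0.5, 0.7)))
        priors = (
            stats.beta.logpdf(1e-12, 1, 1)
            + stats.norm.logpdf(0.5, 0, 0.01**-0.5)
            + stats.gamma.logpdf(0.7**-2, 0.1, scale=10.0)
        )
        assert lp_small == pytest.approx(plain + priors, rel=1e-9)

    def test_matches_term_by_term_hand_sum_on_tiny_dataset(self):
        # N=5: detected {e^1, e^2, e^3}, 2 non-detects at LODs 0.5 and 0.8
        data = CensoredCount.from_values([math.e, math.e**2, math.e**3], 2, [0.5, 0.8])
        p0, mu, sigma = 0.25, 1.5, 0.9
        pr = PriorSpec()
        hand = 0.0
        for y in (1.0, 2.0, 3.0):
            hand += math.log(1 - p0) + stats.norm.logpdf(y, mu, sigma)
        for lod in (0.5, 0.8):
            hand += math.log(p0 + (1 - p0) * stats.norm.cdf((math.log(lod) - mu) / sigma))
        hand += stats.beta.logpdf(p0, 1, 1)
        hand += stats.norm.logpdf(mu, 0, 0.01**-0.5)
        hand += stats.gamma.logpdf(sigma**-2, 0.1, scale=10.0)
        assert log_posterior((p0, mu, sigma), data, pr) == pytest.approx(hand, rel=1e-10)

    def test_incompatible_boundary_returns_neg_inf_not_exception(self):
        data = CensoredCount.from_values([1.0, 2.0], 0, 0.001)
        assert log_posterior((1.0, 0.0, 1.0), data) == -np.inf
        assert log_posterior((0.5, 0.0, -1.0), data) == -np.inf


class TestFitMcmc:
    def test_recovers_generating_parameters(self):
        truth = dict(p0=0.10, mu=1.0, sigma=0.5)
        sc = ResidueScenario(analyte="BP", food_category="f", lod=0.5, n_samples=1000, **truth)
        ds = generate_residues([sc], seed=21)
        counts = CensoredCount.from_dataset(ds, "BP", "f")
        draws = fit_mcmc(counts, settings=McmcSettings(n_iterations=6000, n_burn_in=2000, seed=22))
        for name, vec in (("p0", draws.p0), ("mu", draws.mu), ("sigma", draws.sigma)):
            post_mean, post_sd = vec.mean(), vec.std(ddof=1)
            assert abs(post_mean - truth[name]) < 3 * post_sd, name

    def test_retains_expected_draw_count_and_is_seed_reproducible(self, uncensored_counts):
        s = McmcSettings(n_iterations=600, n_burn_in=100, n_chains=2, seed=5)
        a = fit_mcmc(uncensored_counts, settings=s)
        b = fit_mcmc(uncensored_counts, settings=s)
        assert len(a) == 2 * 500
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.p0, b.p0)
        assert split_rhat(a.mu) < 1.05

    def test_all_nondetect_warns_but_returns_draws(self):
        data = CensoredCount(n_total=20, observed_log_values=np.empty(0), lods=np.full(20, 0.5))
        with pytest.warns(UserWarning, match="weakly identified"):
            draws = fit_mcmc(data, settings=McmcSettings(n_iterations=500, n_burn_in=100, seed=1))
        assert len(draws) == 400
        assert np.all((draws.p0 >= 0) & (draws.p0 <= 1))

    def test_mu_posterior_matches_normal_conjugate_closed_form(self, uncensored_counts):
        """Sigma clamped, no censoring: mu | y is exactly Normal."""
        pr = PriorSpec()
        sigma = 0.5
        draws = fit_mcmc(
            uncensored_counts,
            pr,
            McmcSettings(n_iterations=14_000, n_burn_in=4_000, seed=9),
            fix_sigma=sigma,
        )
        y = uncensored_counts.observed_log_values
        prec = pr.mu_precision + y.size / sigma**2
        mean = (y.sum() / sigma**2) / prec
        ks = stats.kstest(draws.mu, "norm", args=(mean, prec**-0.5))
        assert ks.statistic < 0.05

    def test_p0_posterior_matches_beta_closed_form(self):
        """mu, sigma clamped and LOD so small every non-detect is a true zero."""
        rng = np.random.default_rng(3)
        vals = np.exp(rng.normal(2.0, 0.5, 40))
        data = CensoredCount.from_values(vals, 10, 1e-6)
        draws = fit_mcmc(
            data, settings=McmcSettings(n_iterations=14_000, n_burn_in=4_000, seed=11), fix_mu=2.0, fix_sigma=0.5
        )
        ks = stats.kstest(draws.p0, "beta", args=(1 + 10, 1 + 40))
        assert ks.statistic < 0.05

    def test_no_nondetects_shrinks_p0_below_prior_mean_and_with_n(self):
        pr = PriorSpec()
        post_means = []
        for n in (10, 100):
            rng = np.random.default_rng(n)
            vals = np.exp(rng.normal(1.0, 0.4, n))
            data = CensoredCount.from_values(vals, 0, 1e-6)
            draws = fit_mcmc(data, pr, McmcSettings(n_iterations=4000, n_burn_in=1000, seed=n))
            post_means.append(draws.p0.mean())
        assert post_means[0] < 0.5  # below the Beta(1,1) prior mean
        assert post_means[1] < post_means[0]  # and decreasing with N


class TestPosteriorMean:
    def test_degenerate_all_zero_mixture(self):
        d = PosteriorDraws(
            p0=np.array([1.0]), mu=np.array([0.0]), sigma=np.array([1.0]), chain=np.zeros(1, int), iteration=np.zeros(1, int)
        )
        assert posterior_mean_concentration(d).mean_c1 == 0.0

    def test_degenerate_unit_concentration(self):
        d = PosteriorDraws(
            p0=np.array([0.0]), mu=np.array([0.0]), sigma=np.array([1e-4]), chain=np.zeros(1, int), iteration=np.zeros(1, int)
        )
        assert posterior_mean_concentration(d).mean_c1 == pytest.approx(1.0, rel=1e-6)

    def test_empty_draws_raise(self):
        d = PosteriorDraws(p0=np.empty(0), mu=np.empty(0), sigma=np.empty(0), chain=np.empty(0, int), iteration=np.empty(0, int))
        with pytest.raises(InsufficientDataError):
            posterior_mean_concentration(d)

    def test_draw_average_at_least_plug_in_under_sigma_uncertainty(self, uncensored_counts):
        draws = fit_mcmc(uncensored_counts, settings=McmcSettings(n_iterations=4000, n_burn_in=1000, seed=17))
        dist = posterior_mean_concentration(draws)
        # Jensen: E over draws of exp(sigma^2/2) exceeds exp at averaged params
        assert dist.mean_c1 >= dist.plug_in * 0.999

    def test_plug_in_formula(self):
        assert expected_concentration(0.016, 3.53, 0.42) == pytest.approx(36.67, abs=0.05)


class TestSampleConcentration:
    def _point_draws(self, p0, mu, sigma):
        return PosteriorDraws(
            p0=np.array([p0]), mu=np.array([mu]), sigma=np.array([sigma]), chain=np.zeros(1, int), iteration=np.zeros(1, int)
        )

    def test_all_zero_when_p0_one(self):
        out = sample_concentration(self._point_draws(1.0, 0.0, 1.0), 100, seed=0)
        assert np.all(out == 0.0)

    def test_near_constant_when_degenerate_lognormal(self):
        out = sample_concentration(self._point_draws(0.0, 0.0, 1e-6), 100, seed=0)
        assert np.allclose(out, 1.0, atol=1e-4)

    def test_empirical_mean_matches_posterior_mean_concentration(self, uncensored_counts):
        draws = fit_mcmc(uncensored_counts, settings=McmcSettings(n_iterations=4000, n_burn_in=1000, seed=23))
        dist = posterior_mean_concentration(draws)
        n = 100_000
        samples = sample_concentration(draws, n, seed=25)
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(samples.mean() - dist.mean_c1) < 3 * se


class TestPersistence:
    def test_draws_round_trip_csv(self, tmp_path, uncensored_counts):
        draws = fit_mcmc(uncensored_counts, settings=McmcSettings(n_iterations=500, n_burn_in=200, seed=2))
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        back = PosteriorDraws.from_csv(path)
        assert np.allclose(back.mu, draws.mu)
        assert np.array_equal(back.chain, draws.chain)
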
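"""Monte-Carlo intake simulation: C2 fits, EDI draws, totals, quantiles."""

import numpy as np
import pytest
from scipy import stats

from bpdrisk import (
    CensoredCount,
    ConsumptionProfile,
    EdiDraws,
    InsufficientDataError,
    LogNormalFit,
    ValidationError,
    fit_c2_distribution,
    percentile,
    simulate_edi,
    total_edi,
)
from bpdrisk.exposure import lognormal_params_from_mean_sd


def _profile(ir_mean, ir_sd, bw_mean, bw_sd, food="rice_flour", group="0-3"):
    return ConsumptionProfile(age_group=group, ir={food: (ir_mean, ir_sd)}, bw=(bw_mean, bw_sd))


class TestC2Fit:
    def test_identical_values_degenerate(self):
        data = CensoredCount.from_values([np.e, np.e, np.e], 0, 0.001)
        fit = fit_c2_distribution(data)
        assert fit.mu == pytest.approx(1.0)
        assert fit.degenerate and fit.sigma == pytest.approx(0.0, abs=1e-9)

    def test_uncensored_matches_closed_form_mle(self):
        rng = np.random.default_rng(12)
        vals = np.exp(rng.normal(1.2, 0.4, 80))
        data = CensoredCount.from_values(vals, 0, 1e-6)
        fit = fit_c2_distribution(data)
        logs = np.log(vals)
        assert fit.mu == pytest.approx(logs.mean())
        assert fit.sigma == pytest.approx(logs.std(ddof=0))

    def test_too_few_detected_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_c2_distribution(CensoredCount.from_values([1.0], 3, 0.5))

    def test_censored_mle_beats_substitution_on_average(self):
        """With 30% censoring, the MLE tracks truth closer than LOD/2 imputation."""
        mu_t, sigma_t = 1.0, 0.6
        lod = float(np.exp(mu_t + sigma_t * stats.norm.ppf(0.30)))
        err_mle, err_sub = [], []
        rng = np.random.default_rng(77)
        for _ in range(50):
            raw = np.exp(rng.normal(mu_t, sigma_t, 100))
            det = raw[raw >= lod]
            n_cens = raw.size - det.size
            data = CensoredCount.from_values(det, n_cens, lod)
            f1 = fit_c2_distribution(data, "censored-mle")
            f2 = fit_c2_distribution(data, "substitution")
            err_mle.append((f1.mu - mu_t) ** 2 + (f1.sigma - sigma_t) ** 2)
            err_sub.append((f2.mu - mu_t) ** 2 + (f2.sigma - sigma_t) ** 2)
        assert np.mean(err_mle) < np.mean(err_sub)


class TestSimulateEdi:
    def test_all_degenerate_unit_inputs(self):
        out = simulate_edi(1.0, _profile(1.0, 0.0, 1.0, 0.0), "rice_flour", n_iterations=50, seed=0)
        assert np.allclose(out.values, 1.0)

    def test_degenerate_scaling(self):
        out = simulate_edi(10.0, _profile(100.0, 0.0, 10.0, 0.0), "rice_flour", n_iterations=50, seed=0)
        assert np.allclose(out.values, 100.0)  # 10 ng/g * 100 g/day / 10 kg

    def test_linear_in_concentration_and_ir_inverse_in_bw(self):
        base = simulate_edi(2.0, _profile(50.0, 0.0, 20.0, 0.0), "rice_flour", n_iterations=10, seed=0)
        double_c = simulate_edi(4.0, _profile(50.0, 0.0, 20.0, 0.0), "rice_flour", n_iterations=10, seed=0)
        half_bw = simulate_edi(2.0, _profile(50.0, 0.0, 10.0, 0.0), "rice_flour", n_iterations=10, seed=0)
        assert np.allclose(double_c.values, 2 * base.values)
        assert np.allclose(half_bw.values, 2 * base.values)

    def test_empirical_mean_matches_independence_factorization(self):
        """E[EDI] = E[C] * E[IR] * E[1/BW] for independent inputs."""
        fit = LogNormalFit(mu=1.0, sigma=0.4, method="censored-mle")
        profile = _profile(80.0, 30.0, 15.0, 2.0)
        n = 200_000
        out = simulate_edi(fit, profile, "rice_flour", n_iterations=n, seed=42)
        e_c = np.exp(1.0 + 0.4**2 / 2)
        e_ir = 80.0
        # E[1/BW] for the (negligibly) truncated normal via quadrature
        from scipy.integrate import quad

        norm = stats.norm(15.0, 2.0)
        z, _ = quad(lambda b: norm.pdf(b), 0, np.inf)
        e_inv_bw, _ = quad(lambda b: norm.pdf(b) / b, 1e-6, np.inf)
        e_inv_bw /= z
        expected = e_c * e_ir * e_inv_bw
        se = out.values.std(ddof=1) / np.sqrt(n)
        assert abs(out.values.mean() - expected) < 3 * se

    def test_reproducible_given_seed(self):
        fit = LogNormalFit(mu=0.5, sigma=0.3, method="censored-mle")
        p = _profile(40.0, 20.0, 12.0, 2.0)
        a = simulate_edi(fit, p, "rice_flour", n_iterations=100, seed=3)
        b = simulate_edi(fit, p, "rice_flour", n_iterations=100, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_heavy_bw_truncation_warns(self):
        with pytest.warns(UserWarning, match="below 0"):
            simulate_edi(1.0, _profile(10.0, 0.0, 6.0, 5.0), "rice_flour", n_iterations=200, seed=1)

    def test_unknown_food_raises(self):
        with pytest.raises(ValidationError):
            simulate_edi(1.0, _profile(10.0, 1.0, 10.0, 1.0), "oatmeal", n_iterations=10, seed=0)


class TestTotalEdi:
    def _draws(self, values, group="0-3", food="rice_flour", analyte="BP"):
        return EdiDraws(age_group=group, analyte=analyte, food_category=food, values=np.asarray(values, float))

    def test_single_part_identity(self):
        d = self._draws([1.0, 2.0, 3.0])
        assert np.array_equal(total_edi([d]).values, d.values)

    def test_constant_parts_sum(self):
        a = self._draws(np.ones(5))
        b = self._draws(2 * np.ones(5), food="oatmeal")
        tot = total_edi([a, b])
        assert np.allclose(tot.values, 3.0)

    def test_matches_direct_summed_simulation(self):
        rng = np.random.default_rng(6)
        parts = [self._draws(np.exp(rng.normal(0, 1, 5000)), food=f) for f in ("a", "b", "c")]
        tot = total_edi(parts)
        direct = parts[0].values + parts[1].values + parts[2].values
        assert np.array_equal(tot.values, direct)
        assert percentile(tot, 0.975) == pytest.approx(float(np.quantile(direct, 0.975)))

    def test_commutes_with_permutation(self):
        rng = np.random.default_rng(7)
        parts = [self._draws(rng.uniform(size=100), food=f) for f in ("a", "b", "c")]
        assert np.allclose(total_edi(parts).values, total_edi(parts[::-1]).values)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValidationError):
            total_edi([self._draws(np.ones(5)), self._draws(np.ones(6), food="oatmeal")])


class TestPercentile:
    def test_constant_vector(self):
        d = EdiDraws("0-3", "BP", "rice_flour", values=np.full(10, 4.2))
        for p in (0.1, 0.5, 0.975):
            assert percentile(d, p) == pytest.approx(4.2)

    def test_linear_interpolation_convention(self):
        d = EdiDraws("0-3", "BP", "rice_flour", values=np.arange(1.0, 101.0))
        assert percentile(d, 0.5) == pytest.approx(50.5)

    def test_tail_quantile_matches_lognormal_closed_form(self):
        rng = np.random.default_rng(11)
        vals = np.exp(rng.normal(2.0, 0.7, 10_000))
        d = EdiDraws("0-3", "BP", "rice_flour", values=vals)
        closed = float(np.exp(2.0 + 0.7 * stats.norm.ppf(0.975)))
        assert percentile(d, 0.975) == pytest.approx(closed, rel=0.03)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(13)
        d = EdiDraws("0-3", "BP", "rice_flour", values=rng.uniform(size=500))
        ps = np.linspace(0.05, 0.95, 19)
        qs = [percentile(d, p) for p in ps]
        assert np.all(np.diff(qs) >= 0)

    def test_empty_raises(self):
        d = EdiDraws("0-3", "BP", "rice_flour", values=np.empty(0))
        with pytest.raises(InsufficientDataError):
            percentile(d, 0.5)


def test_lognormal_mean_sd_parameterization_round_trip():
    mu, sigma = lognormal_params_from_mean_sd(80.0, 30.0)
    assert np.exp(mu + sigma**2 / 2) == pytest.approx(80.0)
    var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
    assert np.sqrt(var) == pytest.approx(30.0)
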
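"""Likelihood values, closed-form fit oracles, AICc."""

import math

import numpy as np
import pytest

import densdep as dd
from conftest import make_series


class TestNegativeLogLikelihood:
    def test_single_zero_residual_standard_normal(self):
        series = make_series([0.05, 0.05])
        cfg = dd.ModelConfig.build({"A": "random_walk"})
        L = dd.negative_log_likelihood(cfg, {"sigma@A": 1.0}, series)
        assert L == pytest.approx(0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_per_transition_additivity(self):
        series = make_series([0.05, 0.05, 0.05])
        cfg = dd.ModelConfig.build({"A": "random_walk"})
        L = dd.negative_log_likelihood(cfg, {"sigma@A": 1.0}, series)
        assert L == pytest.approx(math.log(2 * math.pi), abs=1e-12)

    def test_exponential_at_unit_growth_reduces_to_random_walk(self):
        series = make_series([0.03, 0.07, 0.02, 0.09, 0.04])
        rw = dd.ModelConfig.build({"A": "random_walk"})
        ex = dd.ModelConfig.build({"A": "exponential"})
        L_rw = dd.negative_log_likelihood(rw, {"sigma@A": 0.5}, series)
        L_ex = dd.negative_log_likelihood(
            ex, {"lambda@A": 1.0, "sigma@A": 0.5}, series
        )
        assert L_ex == pytest.approx(L_rw, abs=1e-12)

    def test_adding_transition_never_decreases_L_at_fixed_params(self):
        # each per-transition term is >= (1/2)ln(2 pi sigma^2)
        cfg = dd.ModelConfig.build({"A": "random_walk"})
        short = make_series([0.05, 0.06, 0.04])
        longer = make_series([0.05, 0.06, 0.04, 0.08])
        params = {"sigma@A": 1.0}
        assert dd.negative_log_likelihood(cfg, params, longer) >= dd.negative_log_likelihood(
            cfg, params, short
        )

    def test_gompertz_zero_density_domain_error(self):
        series = make_series([0.0, 0.05, 0.06])
        cfg = dd.ModelConfig.build({"A": "gompertz"})
        with pytest.raises(ValueError, match="zero density"):
            dd.negative_log_likelihood(
                cfg, {"lambda@A": 1.0, "beta@A": 0.1, "sigma@A": 1.0}, series
            )

    def test_relabeling_invariance(self):
        vals_a, vals_b = [0.03, 0.05, 0.04, 0.06], [0.1, 0.12, 0.09, 0.11]
        s1 = {**make_series(vals_a, "A"), **make_series(vals_b, "B")}
        s2 = {**make_series(vals_b, "A"), **make_series(vals_a, "B")}
        cfg = dd.ModelConfig.build(
            {"A": "ricker", "B": "ricker"},
            {"lambda": [["A", "B"]], "beta": [["A", "B"]]},
        )
        params = {"lambda@A+B": 1.5, "beta@A+B": 8.0, "sigma@A+B": 0.03}
        assert dd.negative_log_likelihood(cfg, params, s1) == pytest.approx(
            dd.negative_log_likelihood(cfg, params, s2), abs=1e-12
        )


class TestClosedFormFits:
    def test_random_walk_sigma_matches_analytic(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.01, 0.2, 12)
        series = make_series(vals)
        fit = dd.fit_config(dd.ModelConfig.build({"A": "random_walk"}), series)
        d = np.diff(vals)
        sigma_hat = math.sqrt(float(np.mean(d**2)))
        assert fit.params["sigma@A"] == pytest.approx(sigma_hat, abs=1e-10)
        n = len(d)
        L = 0.5 * n * math.log(2 * math.pi * sigma_hat**2) + 0.5 * n
        assert fit.nll == pytest.approx(L, abs=1e-10)

    def test_exponential_lambda_is_origin_slope(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.01, 0.2, 12)
        series = make_series(vals)
        fit = dd.fit_config(dd.ModelConfig.build({"A": "exponential"}), series)
        lam_hat = float(np.sum(vals[:-1] * vals[1:]) / np.sum(vals[:-1] ** 2))
        assert fit.get("lambda", "A") == pytest.approx(lam_hat, abs=1e-10)


class TestFitRecovery:
    def test_noise_free_ricker_recovered_to_four_digits(self, ricker_series):
        fit = dd.fit_config(dd.ModelConfig.build({"A": "ricker"}), ricker_series)
        assert fit.get("lambda", "A") == pytest.approx(3.66, rel=1e-4)
        assert fit.get("beta", "A") == pytest.approx(19.11, rel=1e-4)
        # sigma driven to its floor on noise-free input
        assert fit.get("sigma", "A") <= 1e-6

    def test_three_transition_grid_equivalence(self):
        # exhaustive profiled-sigma grid around truth vs the optimizer
        vals = dd.simulate_trajectory(
            "ricker", {"lambda": 2.0, "beta": 10.0}, 0.01, 0.04, 3, 5
        )
        series = make_series(vals)
        fit = dd.fit_config(dd.ModelConfig.build({"A": "ricker"}), series)
        assert math.isnan(fit.aicc)  # n = 3 transitions <= k + 1 = 4
        nf, nt = series["A"].transitions()
        lam_c, beta_c = fit.get("lambda", "A"), fit.get("beta", "A")
        lam_span, beta_span = math.log(10.0), 5 * abs(beta_c) + 10
        best = np.inf
        for _ in range(16):
            lams = np.exp(np.linspace(math.log(lam_c) - lam_span, math.log(lam_c) + lam_span, 200))
            betas = np.linspace(beta_c - beta_span, beta_c + beta_span, 200)
            pred = lams[:, None, None] * nf * np.exp(-betas[None, :, None] * nf)
            s2 = np.maximum(np.mean((nt - pred) ** 2, axis=2), 1e-16)
            nll = 0.5 * len(nf) * (math.log(2 * math.pi) + np.log(s2)) + 0.5 * len(nf)
            i, j = np.unravel_index(np.argmin(nll), nll.shape)
            best = min(best, float(nll[i, j]))
            lam_c, beta_c = float(lams[i]), float(betas[j])
            lam_span *= 0.4
            beta_span *= 0.4
        assert fit.nll == pytest.approx(best, abs=1e-6)

    def test_fit_deterministic_given_seed(self, ricker_series):
        cfg = dd.ModelConfig.build({"A": "ricker"})
        a = dd.fit_config(cfg, ricker_series, seed=3)
        b = dd.fit_config(cfg, ricker_series, seed=3)
        assert a.params == b.params

    def test_shared_parameter_fit_uses_pooled_transitions(self):
        t1 = dd.simulate_trajectory("ricker", {"lambda": 3.0, "beta": 15.0}, 0.0, 0.01, 11, 0)
        t2 = dd.simulate_trajectory("ricker", {"lambda": 3.0, "beta": 15.0}, 0.0, 0.03, 11, 0)
        series = {**make_series(t1, "A"), **make_series(t2, "B")}
        cfg = dd.ModelConfig.build(
            {"A": "ricker", "B": "ricker"},
            {"lambda": [["A", "B"]], "beta": [["A", "B"]]},
        )
        fit = dd.fit_config(cfg, series)
        assert fit.n == 22
        assert fit.get("lambda", "A") == pytest.approx(3.0, rel=1e-3)
        assert fit.get("beta", "B") == pytest.approx(15.0, rel=1e-3)


class TestAicc:
    def test_direct_formula(self):
        assert dd.aicc(0.0, 2, 12) == pytest.approx(4 + 12 / 9, abs=1e-12)

    def test_large_n_limit_is_plain_aic(self):
        assert dd.aicc(5.0, 3, 10**7) == pytest.approx(2 * 5.0 + 2 * 3, abs=1e-4)

    @pytest.mark.parametrize("n, k", [(12, 11), (5, 4), (3, 3)])
    def test_undefined_denominator_raises(self, n, k):
        with pytest.raises(ValueError, match="AICc undefined"):
            dd.aicc(0.0, k, n)


class TestFitResult:
    def test_summary_names_all_parameters(self, ricker_series):
        fit = dd.fit_config(dd.ModelConfig.build({"A": "ricker"}), ricker_series)
        text = fit.summary()
        for name in fit.params:
            assert name in text
        assert f"{fit.k}" in text

    def test_missing_location_series_rejected(self):
        cfg = dd.ModelConfig.build({"A": "ricker", "B": "ricker"})
        with pytest.raises(ValueError, match="no series"):
            dd.fit_config(cfg, make_series([0.1, 0.2, 0.3]))

    def test_single_year_series_rejected(self):
        cfg = dd.ModelConfig.build({"A": "random_walk"})
        with pytest.raises(ValueError, match="transitions"):
            dd.fit_config(cfg, make_series([0.1]))
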
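"""Gompertz curve, candidate-model machinery, likelihood and ML fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import larvalfit as lf
from larvalfit.gompertz import (FitConfig, GompertzParams, ModelSpec,
                                UnknownFactorLevelError, aicc, akaike_weights,
                                build_design_matrices, count_parameters,
                                enumerate_model_specs, fit_gompertz,
                                gompertz_length, gompertz_predict,
                                negative_log_likelihood, _nll_grad, _prepare)
from .conftest import TRUE_SPEC

rates = st.floats(min_value=1e-3, max_value=1.0)


class TestCurve:
    def test_initial_size_and_asymptote(self):
        p = GompertzParams(S0=6.0, gamma=0.12, alpha=0.06)
        assert gompertz_predict(p, 0.0) == pytest.approx(6.0, abs=1e-12)
        assert gompertz_predict(p, 1e7) == pytest.approx(6.0 * math.e ** 2,
                                                         rel=1e-9)
        assert p.asymptote == pytest.approx(44.334, abs=5e-3)
        # at the half-life of the decaying rate the exponent is half spent
        t_half = math.log(2) / p.alpha
        assert gompertz_predict(p, t_half) == pytest.approx(
            6.0 * math.exp(1.0), rel=1e-12)

    def test_small_alpha_limit_is_exponential(self):
        y_tiny = gompertz_length(10.0, 6.0, 0.1, 1e-13)
        y_zero = gompertz_length(10.0, 6.0, 0.1, 0.0)
        assert y_zero == pytest.approx(6.0 * math.exp(1.0), rel=1e-12)
        assert y_tiny == pytest.approx(y_zero, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gompertz_length(-1.0, 6.0, 0.1, 0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(S0=6.0, gamma=-0.1, alpha=0.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gamma=rates, alpha=rates, t=st.floats(min_value=0.1, max_value=200))
    def test_monotonicity_properties(self, gamma, alpha, t):
        y = gompertz_length(t, 6.0, gamma, alpha)
        assert gompertz_length(t + 1.0, 6.0, gamma, alpha) >= y
        assert gompertz_length(t, 6.0, gamma * 1.1, alpha) >= y
        assert gompertz_length(t, 6.0, gamma, alpha * 1.1) <= y


class TestSpecs:
    def test_seventeen_specs_one_null(self):
        specs = enumerate_model_specs()
        assert len(specs) == 17
        assert sum(s.is_null for s in specs) == 1
        assert specs[-1].is_null
        assert len(set(specs)) == 17

    def test_null_requires_both_null(self):
        with pytest.raises(ValueError):
            ModelSpec("1", "Location + Salinity + Density")

    # dummy-coding arithmetic: intercept + binary mains + 2-column density,
    # interactions add the products of their parents' columns
    EXPECTED_COLS = {
        "1": 1,
        "Location + Salinity + Density": 5,
        "Location * Salinity + Density": 6,
        "Location + Salinity * Density": 7,
        "Location * Salinity * Density": 12,
    }

    def test_design_matrix_column_counts(self, design):
        units = lf.units_to_frame(design)
        for spec in enumerate_model_specs():
            Xg, Xa = build_design_matrices(spec, units)
            assert Xg.shape[1] == self.EXPECTED_COLS[spec.gamma_formula]
            assert Xa.shape[1] == self.EXPECTED_COLS[spec.alpha_formula]
            assert count_parameters(spec) == 2 + Xg.shape[1] + Xa.shape[1]

    @pytest.mark.parametrize("gamma,alpha,df", [
        ("Location + Salinity + Density", "Location + Salinity * Density", 14),
        ("Location + Salinity * Density", "Location + Salinity * Density", 16),
        ("Location + Salinity + Density", "Location + Salinity + Density", 12),
        ("1", "1", 4),
    ])
    def test_parameter_counts_match_published_df(self, gamma, alpha, df):
        assert count_parameters(ModelSpec(gamma, alpha)) == df

    def test_unknown_level_rejected(self, design):
        units = lf.units_to_frame(design)
        units.loc[0, "location"] = "montane"
        with pytest.raises(UnknownFactorLevelError):
            build_design_matrices(TRUE_SPEC, units)


def _toy_growth(design, n_units=3, days=(0, 7, 14, 21, 28)):
    units = lf.units_to_frame(design[:n_units])
    rows = []
    rng = np.random.default_rng(0)
    for uid in units["unit_id"]:
        for d in days:
            rows.append((uid, d, 6.0 + 0.5 * d + rng.normal(0, 0.3)))
    growth = pd.DataFrame(rows, columns=["unit_id", "day",
                                         "mean_total_length_mm"])
    return units, growth


class TestLikelihood:
    def _theta(self, spec, units):
        Xg, Xa = build_design_matrices(spec, units)
        theta = np.zeros(2 + Xg.shape[1] + Xa.shape[1])
        theta[0] = 6.0
        theta[1] = math.log(0.12)
        theta[1 + Xg.shape[1]] = math.log(0.06)
        theta[-1] = math.log(0.4)
        return theta

    def test_matches_pointwise_gaussian_oracle(self, design):
        """NLL equals a brute-force sum of independent normal log-densities."""
        units, growth = _toy_growth(design)
        spec = enumerate_model_specs()[-1]
        theta = self._theta(spec, units)
        got = negative_log_likelihood(theta, spec, growth, units)
        mu = [6.0 * math.exp((0.12 / 0.06)
                             * (1 - math.exp(-0.06 * d)))
              for d in growth["day"]]
        oracle = -sum(stats.norm.logpdf(y, m, 0.4)
                      for y, m in zip(growth["mean_total_length_mm"], mu))
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_permutation_invariance(self, design):
        units, growth = _toy_growth(design)
        spec = TRUE_SPEC
        theta = self._theta(spec, units)
        shuffled = growth.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert negative_log_likelihood(theta, spec, growth, units) == \
            pytest.approx(negative_log_likelihood(theta, spec, shuffled, units),
                          abs=1e-10)

    def test_zero_residuals_closed_form(self, design):
        units = lf.units_to_frame(design[:2])
        days = np.array([0, 7, 14])
        mu = gompertz_length(days.astype(float), 6.0, 0.12, 0.06)
        growth = pd.DataFrame({
            "unit_id": np.repeat(units["unit_id"], len(days)),
            "day": np.tile(days, 2),
            "mean_total_length_mm": np.tile(mu, 2),
        })
        spec = enumerate_model_specs()[-1]
        theta = self._theta(spec, units)
        sigma = 0.4
        n = len(growth)
        assert negative_log_likelihood(theta, spec, growth, units) == \
            pytest.approx(n * (math.log(sigma) + 0.5 * math.log(2 * math.pi)),
                          abs=1e-10)

    def test_gradient_matches_finite_differences(self, design):
        units, growth = _toy_growth(design, n_units=6)
        prob = _prepare(TRUE_SPEC, growth, units)
        theta = self._theta(TRUE_SPEC, units) + 0.01
        nll, grad = _nll_grad(theta, prob)
        eps = 1e-6
        for i in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (_nll_grad(up, prob)[0] - _nll_grad(dn, prob)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_wrong_theta_size_rejected(self, design):
        units, growth = _toy_growth(design)
        with pytest.raises(ValueError):
            negative_log_likelihood(np.ones(3), TRUE_SPEC, growth, units)


class TestFit:
    def test_noiseless_recovery(self, design):
        cfg = lf.strong_effects_config(seed=1).replace(sigma_resid=0.0)
        ds = lf.simulate_dataset(design, cfg)
        fit = fit_gompertz(TRUE_SPEC, ds.growth, ds.units_frame,
                           FitConfig(n_restarts=3, seed=2))
        assert fit.coefficients["S0"] == pytest.approx(cfg.S0_true, rel=1e-4)
        rates_df = fit.cell_rates()
        truth_g = [cfg.gamma_by_cell[c] for c in lf.all_cells()]
        truth_a = [cfg.alpha_by_cell[c] for c in lf.all_cells()]
        np.testing.assert_allclose(rates_df["gamma"], truth_g, rtol=1e-4)
        np.testing.assert_allclose(rates_df["alpha"], truth_a, rtol=1e-4)

    def test_multistart_stability(self, strong_dataset):
        f1 = fit_gompertz(TRUE_SPEC, strong_dataset.growth,
                          strong_dataset.units_frame,
                          FitConfig(n_restarts=4, seed=100))
        f2 = fit_gompertz(TRUE_SPEC, strong_dataset.growth,
                          strong_dataset.units_frame,
                          FitConfig(n_restarts=4, seed=200))
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)

    def test_underdetermined_refused(self, design):
        units, growth = _toy_growth(design, n_units=1, days=(0, 7))
        with pytest.raises(ValueError, match="under-determined"):
            fit_gompertz(TRUE_SPEC, growth, units.iloc[:1])

    def test_fit_result_bookkeeping(self, strong_model_table):
        for fit in strong_model_table.fits:
            assert fit.k == count_parameters(fit.spec)
            assert fit.aicc == pytest.approx(
                aicc(fit.log_likelihood, fit.k, fit.n_obs), abs=1e-12)


class TestAICcAndWeights:
    def test_direct_arithmetic(self):
        assert aicc(-10.0, 4, 20) == pytest.approx(28 + 40 / 15, abs=1e-12)
        assert aicc(-10.0, 0, 20) == pytest.approx(20.0, abs=1e-12)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 4, 10 ** 9) == pytest.approx(28.0, abs=1e-6)
        assert aicc(-10.0, 4, 100) > aicc(-10.0, 4, 10 ** 9)

    def test_small_n_refused(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 4, 5)

    def test_weights_basics(self):
        assert akaike_weights([0.0]) == pytest.approx([1.0])
        np.testing.assert_allclose(akaike_weights([0.0, 0.0]), [0.5, 0.5])
        with pytest.raises(ValueError):
            akaike_weights([])
        with pytest.raises(ValueError):
            akaike_weights([0.5, 1.0])  # min not zero

    def test_weights_invariant_to_aicc_shift(self):
        aiccs = np.array([100.0, 101.5, 104.0, 120.0])
        w1 = akaike_weights(aiccs - aiccs.min())
        w2 = akaike_weights((aiccs + 57.3) - (aiccs + 57.3).min())
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestModelTable:
    def test_structure(self, strong_model_table):
        frame = strong_model_table.frame
        assert len(frame) == 17
        assert frame.iloc[0]["dAICc"] == 0.0
        assert frame["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert list(frame["rank"]) == list(range(1, 18))
        assert (frame["dAICc"].diff().dropna() >= 0).all()

    def test_full_model_dominates_loglik(self, strong_model_table):
        """The richest parameterization nests all others, so its maximized
        log-likelihood must be at least every other model's."""
        fits = strong_model_table.fits
        full = [f for f in fits
                if f.spec.gamma_formula == "Location * Salinity * Density"
                and f.spec.alpha_formula == "Location * Salinity * Density"][0]
        for f in fits:
            assert full.log_likelihood >= f.log_likelihood - 1e-4

    def test_csv_roundtrip(self, strong_model_table, tmp_path):
        path = tmp_path / "model_table.csv"
        strong_model_table.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["rank", "gamma_formula", "alpha_formula",
                                      "logLik", "k", "n", "AICc", "dAICc",
                                      "weight", "converged"]
        assert len(back) == 17
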
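"""Regression models: beta/Gamma/binomial fits and effect-size transforms.

The beta regression is checked along two independent routes: against
statsmodels' beta-regression implementation and against a generic
derivative-free optimizer applied to a log-likelihood written from the
density directly in this test file.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from brainstates import regression


def make_design(rng, n, p_extra=2):
    X = pd.DataFrame({"const": np.ones(n)})
    for j in range(p_extra):
        X[f"x{j + 1}"] = rng.normal(size=n)
    return X


def beta_negll_independent(theta, y, X):
    """Beta log-likelihood written directly from the density (test-local)."""
    beta, phi = theta[:-1], np.exp(theta[-1])
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    a, b = mu * phi, (1 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1) * np.log(y)
        + (b - 1) * np.log(1 - y)
    )
    return -ll.sum()


class TestTransformWMH:
    @pytest.mark.parametrize(
        "vol,ln_expected,zero_expected",
        [(1.0, 0.0, 0.0), (0.0, 0.0, 1.0), (2.37, 0.862890, 0.0)],
    )
    def test_values(self, vol, ln_expected, zero_expected):
        lnv, zero = regression.transform_wmh(np.array([vol]))
        assert lnv[0] == pytest.approx(ln_expected, abs=1e-5)
        assert zero[0] == zero_expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            regression.transform_wmh(np.array([-0.1]))


class TestBetaRegression:
    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(1)
        n, mu, phi = 10_000, 0.25, 40.0
        y = rng.beta(mu * phi, (1 - mu) * phi, size=n)
        X = pd.DataFrame({"const": np.ones(n)})
        fit = regression.beta_regression(y, X)
        assert special.expit(fit.params["const"]) == pytest.approx(0.25, abs=0.01)
        assert fit.dispersion == pytest.approx(40.0, abs=2.0)

    def test_matches_statsmodels_route(self):
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(2)
        for trial in range(5):
            n = 400
            X = make_design(rng, n)
            beta = rng.normal(0, 0.5, size=3)
            beta[0] = -1.0
            mu = special.expit(X.to_numpy() @ beta)
            y = rng.beta(mu * 30, (1 - mu) * 30)
            ours = regression.beta_regression(y, X)
            sm_fit = BetaModel(y, X.to_numpy()).fit(disp=0)
            assert np.allclose(
                ours.params.to_numpy(), sm_fit.params[:3], atol=1e-4
            )
            assert np.allclose(
                ours.se.to_numpy(), sm_fit.bse[:3], rtol=1e-3
            )

    def test_matches_generic_optimizer_to_1e6(self):
        rng = np.random.default_rng(3)
        n = 300
        X = make_design(rng, n, p_extra=1)
        mu = special.expit(-1.0 + 0.4 * X["x1"].to_numpy())
        y = rng.beta(mu * 25, (1 - mu) * 25)
        ours = regression.beta_regression(y, X)
        start = np.array([-1.0, 0.4, np.log(25.0)])
        res = optimize.minimize(
            beta_negll_independent,
            start,
            args=(y, X.to_numpy()),
            method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 50_000},
        )
        assert res.success
        assert np.allclose(ours.params.to_numpy(), res.x[:2], atol=1e-6)

    def test_boundary_outcomes_rejected_with_guidance(self):
        X = pd.DataFrame({"const": np.ones(4)})
        with pytest.raises(ValueError, match="shrink_boundary"):
            regression.beta_regression(np.array([0.0, 0.5, 0.6, 0.7]), X)

    def test_explicit_boundary_shrinkage(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([[0.0, 1.0], rng.beta(2, 6, size=200)])
        X = pd.DataFrame({"const": np.ones(y.size)})
        fit = regression.beta_regression(y, X, shrink_boundary=True)
        assert fit.converged

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(5)
        n = 50
        X = make_design(rng, n, p_extra=1)
        X["dup"] = X["x1"]
        y = rng.beta(2, 6, size=n)
        with pytest.raises(ValueError, match="rank"):
            regression.beta_regression(y, X)


class TestGammaGLM:
    def test_recovers_known_multiplier(self):
        rng = np.random.default_rng(6)
        n = 5000
        fo = rng.beta(20, 60, size=n)
        X = pd.DataFrame({"const": np.ones(n), "fo_high": fo})
        b_true = 20 * np.log(0.98)
        mean = np.exp(np.log(80.0) + b_true * fo)
        y = rng.gamma(shape=6.0, scale=mean / 6.0)
        fit = regression.gamma_glm(y, X)
        eff = regression.effect_per_k_pp(fit, 5.0)
        se = fit.se["fo_high"]
        assert abs(fit.params["fo_high"] - b_true) <= 2 * se
        assert eff.ci_lower <= 0.98 <= eff.ci_upper

    def test_constant_outcome_collapses_to_intercept(self):
        rng = np.random.default_rng(7)
        n = 60
        X = make_design(rng, n, p_extra=1)
        y = np.full(n, 37.0)
        fit = regression.gamma_glm(y, X)
        assert fit.params["x1"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["const"] == pytest.approx(np.log(37.0), abs=1e-8)

    def test_nonpositive_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(3)})
        with pytest.raises(ValueError):
            regression.gamma_glm(np.array([1.0, 0.0, 2.0]), X)

    def test_matches_independent_ml_optimizer(self):
        # for a log-link Gamma GLM the beta score is shape-free, so ML in
        # beta coincides with the exponential-likelihood optimum
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = 120
            X = make_design(rng, n, p_extra=1)
            beta = np.array([2.0, rng.normal(0, 0.3)])
            y = rng.gamma(shape=3.0, scale=np.exp(X.to_numpy() @ beta) / 3.0)
            ours = regression.gamma_glm(y, X)

            def negll(b):
                mu = np.exp(X.to_numpy() @ b)
                return np.sum(np.log(mu) + y / mu)

            res = optimize.minimize(
                negll, beta, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000},
            )
            assert np.allclose(ours.params.to_numpy(), res.x, atol=1e-6)


class TestBinomialGLM:
    def test_half_successes_null_intercept(self):
        n = 40
        X = pd.DataFrame({"const": np.ones(n)})
        fit = regression.binomial_glm(np.full(n, 10.0), np.full(n, 20.0), X)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_planted_odds_ratio(self):
        rng = np.random.default_rng(9)
        n = 5000
        fo = rng.beta(20, 60, size=n)
        X = pd.DataFrame({"const": np.ones(n), "fo_high": fo})
        b_true = np.log(1.19) * 5.0  # OR 1.19 per 20 pp on the proportion scale
        p = special.expit(0.8 + b_true * fo)
        succ = rng.binomial(10, p)
        fit = regression.binomial_glm(succ, np.full(n, 10.0), X)
        assert abs(fit.params["fo_high"] - b_true) <= 2 * fit.se["fo_high"]

    def test_or_per_20pp_is_fourth_power_of_per_5pp(self):
        rng = np.random.default_rng(10)
        n = 500
        fo = rng.uniform(0.1, 0.4, size=n)
        X = pd.DataFrame({"const": np.ones(n), "fo_high": fo})
        succ = rng.binomial(10, special.expit(0.3 + 1.2 * fo))
        fit = regression.binomial_glm(succ, np.full(n, 10.0), X)
        per5 = regression.effect_per_k_pp(fit, 5.0)
        per20 = regression.effect_per_k_pp(fit, 20.0)
        assert per20.estimate == pytest.approx(per5.estimate ** 4, rel=1e-10)

    def test_separation_reported_with_covariate_name(self):
        n = 30
        x = np.concatenate([np.zeros(15), np.ones(15)])
        X = pd.DataFrame({"const": np.ones(n), "group": x})
        succ = np.where(x > 0, 10.0, 0.0)
        with pytest.raises(RuntimeError, match="separation|converge"):
            regression.binomial_glm(succ, np.full(n, 10.0), X)

    def test_invalid_successes_rejected(self):
        X = pd.DataFrame({"const": np.ones(2)})
        with pytest.raises(ValueError):
            regression.binomial_glm(np.array([5.0, 11.0]), np.full(2, 10.0), X)

    def test_matches_independent_ml_optimizer(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = 150
            X = make_design(rng, n, p_extra=1)
            beta = np.array([0.4, rng.normal(0, 0.4)])
            p = special.expit(X.to_numpy() @ beta)
            succ = rng.binomial(8, p).astype(float)
            ours = regression.binomial_glm(succ, np.full(n, 8.0), X)

            def negll(b):
                eta = X.to_numpy() @ b
                return np.sum(8.0 * np.log1p(np.exp(eta)) - succ * eta)

            res = optimize.minimize(
                negll, beta, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000},
            )
            assert np.allclose(ours.params.to_numpy(), res.x, atol=1e-6)


class TestEffectTransforms:
    @pytest.fixture
    def fit_with_known_slope(self):
        def make(slope, se=0.01, name="ln_wmh"):
            params = pd.Series({"const": -1.1, name: slope})
            cov = pd.DataFrame(
                np.diag([0.02 ** 2, se ** 2]), index=params.index,
                columns=params.index,
            )
            return regression.RegressionResult(
                model="beta", params=params, cov_params=cov,
                dispersion=40.0, loglik=0.0, n_obs=100,
            )

        return make

    def test_iqr_scaling_factor(self, fit_with_known_slope):
        # the reporting factor for quartiles 0.468/2.37 is ln 5.06 = 1.621
        fit = fit_with_known_slope(1.0)
        eff = regression.effect_per_iqr(fit, 0.468, 2.37)
        assert np.log(eff.estimate) == pytest.approx(np.log(2.37 / 0.468))
        assert np.log(2.37 / 0.468) == pytest.approx(1.621, abs=2e-3)

    def test_zero_slope_gives_unit_odds_ratio(self, fit_with_known_slope):
        eff = regression.effect_per_iqr(fit_with_known_slope(0.0), 0.2, 3.7)
        assert eff.estimate == pytest.approx(1.0)

    def test_odds_ratio_round_trip(self, fit_with_known_slope):
        slope = np.log(0.94) / np.log(5.06)
        eff = regression.effect_per_iqr(
            fit_with_known_slope(slope), 0.468, 2.37
        )
        assert eff.estimate == pytest.approx(0.94, abs=1e-3)

    def test_per_5pp_multiplier(self, fit_with_known_slope):
        fit = fit_with_known_slope(20 * np.log(0.98), name="fo_high")
        eff = regression.effect_per_k_pp(fit, 5.0)
        assert eff.estimate == pytest.approx(0.98)

    def test_zero_percentage_points_is_identity(self, fit_with_known_slope):
        fit = fit_with_known_slope(0.7, name="fo_high")
        assert regression.effect_per_k_pp(fit, 0.0).estimate == pytest.approx(1.0)

    def test_decrease_multiplier_reciprocal(self, fit_with_known_slope):
        # a 0.98-fold change per 5 pp increase is a 1.02-fold change per decrease
        fit = fit_with_known_slope(20 * np.log(0.98), name="fo_high")
        eff = regression.effect_per_k_pp(fit, -5.0)
        assert round(eff.estimate, 2) == 1.02

    def test_reporting_scale_preserves_pvalue(self, fit_with_known_slope):
        fit = fit_with_known_slope(-0.03, se=0.02)
        p_link = fit.pvalues["ln_wmh"]
        eff = regression.effect_per_iqr(fit, 0.5, 2.5)
        assert eff.pvalue == p_link

    def test_ci_transform_is_monotone(self, fit_with_known_slope):
        fit = fit_with_known_slope(-0.05, se=0.02)
        eff = regression.effect_per_iqr(fit, 0.5, 2.5)
        assert eff.ci_lower < eff.estimate < eff.ci_upper

    def test_missing_coefficient_reported(self, fit_with_known_slope):
        with pytest.raises(KeyError):
            regression.effect_per_k_pp(fit_with_known_slope(0.1), coef="fo_high")


class TestZeroIndicatorRule:
    def test_indicator_dropped_without_zeros(self):
        rng = np.random.default_rng(12)
        n = 200
        df = pd.DataFrame(
            {
                "wmh_total_ml": rng.lognormal(0, 1, size=n),
                "age": rng.uniform(50, 80, size=n),
                "sex": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
            }
        )
        df = regression.add_wmh_columns(df)
        X = regression.build_design(df, ("ln_wmh", "wmh_zero", "age", "female"))
        assert "wmh_zero" not in X.columns

    def test_estimates_unchanged_by_dropping_constant_indicator(self):
        rng = np.random.default_rng(13)
        n = 300
        df = pd.DataFrame(
            {
                "wmh_total_ml": rng.lognormal(0, 1, size=n),
                "age": rng.uniform(50, 80, size=n),
                "sex": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
            }
        )
        df = regression.add_wmh_columns(df)
        y = rng.beta(10, 30, size=n)
        X_auto = regression.build_design(
            df, ("ln_wmh", "wmh_zero", "age", "female")
        )
        X_manual = regression.build_design(df, ("ln_wmh", "age", "female"))
        a = regression.beta_regression(y, X_auto)
        b = regression.beta_regression(y, X_manual)
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-8)
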
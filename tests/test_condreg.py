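import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq

from ccwin import (
    DailySeries,
    ModelSpec,
    NaturalSpline,
    StratumScheme,
    assign_strata,
    fit_conditional_gaussian,
    fit_conditional_poisson,
    fit_time_series_glm,
    informative_strata,
    natural_spline_basis,
)
from ccwin.condreg import (
    ConditionalGaussianRegressor,
    ConditionalPoissonRegressor,
    IdentifiabilityError,
)
from conftest import random_stratified_frame


def _oracle_slope(df, family):
    """Dummy-variable (unconditional) fit with one indicator per stratum."""
    X = np.column_stack([df["x"].to_numpy(), pd.get_dummies(df["stratum"], dtype=float)])
    y = df["y"].to_numpy()
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return float(np.asarray(res.params)[0]), float(np.asarray(res.bse)[0])


class TestOracleEquivalence:
    """Conditional fits must agree with explicit stratum-indicator fits."""

    @pytest.mark.parametrize("seed", range(10))
    def test_gaussian_matches_dummy_ols(self, seed):
        rng = np.random.default_rng(seed)
        df = random_stratified_frame(rng, "gaussian")
        est = ConditionalGaussianRegressor().fit(
            df[["x"]].to_numpy(), df["y"].to_numpy(), strata=df["stratum"].to_numpy()
        )
        beta, se = _oracle_slope(df, "gaussian")
        assert est.coef_[0] == pytest.approx(beta, abs=1e-8)
        assert est.se_[0] == pytest.approx(se, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_poisson_matches_dummy_glm(self, seed):
        rng = np.random.default_rng(100 + seed)
        df = random_stratified_frame(rng, "poisson")
        if df.groupby("stratum")["y"].sum().min() <= 0:
            df = df[df.groupby("stratum")["y"].transform("sum") > 0]
        est = ConditionalPoissonRegressor().fit(
            df[["x"]].to_numpy(), df["y"].to_numpy(), strata=df["stratum"].to_numpy()
        )
        beta, _ = _oracle_slope(df, "poisson")
        assert est.converged_
        assert est.coef_[0] == pytest.approx(beta, abs=1e-6)


class TestConditionalPoisson:
    def test_symmetric_outcomes_give_zero_slope(self):
        # equal counts across each pair: the conditional score at beta=0 vanishes
        x = np.array([[0.1], [0.9], [0.4], [0.6], [1.2], [0.3]])
        y = np.array([2.0, 2.0, 5.0, 5.0, 1.0, 1.0])
        strata = np.array([0, 0, 1, 1, 2, 2])
        est = ConditionalPoissonRegressor().fit(x, y, strata=strata)
        assert est.coef_[0] == pytest.approx(0.0, abs=1e-10)

    def test_monotone_likelihood_reported_as_divergence(self):
        est = ConditionalPoissonRegressor().fit(
            np.array([[0.0], [1.0]]), np.array([0.0, 1.0]), strata=np.array([0, 0])
        )
        assert not est.converged_
        assert any("+inf" in n for n in est.notes_)

    def test_pairs_with_binary_outcomes_reduce_to_conditional_logistic(self):
        # strata of size 2 with totals 1: P(y_i=1 | pair) = e^{b dx}/(1+e^{b dx});
        # the MLE solves sum_pairs dx * (y2 - p(b dx)) = 0 — solve independently
        rng = np.random.default_rng(3)
        n_pairs = 40
        dx = rng.normal(size=n_pairs)
        b_true = 0.8
        p = 1.0 / (1.0 + np.exp(-b_true * dx))
        second = (rng.uniform(size=n_pairs) < p).astype(float)
        x = np.c_[np.ravel(np.column_stack([np.zeros(n_pairs), dx]))]
        y = np.ravel(np.column_stack([1.0 - second, second]))
        strata = np.repeat(np.arange(n_pairs), 2)

        def score(b):
            return float(np.sum(dx * (second - 1.0 / (1.0 + np.exp(-b * dx)))))

        b_hat = brentq(score, -20, 20)
        est = ConditionalPoissonRegressor().fit(x, y, strata=strata)
        assert est.coef_[0] == pytest.approx(b_hat, abs=1e-7)

    def test_information_matrix_psd_along_path(self):
        rng = np.random.default_rng(9)
        df = random_stratified_frame(rng, "poisson", n_strata=6)
        X = df[["x"]].to_numpy()
        y = df["y"].to_numpy()
        codes = pd.factorize(df["stratum"])[0]
        for theta in ([-2.0], [0.0], [0.7], [3.0]):
            _, p_rec, Ys = ConditionalPoissonRegressor._loglik_parts(
                np.array(theta), X, y, codes, codes.max() + 1
            )
            info = ConditionalPoissonRegressor._information(X, Ys * p_rec, Ys, codes)
            assert np.linalg.eigvalsh(info).min() >= -1e-10

    def test_loglik_increases_along_newton_path(self):
        # concave likelihood: the final loglik dominates the start value
        rng = np.random.default_rng(11)
        df = random_stratified_frame(rng, "poisson", n_strata=8)
        X, y = df[["x"]].to_numpy(), df["y"].to_numpy()
        codes = pd.factorize(df["stratum"])[0]
        ll0, _, _ = ConditionalPoissonRegressor._loglik_parts(
            np.zeros(1), X, y, codes, codes.max() + 1
        )
        est = ConditionalPoissonRegressor().fit(X, y, strata=df["stratum"].to_numpy())
        assert est.loglik_ >= ll0 - 1e-12


class TestConditionalGaussian:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        shifts = np.repeat(rng.normal(size=10) * 5, 2)
        y = 2.0 * x + shifts  # slope 2 plus stratum levels, no noise
        est = ConditionalGaussianRegressor().fit(
            x[:, None], y, strata=np.repeat(np.arange(10), 2)
        )
        assert est.coef_[0] == pytest.approx(2.0, abs=1e-10)
        assert est.rss_ == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("family", ["gaussian", "poisson"])
    def test_stratum_constant_exposure_shift_invariance(self, family):
        rng = np.random.default_rng(5)
        df = random_stratified_frame(rng, family)
        if family == "poisson":
            df = df[df.groupby("stratum")["y"].transform("sum") > 0]
        cls = ConditionalGaussianRegressor if family == "gaussian" else ConditionalPoissonRegressor
        base = cls().fit(df[["x"]].to_numpy(), df["y"].to_numpy(), strata=df["stratum"].to_numpy())
        codes = pd.factorize(df["stratum"])[0]
        shifted = df["x"].to_numpy() + rng.normal(size=codes.max() + 1)[codes] * 10
        est = cls().fit(shifted[:, None], df["y"].to_numpy(), strata=df["stratum"].to_numpy())
        assert est.coef_[0] == pytest.approx(base.coef_[0], abs=1e-6)

    def test_zero_residual_df_is_error(self):
        from ccwin.condreg import FitError

        with pytest.raises(FitError):
            ConditionalGaussianRegressor().fit(
                np.array([[1.0], [2.0]]), np.array([1.0, 2.0]), strata=np.array([0, 0])
            )

    def test_all_columns_stratum_constant_is_identifiability_error(self):
        x = np.array([[1.0], [1.0], [2.0], [2.0]])
        with pytest.raises(IdentifiabilityError):
            ConditionalGaussianRegressor().fit(
                x, np.array([1.0, 2.0, 3.0, 4.0]), strata=np.array([0, 0, 1, 1])
            )


def _truncated_power_natural_basis(x, knots):
    """Independent oracle: ESL-style truncated-power natural cubic basis."""
    xi = np.asarray(knots)
    K = len(xi)

    def d(k, x):
        return ((np.maximum(x - xi[k], 0) ** 3) - (np.maximum(x - xi[K - 1], 0) ** 3)) / (
            xi[K - 1] - xi[k]
        )

    cols = [x] + [d(k, x) - d(K - 2, x) for k in range(K - 2)]
    return np.column_stack(cols)


class TestNaturalSpline:
    def test_affine_beyond_boundary_knots(self):
        ns = NaturalSpline(df=4).fit(np.linspace(0.0, 10.0, 60))
        grid = np.array([11.0, 12.0, 13.0, -1.0, -2.0, -3.0])
        out = ns.transform(grid)
        # equally spaced points outside: second differences vanish per column
        np.testing.assert_allclose(out[2] - out[1], out[1] - out[0], atol=1e-9)
        np.testing.assert_allclose(out[5] - out[4], out[4] - out[3], atol=1e-9)

    def test_df1_single_monotone_column(self):
        basis = natural_spline_basis(np.linspace(0.0, 10.0, 11), df=1)
        assert basis.shape == (11, 1)
        diffs = np.diff(basis[:, 0])
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_matches_truncated_power_oracle_fit(self, rng):
        x = np.sort(rng.uniform(0, 1, size=200))
        y = np.sin(6 * x) + 0.1 * rng.normal(size=200)
        df = 5
        ns = NaturalSpline(df=df).fit(x)
        knots = np.concatenate([[ns.lo_], np.quantile(x, np.arange(1, df) / df), [ns.hi_]])
        B_mine = np.column_stack([np.ones_like(x), ns.transform(x)])
        B_oracle = np.column_stack([np.ones_like(x), _truncated_power_natural_basis(x, knots)])
        fitted_mine = B_mine @ np.linalg.lstsq(B_mine, y, rcond=None)[0]
        fitted_oracle = B_oracle @ np.linalg.lstsq(B_oracle, y, rcond=None)[0]
        np.testing.assert_allclose(fitted_mine, fitted_oracle, atol=1e-8)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            natural_spline_basis([1.0, 1.0, 2.0, 2.0], df=3)


class TestTimeSeriesGLM:
    def test_unconfounded_series_recovers_slope(self, rng):
        n = 1460
        x = rng.normal(size=n)
        y = 1.0 * x + 0.3 * rng.normal(size=n)
        s = DailySeries(dates=pd.date_range("2001-01-01", periods=n, freq="D"), outcome=y, exposure=x)
        fr = fit_time_series_glm(s, ModelSpec(family="gaussian"), df_per_year=6)
        assert fr.beta == pytest.approx(1.0, abs=0.05)

    def test_twelve_df_variant_runs_and_differs(self, sim2_samples_50):
        s = sim2_samples_50[0].series
        f6 = fit_time_series_glm(s, df_per_year=6)
        f12 = fit_time_series_glm(s, df_per_year=12)
        assert f6.beta != f12.beta
        assert "df=120" in f12.notes[0]


class TestDesignHandling:
    def test_dow_dropped_when_absorbed_by_design(self):
        rng = np.random.default_rng(6)
        n = 364
        s = DailySeries(
            dates=pd.date_range("2001-01-01", periods=n, freq="D"),
            outcome=rng.normal(size=n),
            exposure=rng.normal(size=n),
        )
        ds = informative_strata(
            assign_strata(s, StratumScheme("CC2W", year_rule="fixed365", allow_partial_years=True)),
            family="gaussian",
        )
        fr = fit_conditional_gaussian(ds, ModelSpec(family="gaussian", dow_factor=True))
        assert any("dow" in note for note in fr.notes)
        assert all(not k.startswith("dow") for k in fr.covariate_estimates)

    def test_dow_estimated_for_consecutive_day_scheme(self):
        rng = np.random.default_rng(7)
        n = 365
        s = DailySeries(
            dates=pd.date_range("2001-01-01", periods=n, freq="D"),
            outcome=rng.normal(size=n),
            exposure=rng.normal(size=n),
        )
        ds = informative_strata(
            assign_strata(s, StratumScheme("CC2D", year_rule="fixed365")), family="gaussian"
        )
        fr = fit_conditional_gaussian(ds, ModelSpec(family="gaussian", dow_factor=True))
        assert sum(k.startswith("dow") for k in fr.covariate_estimates) == 6

    def test_temperature_spline_enters_poisson_fit(self):
        rng = np.random.default_rng(8)
        n = 730
        temp = 10 + 10 * np.sin(2 * np.pi * np.arange(n) / 365) + rng.normal(size=n)
        x = rng.normal(size=n)
        lam = np.exp(1.0 + 0.2 * x + 0.02 * temp)
        s = DailySeries(
            dates=pd.date_range("2001-01-01", periods=n, freq="D"),
            outcome=rng.poisson(lam).astype(float),
            exposure=x,
            temperature=temp,
        )
        ds = informative_strata(
            assign_strata(s, StratumScheme("CC2D", year_rule="fixed365")), family="poisson"
        )
        fr = fit_conditional_poisson(ds, ModelSpec(family="poisson", temperature_spline_df=3))
        assert sum(k.startswith("temp_ns") for k in fr.covariate_estimates) == 3
        assert fr.beta == pytest.approx(0.2, abs=0.1)

    def test_fit_result_serialization_roundtrip(self, sim1_samples_50):
        import json

        from ccwin.study import fit_method

        fr = fit_method(sim1_samples_50[0].series, "CC2D")
        d = json.loads(fr.to_json())
        assert d["beta"] == fr.beta and d["converged"] is True
        row = fr.to_csv_row()
        assert row.loc[0, "beta"] == fr.beta
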
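"""Spatial GLS fitting, pseudo-R^2, VIF, partial predictions, species models."""

import numpy as np
import pandas as pd
import pytest

from cwmitv import (CorrelationModel, fit_gls, fit_gls_r2, nagelkerke_r2,
                    partial_prediction, species_level_models,
                    summarize_species_models, vif)
from cwmitv.spatial import correlation_matrix


def random_design(rng, n=40, p=3):
    coords = rng.uniform(0, 100, (n, 2))
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    beta = rng.normal(size=p)
    y = 1.0 + X.to_numpy() @ beta + rng.normal(size=n)
    return y, X, coords


def simulate_spatial(rng, coords, range_m, sd=1.0):
    d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    C = np.exp(-d / range_m)
    C[np.diag_indices(len(coords))] += 1e-10
    return sd * (np.linalg.cholesky(C) @ rng.standard_normal(len(coords)))


class TestOlsEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_family_none_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        y, X, coords = random_design(rng)
        fit = fit_gls(y, X, coords, CorrelationModel(family="none"),
                      standardize=False)
        M = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        assert np.allclose(fit.params["coef"].to_numpy(), beta, atol=1e-8)

    def test_loglik_matches_gaussian_ols(self):
        rng = np.random.default_rng(1)
        y, X, coords = random_design(rng)
        fit = fit_gls(y, X, coords, CorrelationModel(family="none"))
        import statsmodels.api as sm
        ols = sm.OLS(y, sm.add_constant((X - X.mean()) / X.std(ddof=0))).fit()
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)


class TestAgainstNlmeGls:
    def test_exponential_ml_fit_matches_nlme(self):
        """Frozen oracle: the same data fitted with R's nlme::gls
        (corExp, method='ML') gives these coefficients, range and
        log-likelihood."""
        rng = np.random.default_rng(42)
        n = 40
        coords = rng.uniform(0, 100, (n, 2))
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        e = simulate_spatial(rng, coords, 20.0)
        y = 1.0 + 0.8 * x1 - 0.5 * x2 + e
        fit = fit_gls(y, pd.DataFrame({"x1": x1, "x2": x2}), coords,
                      CorrelationModel(), standardize=False)
        assert np.allclose(fit.params["coef"].to_numpy(),
                           [0.7274311, 0.6920451, -0.5080388], atol=1e-5)
        assert fit.range_ == pytest.approx(13.78165, abs=1e-3)
        assert fit.loglik == pytest.approx(-43.71661, abs=1e-4)


class TestCorrelationModel:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            CorrelationModel(family="cubic")

    def test_nugget_correlation_structure(self):
        d = np.array([[0.0, 10.0], [10.0, 0.0]])
        C = correlation_matrix(d, "exponential", 10.0, 0.2)
        assert C[0, 0] == 1.0
        assert C[0, 1] == pytest.approx(0.8 * np.exp(-1.0))

    def test_spherical_zero_beyond_range(self):
        d = np.array([[0.0, 50.0], [50.0, 0.0]])
        C = correlation_matrix(d, "spherical", 20.0, 0.0)
        assert C[0, 1] == 0.0


class TestFitBehaviour:
    def test_constant_response_zero_slopes_zero_r2(self):
        rng = np.random.default_rng(2)
        _, X, coords = random_design(rng)
        y = np.full(len(X), 3.0)
        fit, null, r2 = fit_gls_r2(y, X, coords, CorrelationModel(family="none"))
        assert np.allclose(fit.params["coef"].to_numpy()[1:], 0, atol=1e-10)
        assert r2 == pytest.approx(0.0, abs=1e-10)

    def test_singular_design_names_collinear_columns(self):
        rng = np.random.default_rng(3)
        y, X, coords = random_design(rng)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(ValueError, match="dup"):
            fit_gls(y, X, coords, CorrelationModel(family="none"))

    def test_standardization_absorbs_predictor_rescaling(self):
        rng = np.random.default_rng(4)
        y, X, coords = random_design(rng)
        fit1 = fit_gls(y, X, coords, CorrelationModel())
        X2 = X.copy()
        X2["x0"] = X2["x0"] * 1000.0
        fit2 = fit_gls(y, X2, coords, CorrelationModel())
        pd.testing.assert_frame_equal(fit1.params, fit2.params,
                                      atol=1e-8, rtol=1e-6)

    def test_full_model_loglik_at_least_null(self):
        rng = np.random.default_rng(5)
        y, X, coords = random_design(rng)
        fit, null, _ = fit_gls_r2(y, X, coords, CorrelationModel())
        assert fit.loglik >= null.loglik - 1e-4

    def test_aic_identity(self):
        rng = np.random.default_rng(6)
        y, X, coords = random_design(rng)
        fit = fit_gls(y, X, coords, CorrelationModel())
        k = len(fit.params) + 1 + 1  # mean params + sigma^2 + range
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)

    def test_range_recovery_median_reasonable(self):
        """Reduced-size check that ML recovers a 20 m range on a grid of
        10 m cells (the full experiment lives in the acceptance suite)."""
        ix, iy = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        coords = np.column_stack([ix.ravel() * 10.0, iy.ravel() * 10.0])
        rng = np.random.default_rng(7)
        est = []
        for _ in range(20):
            y = simulate_spatial(rng, coords, 20.0)
            fit = fit_gls(y, None, coords, CorrelationModel())
            est.append(fit.range_)
        assert 8.0 <= np.median(est) <= 45.0


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        rng = np.random.default_rng(8)
        y, X, coords = random_design(rng)
        fit = fit_gls(y, X, coords, CorrelationModel(family="none"))
        assert nagelkerke_r2(fit, fit) == pytest.approx(0.0)

    def test_matches_hand_formula(self):
        from dataclasses import replace
        rng = np.random.default_rng(9)
        y, X, coords = random_design(rng)
        fit, null, r2 = fit_gls_r2(y, X, coords, CorrelationModel(family="none"))
        ll0, llm, n = null.loglik, fit.loglik, fit.n
        expected = (1 - np.exp(2 * (ll0 - llm) / n)) / (1 - np.exp(2 * ll0 / n))
        assert r2 == pytest.approx(expected, rel=1e-12)
        assert 0 <= r2 <= 1

    def test_monotone_in_full_loglik(self):
        from dataclasses import replace
        rng = np.random.default_rng(10)
        y, X, coords = random_design(rng)
        fit, null, _ = fit_gls_r2(y, X, coords, CorrelationModel(family="none"))
        better = replace(fit, loglik=fit.loglik + 1.0)
        assert nagelkerke_r2(better, null) > nagelkerke_r2(fit, null)

    def test_mismatched_n_rejected(self):
        rng = np.random.default_rng(11)
        y, X, coords = random_design(rng)
        fit = fit_gls(y, X, coords, CorrelationModel(family="none"))
        y2, X2, c2 = random_design(rng, n=30)
        null2 = fit_gls(y2, None, c2, CorrelationModel(family="none"))
        with pytest.raises(ValueError):
            nagelkerke_r2(fit, null2)


class TestVif:
    def test_orthogonal_predictors_all_one(self):
        rng = np.random.default_rng(12)
        # orthonormal columns, also orthogonal to the intercept
        Q, _ = np.linalg.qr(np.column_stack([np.ones(30), rng.normal(size=(30, 4))]))
        X = pd.DataFrame(Q[:, 1:], columns=list("abcd"))
        assert np.allclose(vif(X).to_numpy(), 1.0, atol=1e-10)

    def test_bivariate_correlation_09_closed_form(self):
        rng = np.random.default_rng(13)
        n = 20000
        z = rng.normal(size=n)
        a = z + rng.normal(size=n) * np.sqrt(1 / 0.81 - 1)
        # construct an exactly 0.9-correlated pair by whitening then mixing
        u = rng.normal(size=(n, 2))
        u = (u - u.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(u.T))).T
        X = pd.DataFrame({"a": u[:, 0], "b": 0.9 * u[:, 0] + np.sqrt(1 - 0.81) * u[:, 1]})
        v = vif(X)
        assert v["a"] == pytest.approx(1 / (1 - 0.81), abs=1e-3)
        assert v["b"] == pytest.approx(5.263, abs=1e-2)

    def test_matches_bruteforce_regression_loop(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(60, 8)) @ rng.normal(size=(8, 8)),
                         columns=[f"x{j}" for j in range(8)])
        v = vif(X)
        for j, c in enumerate(X.columns):
            others = X.drop(columns=[c]).to_numpy()
            A = np.column_stack([np.ones(len(X)), others])
            beta, *_ = np.linalg.lstsq(A, X[c].to_numpy(), rcond=None)
            resid = X[c].to_numpy() - A @ beta
            tot = X[c].to_numpy() - X[c].mean()
            r2 = 1 - (resid @ resid) / (tot @ tot)
            assert v[c] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_exact_collinearity_reports_inf(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.isinf(vif(X)).all()


class TestPartialPrediction:
    def _fit(self):
        rng = np.random.default_rng(16)
        y, X, coords = random_design(rng)
        return fit_gls(y, X, coords, CorrelationModel(family="none"))

    def test_linearity_two_points_differ_by_twice_coef(self):
        fit = self._fit()
        curve = partial_prediction(fit, "x1", [-1.0, 1.0])
        diff = curve["predicted"].iloc[1] - curve["predicted"].iloc[0]
        assert diff == pytest.approx(2 * fit.params.loc["x1", "coef"])

    def test_matches_design_matrix_product(self):
        fit = self._fit()
        grid = np.linspace(-2, 2, 7)
        curve = partial_prediction(fit, "x2", grid)
        M = np.zeros((7, len(fit.params)))
        M[:, 0] = 1.0
        M[:, list(fit.params.index).index("x2")] = grid
        assert np.allclose(curve["predicted"].to_numpy(),
                           M @ fit.params["coef"].to_numpy())

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError):
            partial_prediction(self._fit(), "nope", [0.0])


def _species_dataset(rng, n_plots=49, n_species=6, slope=0.0):
    """Plot-specific species means driven (or not) by one gradient."""
    ix, iy = np.meshgrid(np.arange(7), np.arange(7), indexing="ij")
    env = pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(n_plots)],
        "x": ix.ravel() * 10.0, "y": iy.ravel() * 10.0,
        "g": rng.normal(size=n_plots),
    })
    rows = []
    for s in range(n_species):
        for i, p in enumerate(env["plot_id"]):
            val = 10.0 + slope * env["g"].iloc[i] + rng.normal(0, 1.0)
            for ind in range(2):
                rows.append({"plot_id": p, "species_id": f"s{s}",
                             "individual_id": f"{p}-s{s}-{ind}",
                             "T": val + rng.normal(0, 0.1)})
    return pd.DataFrame(rows), env


class TestSpeciesLevelModels:
    def test_sparse_species_excluded(self):
        rng = np.random.default_rng(17)
        traits, env = _species_dataset(rng, n_species=2)
        traits = traits[~((traits.species_id == "s1")
                          & (~traits.plot_id.isin([f"p{i}" for i in range(5)])))]
        fits = species_level_models(traits, env, ["g"], min_plots=10)
        assert set(fits["species_id"]) == {"s0"}

    def test_strong_slope_detected(self):
        rng = np.random.default_rng(18)
        traits, env = _species_dataset(rng, slope=2.0)
        fits = species_level_models(traits, env, ["g"], min_plots=10)
        assert (fits["p"] < 0.05).mean() > 0.8

    def test_summary_counts(self):
        rng = np.random.default_rng(19)
        traits, env = _species_dataset(rng, slope=2.0, n_species=3)
        fits = species_level_models(traits, env, ["g"], min_plots=10)
        summ = summarize_species_models(fits)
        assert len(summ) == 3
        assert summ["any_significant"].all()
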
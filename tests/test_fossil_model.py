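"""Fossil-count models: fits, posterior simulation, LOOCV, Moran's tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from darkbirds import data_prep, fossil_model, synthetic
from darkbirds.fossil_model import goodness_of_fit


@pytest.fixture(scope="module")
def noiseless():
    """Design plus exactly log-linear (unrounded) counts from known beta."""
    arch, truth = synthetic.generate_archipelago_dataset(seed=21, lm_sigma=0.0)
    design = data_prep.prepare_design(arch, synthetic.RETAINED_PREDICTORS, synthetic.DEFAULT_TRANSFORMS)
    beta = np.array([truth.lm_coefficients["intercept"]] + [truth.lm_coefficients[c] for c in design.columns])
    X = np.column_stack([np.ones(len(arch)), design.values.to_numpy(float)])
    counts = np.expm1(X @ beta)  # fractional, so log1p(counts) is exactly linear
    return design, counts, beta


class TestLinearModel:
    def test_noiseless_data_interpolated_exactly(self, noiseless):
        design, counts, beta = noiseless
        fit = fossil_model.fit_fossil_lm(design, counts)
        assert np.allclose(fit.coefficients.to_numpy(), beta, atol=1e-8)
        assert fit.r2_multiple == pytest.approx(1.0, abs=1e-9)

    def test_refit_on_own_fitted_values_gives_r2_one(self, design, lm_fit):
        X = sm.add_constant(design.values)
        fitted_log = X.to_numpy() @ lm_fit.coefficients.to_numpy()
        refit = fossil_model.fit_fossil_lm(design, np.expm1(fitted_log))
        assert refit.r2_multiple == pytest.approx(1.0, abs=1e-9)

    def test_r2_ordering_and_covariance_psd(self, lm_fit):
        assert 0 <= lm_fit.r2_adjusted <= lm_fit.r2_multiple <= 1
        eigs = np.linalg.eigvalsh(lm_fit.coef_covariance)
        assert (eigs > -1e-10).all()

    def test_duplicated_column_reported_as_rank_deficient(self, design, arch_dataset):
        arch, _ = arch_dataset
        X = design.values.copy()
        X["dup"] = X["research_effort"]
        with pytest.raises(ValueError, match="rank deficient"):
            fossil_model.fit_fossil_lm(X, arch["n_fossil"])


class TestPosteriorSimulation:
    def test_draw_mean_converges_to_estimates(self, lm_fit):
        draws = fossil_model.simulate_posterior(lm_fit, n_draws=100_000, seed=1)
        mcse = draws.coef.std(axis=0, ddof=1) / np.sqrt(draws.n_draws)
        assert (np.abs(draws.coef.mean(axis=0) - lm_fit.coefficients.to_numpy()) < 3 * mcse).all()

    def test_draw_covariance_matches_coef_covariance(self, lm_fit):
        # E[cov of draws] = E[sigma^2] (X'X)^-1; compare against the fit's
        # covariance with a generous multiplicative band
        draws = fossil_model.simulate_posterior(lm_fit, n_draws=100_000, seed=2)
        emp = np.cov(draws.coef.T)
        dof_factor = lm_fit.df_resid / (lm_fit.df_resid - 2)  # inverse-chi-square mean
        expected = lm_fit.coef_covariance * dof_factor
        ratio = np.diag(emp) / np.diag(expected)
        assert np.all((ratio > 0.9) & (ratio < 1.1))

    def test_scale_draws_positive_and_seeded(self, lm_fit):
        d1 = fossil_model.simulate_posterior(lm_fit, n_draws=500, seed=3)
        d2 = fossil_model.simulate_posterior(lm_fit, n_draws=500, seed=3)
        assert (d1.scale > 0).all()
        assert np.array_equal(d1.coef, d2.coef) and np.array_equal(d1.scale, d2.scale)

    def test_zero_draws_rejected(self, lm_fit):
        with pytest.raises(ValueError):
            fossil_model.simulate_posterior(lm_fit, n_draws=0)


class TestQuasipoisson:
    def test_equidispersed_poisson_data_gives_unit_dispersion(self):
        rng = np.random.default_rng(31)
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.poisson(np.exp(0.5 + 0.4 * X["a"] - 0.2 * X["b"]))
        fit = fossil_model.fit_fossil_glm(X, y)
        assert 0.8 < fit.residual_sd_or_dispersion < 1.2

    def test_coefficients_equal_plain_poisson(self, design, arch_dataset):
        arch, _ = arch_dataset
        fit = fossil_model.fit_fossil_glm(design, arch["n_fossil"])
        plain = sm.GLM(
            arch["n_fossil"].to_numpy(float),
            sm.add_constant(design.values),
            family=sm.families.Poisson(),
        ).fit()
        assert np.allclose(fit.coefficients.to_numpy(), plain.params, atol=1e-8)

    def test_negative_counts_rejected(self, design):
        with pytest.raises(ValueError):
            fossil_model.fit_fossil_glm(design, np.full(len(design.values), -1))


class TestGoodnessOfFit:
    def test_perfect_predictions(self):
        obs = np.array([3.0, 1.0, 7.0, 2.0])
        g = goodness_of_fit(obs, obs)
        assert (g.spearman, g.r2_cv, g.pbias) == (1.0, 1.0, 0.0)

    def test_ten_percent_inflation_gives_pbias_ten(self):
        obs = np.array([3.0, 1.0, 7.0, 2.0])
        g = goodness_of_fit(obs, 1.1 * obs)
        assert g.pbias == pytest.approx(10.0)
        assert g.r2_cv == pytest.approx(1.0)

    def test_constant_predictions_reported_missing_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            g = goodness_of_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(g.spearman)

    def test_loocv_invariant_to_row_order(self, design, arch_dataset):
        arch, _ = arch_dataset
        g1 = fossil_model.loocv_goodness("lm", design.values, arch["n_fossil"])
        perm = np.random.default_rng(0).permutation(len(arch))
        g2 = fossil_model.loocv_goodness("lm", design.values.iloc[perm], arch["n_fossil"].iloc[perm])
        assert g1.spearman == pytest.approx(g2.spearman, abs=1e-12)
        assert g1.r2_cv == pytest.approx(g2.r2_cv, abs=1e-12)
        assert g1.pbias == pytest.approx(g2.pbias, abs=1e-12)

    def test_needs_three_rows(self, design, arch_dataset):
        arch, _ = arch_dataset
        with pytest.raises(ValueError, match="3 rows"):
            fossil_model.loocv_goodness("lm", design.values.iloc[:2], arch["n_fossil"].iloc[:2])

    def test_lm_beats_glm_on_lognormal_data(self):
        # on data generated on the LM's own scale, the LM's cross-validated
        # r2 should win in the majority of replicates
        wins = 0
        reps = 30
        for s in range(reps):
            arch, _ = synthetic.generate_archipelago_dataset(seed=200 + s)
            design = data_prep.prepare_design(
                arch, synthetic.RETAINED_PREDICTORS, synthetic.DEFAULT_TRANSFORMS
            )
            lm = fossil_model.loocv_goodness("lm", design, arch["n_fossil"])
            glm = fossil_model.loocv_goodness("quasipoisson", design, arch["n_fossil"])
            wins += lm.r2_cv > glm.r2_cv
        assert wins > reps / 2


class TestPartialR2:
    def test_single_predictor_partial_equals_multiple(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame({"a": rng.normal(size=80)})
        counts = np.expm1(np.maximum(0.5 + 0.8 * X["a"] + rng.normal(0, 0.3, 80), 0))
        fit = fossil_model.fit_fossil_lm(X, counts)
        assert fit.partial_r2["a"] == pytest.approx(fit.r2_multiple, abs=1e-9)

    def test_null_predictor_has_negligible_partial_r2(self):
        rng = np.random.default_rng(42)
        n = 500
        X = pd.DataFrame({"real": rng.normal(size=n), "null": rng.normal(size=n)})
        counts = np.expm1(np.maximum(1.0 + 0.7 * X["real"] + rng.normal(0, 0.4, n), 0))
        fit = fossil_model.fit_fossil_lm(X, counts)
        assert fit.partial_r2["null"] < 0.02

    def test_partials_bounded_by_multiple_r2(self, lm_fit):
        assert (lm_fit.partial_r2 <= lm_fit.r2_multiple + 1e-12).all()


class TestMoransTest:
    def test_iid_residuals_match_null_expectation(self):
        n = 50
        rng = np.random.default_rng(51)
        coords = rng.uniform(0, 10, size=(n, 2))
        W = fossil_model.knn_weights(coords, k=5)
        vals = np.array([fossil_model.morans_i(rng.normal(size=n), W)[0] for _ in range(200)])
        mcse = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (-1.0 / (n - 1))) < 3 * mcse

    def test_smooth_gradient_detected_as_autocorrelated(self):
        rng = np.random.default_rng(52)
        coords = rng.uniform(0, 10, size=(80, 2))
        gradient = coords[:, 0] + coords[:, 1]
        res = fossil_model.morans_test(gradient, coords, k_range=[5])
        assert res["morans_i"].iloc[0] > 0
        assert res["p_value"].iloc[0] < 0.01

    def test_k_equal_n_rejected(self):
        coords = np.random.default_rng(0).uniform(size=(10, 2))
        with pytest.raises(ValueError, match="smaller"):
            fossil_model.morans_test(np.zeros(10), coords, k_range=[10])

    def test_default_range_covers_one_to_twenty(self, lm_fit, arch_dataset, design):
        arch, _ = arch_dataset
        rng = np.random.default_rng(53)
        coords = rng.uniform(0, 360, size=(len(arch), 2))
        X = sm.add_constant(design.values).to_numpy()
        resid = np.log1p(arch["n_fossil"].to_numpy()) - X @ lm_fit.coefficients.to_numpy()
        res = fossil_model.morans_test(resid, coords)
        assert list(res["k"]) == list(range(1, 21))
        assert res["p_value"].between(0, 1).all()
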
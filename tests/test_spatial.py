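import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from stygoscale.errors import FitError, StygoscaleError
from stygoscale.spatial import (
    MaternParams,
    autocorrelation_range,
    final_presence_model,
    fit_spatial_glmm,
    format_fit_report,
    matern_correlation,
    matern_matrix,
    nitrate_models,
    simulate_glmm_response,
    stepwise_backward_aic,
)


class TestMaternCorrelation:
    def test_zero_lag(self):
        assert matern_correlation(0.0, 1.26, 0.00061) == 1.0

    @pytest.mark.parametrize("rd", [0.1, 1.0, 5.0])
    def test_exponential_special_case(self, rd):
        assert matern_correlation(rd, 0.5, 1.0) == pytest.approx(
            np.exp(-rd), abs=1e-10)

    def test_nu_three_halves_closed_form(self):
        # (1 + rho d) exp(-rho d) under this parameterization
        assert matern_correlation(1.0, 1.5, 1.0) == pytest.approx(
            2.0 * np.exp(-1.0), abs=1e-8)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 5000, 200)
        c = matern_correlation(d, 1.26, 0.00061)
        assert np.all(np.diff(c) < 0)

    def test_invalid_params(self):
        with pytest.raises(StygoscaleError):
            matern_correlation(1.0, -0.5, 1.0)
        with pytest.raises(StygoscaleError):
            matern_correlation(1.0, 0.5, 0.0)

    @pytest.mark.parametrize("nu", [0.3, 1.0, 2.7])
    def test_matrix_positive_definite(self, nu, rng):
        coords = rng.uniform(0, 10000, (50, 2))
        C = matern_matrix(coords, nu, 0.001)
        assert np.linalg.eigvalsh(C).min() > -1e-8


class TestSpatialGLMMCore:
    @pytest.fixture(scope="class")
    def binom_data(self):
        rng = np.random.default_rng(21)
        n = 120
        coords = rng.uniform(0, 15000, (n, 2))
        X = pd.DataFrame({"Intercept": np.ones(n),
                          "coverage": rng.uniform(0, 100, n)})
        y = simulate_glmm_response(X, coords, [-1.5, 0.03], lam=1.0,
                                   nu=1.26, rho=0.00061, family="binomial",
                                   seed=22)
        return X, y, coords

    def test_lambda_to_zero_recovers_plain_glm(self, binom_data):
        X, y, coords = binom_data
        fit = fit_spatial_glmm(X, y, coords, lambda_fix=1e-8)
        glm = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.terms.estimate.to_numpy(), glm.params,
                                   atol=1e-4)
        assert abs(fit.loglik - glm.llf) / abs(glm.llf) < 1e-3

    def test_gamma_constant_response(self):
        rng = np.random.default_rng(4)
        n = 60
        coords = rng.uniform(0, 5000, (n, 2))
        X = pd.DataFrame({"Intercept": np.ones(n),
                          "coverage": rng.uniform(0, 100, n)})
        y = np.full(n, 12.0)
        fit = fit_spatial_glmm(X, y, coords, family="gamma")
        assert fit.terms.loc["coverage", "estimate"] == pytest.approx(0.0,
                                                                      abs=1e-4)
        # intercept = log link of the constant
        assert fit.terms.loc["Intercept", "estimate"] == pytest.approx(
            np.log(12.0), abs=1e-3)

    def test_seeded_determinism(self, binom_data):
        X, y, coords = binom_data
        a = fit_spatial_glmm(X, y, coords)
        b = fit_spatial_glmm(X, y, coords)
        pd.testing.assert_frame_equal(a.terms, b.terms)

    def test_singular_design_rejected(self, binom_data):
        X, y, coords = binom_data
        X2 = X.copy()
        X2["dup"] = X2["coverage"]
        with pytest.raises(FitError):
            fit_spatial_glmm(X2, y, coords)

    def test_small_n_rejected(self):
        with pytest.raises(FitError):
            fit_spatial_glmm(np.ones((10, 1)), np.ones(10),
                             np.zeros((10, 2)))

    def test_duplicate_coordinates_jittered(self, binom_data):
        X, y, coords = binom_data
        dup = coords.copy()
        dup[1] = dup[0]
        fit = fit_spatial_glmm(X, y, dup)
        assert fit.converged

    def test_report_lists_all_terms(self, binom_data):
        X, y, coords = binom_data
        fit = fit_spatial_glmm(X, y, coords, lambda_fix=0.5)
        report = format_fit_report(fit)
        assert "coverage" in report and "nu, rho" in report


class TestRecovery:
    def test_gamma_slope_recovered(self):
        # small-scale recovery; the full study runs in the acceptance suite
        rng = np.random.default_rng(31)
        n = 150
        ests, ses = [], []
        for rep in range(5):
            coords = rng.uniform(0, 15000, (n, 2))
            X = pd.DataFrame({"Intercept": np.ones(n),
                              "coverage": rng.uniform(0, 100, n)})
            y = simulate_glmm_response(X, coords, [2.7, -0.007], lam=0.2,
                                       nu=1.26, rho=0.00061, family="gamma",
                                       shape=5.0, seed=100 + rep)
            fit = fit_spatial_glmm(X, y, coords, family="gamma")
            ests.append(fit.terms.loc["coverage", "estimate"])
            ses.append(fit.terms.loc["coverage", "se"])
        mean_est = np.mean(ests)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean_est - (-0.007)) < max(2 * mc_se, 2 * np.mean(ses))


class TestStepwise:
    def _make_fit(self, seed, beta_noise=0.0):
        rng = np.random.default_rng(seed)
        n = 120
        coords = rng.uniform(0, 15000, (n, 2))
        X = pd.DataFrame({
            "Intercept": np.ones(n),
            "signal": rng.uniform(0, 100, n),
            "noise": rng.normal(size=n),
        })
        y = simulate_glmm_response(
            X, coords, [-2.0, 0.05, beta_noise], lam=0.5, nu=1.0,
            rho=0.0005, family="binomial", seed=seed + 1)
        return fit_spatial_glmm(X, y, coords)

    def test_noise_dropped_signal_kept(self):
        # AIC drops a 1-df pure-noise term with prob ~P(chi2_1 < 2) ~ 0.84,
        # so a majority of drops is the correct expectation here.
        kept_signal = dropped_noise = 0
        n_reps = 6
        for rep in range(n_reps):
            full = self._make_fit(500 + rep)
            selected, trace = stepwise_backward_aic(full)
            terms = list(selected.design.columns)
            kept_signal += "signal" in terms
            dropped_noise += "noise" not in terms
        assert kept_signal >= n_reps - 1
        assert dropped_noise >= 4

    def test_aic_never_increases(self):
        full = self._make_fit(77)
        selected, trace = stepwise_backward_aic(full)
        aics = [step["aic"] for step in trace]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))
        assert selected.aic <= full.aic + 1e-9

    def test_single_strong_covariate_unchanged(self):
        rng = np.random.default_rng(9)
        n = 120
        coords = rng.uniform(0, 15000, (n, 2))
        X = pd.DataFrame({"Intercept": np.ones(n),
                          "signal": rng.uniform(0, 100, n)})
        y = simulate_glmm_response(X, coords, [-2.5, 0.06], lam=0.3,
                                   nu=1.0, rho=0.0005, family="binomial",
                                   seed=10)
        full = fit_spatial_glmm(X, y, coords)
        selected, trace = stepwise_backward_aic(full)
        assert list(selected.design.columns) == ["Intercept", "signal"]
        assert len(trace) == 1


class TestAutocorrelationRange:
    def test_exponential_closed_form(self):
        mp = MaternParams(nu=0.5, rho=0.001, lam=1.0)
        assert autocorrelation_range(mp, 0.05) == pytest.approx(
            -np.log(0.05) / 0.001, rel=1e-4)

    def test_threshold_one_gives_zero(self):
        assert autocorrelation_range(MaternParams(1.0, 0.001, 1.0), 1.0) == 0.0

    def test_decreasing_in_rho(self):
        ranges = [autocorrelation_range(MaternParams(1.0, r, 1.0))
                  for r in (0.0005, 0.001, 0.002)]
        assert ranges[0] > ranges[1] > ranges[2]

    def test_invalid_threshold(self):
        with pytest.raises(StygoscaleError):
            autocorrelation_range(MaternParams(1.0, 0.001, 1.0), 0.0)


class TestModelSurfaces:
    def test_nitrate_models_signs_on_default_simulation(self, small_study):
        fits = nitrate_models(small_study["sites"],
                              small_study["proportions"], size=600)
        assert fits["crop"].terms.loc["crop", "estimate"] > 0
        assert fits["forest"].terms.loc["forest", "estimate"] < 0
        for fit in fits.values():
            assert fit.family == "gamma"

    def test_nitrate_refuses_few_sites(self, small_study):
        few = small_study["sites"].copy()
        few.loc[few.index[5:], "nitrate_mg_l"] = np.nan
        with pytest.raises(FitError, match="nitrate"):
            nitrate_models(few, small_study["proportions"])

    def test_final_presence_model_keeps_gradient(self, small_study):
        from stygoscale.site_stats import forest_agriculture_gradient

        props = small_study["proportions"]
        at_true = props[(props.size_m == 600) & (props.buffer_type == "catchment")]
        wide = at_true.pivot(index="site_id", columns="class",
                             values="proportion")
        rng = np.random.default_rng(2)
        cov = pd.DataFrame({
            "site_id": wide.index,
            "land_use": forest_agriculture_gradient(
                wide.forest, wide.pasture, wide.crop),
            "noise_cov": rng.normal(size=len(wide)),
        })
        selected, trace, full = final_presence_model(
            small_study["sites"], cov)
        assert "land_use" in selected.design.columns
        assert selected.terms.loc["land_use", "estimate"] > 0
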
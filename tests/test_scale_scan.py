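import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import logit_glm_oracle

from stygoscale.errors import DegenerateResponseError, StygoscaleError
from stygoscale.scale_scan import (
    fit_binomial_glm,
    mcfadden_pseudo_r2,
    peak_scale,
    scan,
    subsample_r2_sd,
    zone_summary,
)


def _dataset(n=25, beta0=-1.0, beta1=0.03, seed=42):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 100, n)
    y = rng.binomial(1, expit(beta0 + beta1 * x))
    if y.min() == y.max():  # re-draw a degenerate sample deterministically
        return _dataset(n, beta0, beta1, seed + 1)
    return x, y


class TestBinomialGLM:
    def test_null_effect_small_z(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 500)
        y = rng.binomial(1, 0.4, 500)
        fit = fit_binomial_glm(x, y)
        assert abs(fit.slope / fit.slope_se) < 3

    @pytest.mark.parametrize("seed", [42, 43, 44])
    def test_matches_likelihood_oracle(self, seed):
        x, y = _dataset(seed=seed)
        fit = fit_binomial_glm(x, y)
        (b0, b1), _ = logit_glm_oracle(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-6)
        assert fit.slope == pytest.approx(b1, abs=1e-6)

    def test_separation_flagged(self):
        x, y = _dataset(n=40)
        y_sep = (x > np.median(x)).astype(float)
        fit = fit_binomial_glm(x, y_sep)
        assert not fit.converged

    def test_single_class_rejected(self):
        x, _ = _dataset()
        with pytest.raises(DegenerateResponseError):
            fit_binomial_glm(x, np.ones_like(x))

    def test_deviance_at_most_null(self):
        x, y = _dataset(n=60)
        fit = fit_binomial_glm(x, y)
        assert fit.deviance <= fit.null_deviance + 1e-8


class TestPseudoR2:
    def test_direct_formula(self):
        assert mcfadden_pseudo_r2(50.0, 100.0) == 0.5
        assert mcfadden_pseudo_r2(100.0, 100.0) == 0.0

    def test_equals_likelihood_ratio_from_oracle(self):
        x, y = _dataset(n=30, seed=7)
        fit = fit_binomial_glm(x, y)
        _, ll_full = logit_glm_oracle(x, y)
        p0 = y.mean()
        ll_null = np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0))
        r2 = mcfadden_pseudo_r2(fit.deviance, fit.null_deviance)
        assert r2 == pytest.approx(1.0 - ll_full / ll_null, abs=1e-6)

    def test_intercept_only_model_scores_zero(self):
        x, y = _dataset(n=50, seed=9)
        fit = fit_binomial_glm(np.zeros_like(x) + 1e-12, y)
        assert mcfadden_pseudo_r2(fit.deviance, fit.null_deviance) == pytest.approx(
            0.0, abs=1e-8)

    def test_bad_null_deviance(self):
        with pytest.raises(StygoscaleError):
            mcfadden_pseudo_r2(1.0, 0.0)


class TestSubsampleSD:
    def test_constant_covariate_gives_zero_sd(self):
        rng = np.random.default_rng(1)
        y = rng.binomial(1, 0.5, 60)
        x = np.full(60, 30.0)
        assert subsample_r2_sd(x, y, reps=30, seed=2) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_seeded_determinism(self):
        x, y = _dataset(n=80, seed=3)
        a = subsample_r2_sd(x, y, reps=50, seed=11)
        b = subsample_r2_sd(x, y, reps=50, seed=11)
        assert a == b

    def test_monte_carlo_stability(self):
        x, y = _dataset(n=120, seed=5)
        big = subsample_r2_sd(x, y, reps=400, seed=1)
        small = subsample_r2_sd(x, y, reps=200, seed=2)
        assert abs(big - small) / big < 0.25

    def test_too_few_reps(self):
        x, y = _dataset(n=80)
        with pytest.raises(StygoscaleError):
            subsample_r2_sd(x, y, reps=1)


class TestScan:
    def test_cardinality(self, small_study):
        cells = scan(small_study["sites"], small_study["proportions"],
                     reps=0, classes=("forest", "pasture", "crop"))
        assert len(cells) == 4 * 2 * 3  # sizes x types x classes

    def test_forest_slope_positive_at_true_scale(self, small_study):
        cells = scan(small_study["sites"], small_study["proportions"], reps=0)
        at600 = cells[cells.size_m == 600]
        assert (at600[at600["class"] == "forest"].slope > 0).all()

    def test_shuffled_labels_lose_the_peak(self, small_study):
        cells = scan(small_study["sites"], small_study["proportions"], reps=0)
        forest_peak = cells[cells["class"] == "forest"].pseudo_r2.max()
        rng = np.random.default_rng(17)
        wins = 0
        n_shuffles = 10
        for _ in range(n_shuffles):
            shuffled = small_study["sites"].copy()
            shuffled["presence"] = rng.permutation(shuffled["presence"].to_numpy())
            null_cells = scan(shuffled, small_study["proportions"], reps=0)
            if null_cells.pseudo_r2.max() < forest_peak:
                wins += 1
        assert wins >= 0.9 * n_shuffles


class TestPeakScale:
    def test_argmax(self):
        cells = pd.DataFrame({
            "size_m": [400, 600, 800],
            "pseudo_r2": [0.02, 0.05, 0.03],
        })
        cells = pd.concat([cells, cells]).reset_index(drop=True)
        best, profile = peak_scale(cells)
        assert best == 600
        assert list(profile.size_m) == [400, 600, 800]

    def test_flat_profile_ties_to_smallest(self):
        cells = pd.DataFrame({
            "size_m": [200, 400, 600] * 2,
            "pseudo_r2": [0.04] * 6,
        })
        best, _ = peak_scale(cells)
        assert best == 200

    def test_empty_scan_rejected(self):
        with pytest.raises(StygoscaleError):
            peak_scale(pd.DataFrame(columns=["size_m", "pseudo_r2"]))

    def test_sd_of_mean_uses_combination_count(self):
        cells = pd.DataFrame({
            "size_m": [600] * 6 + [400] * 6,
            "pseudo_r2": list(np.linspace(0.01, 0.06, 6)) * 2,
        })
        _, profile = peak_scale(cells)
        vals = np.linspace(0.01, 0.06, 6)
        expected = vals.std(ddof=1) / np.sqrt(6)
        assert profile.sd_of_mean.iloc[0] == pytest.approx(expected)


class TestZoneSummary:
    def test_printed_arithmetic(self):
        zs = zone_summary([327.0], scale_interval=(400.0, 1000.0))
        assert zs.fold_range[0] == pytest.approx(400 / 327, abs=1e-12)
        assert zs.fold_range[1] == pytest.approx(1000 / 327, abs=1e-12)
        assert round(zs.fold_range[0], 1) == 1.2
        assert round(zs.fold_range[1]) == 3

    def test_equal_extents_fold_one(self):
        zs = zone_summary([250.0] * 5, scale_interval=(250.0, 250.0))
        assert zs.fold_range == (1.0, 1.0)
        assert zs.fraction_below == 0.0

    def test_median_matches_sorting_oracle(self, rng):
        extents = rng.lognormal(np.log(300), 0.5, 1000)
        zs = zone_summary(extents)
        srt = np.sort(extents)
        oracle = 0.5 * (srt[499] + srt[500])
        assert zs.median_extent == pytest.approx(oracle)

    def test_empty_rejected(self):
        with pytest.raises(StygoscaleError):
            zone_summary([])
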
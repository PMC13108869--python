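import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from divekin.models import (
    ModelSpec,
    SeparationError,
    compare_models,
    fit_feeding_glmm,
    fit_logistic_glmm,
    predict_feeding,
    table4_candidate_specs,
)
from divekin.simulate import simulate_dive_features


def simulate_glmm_data(seed, n=400, n_groups=10, beta0=0.5, beta1=-2.0,
                       group_sd=0.5):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, n)
    u = rng.normal(0.0, group_sd, n_groups)
    x = rng.normal(size=n)
    eta = beta0 + beta1 * x + u[g]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, pd.DataFrame({"x": x}), g


class TestFitLogisticGlmm:
    def test_recovers_generating_coefficients(self):
        y, X, g = simulate_glmm_data(0)
        fit = fit_logistic_glmm(y, X, g)
        assert fit.converged
        assert fit.params["Intercept"] == pytest.approx(0.5, abs=3 * fit.bse["Intercept"])
        assert fit.params["x"] == pytest.approx(-2.0, abs=3 * fit.bse["x"])
        assert 0.1 < fit.re_sd < 1.5

    def test_null_model_balanced_response(self):
        rng = np.random.default_rng(5)
        n = 400
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        g = rng.integers(0, 10, n)
        fit = fit_logistic_glmm(y, pd.DataFrame(index=range(n)), g)
        # logit(0.5) = 0
        assert abs(fit.params["Intercept"]) <= 2 * fit.bse["Intercept"] + 0.05

    def test_all_ones_is_separation_error(self):
        with pytest.raises(SeparationError):
            fit_logistic_glmm(np.ones(50), pd.DataFrame(index=range(50)),
                              np.zeros(50, dtype=int))

    def test_aic_identity(self):
        y, X, g = simulate_glmm_data(1)
        fit = fit_logistic_glmm(y, X, g)
        k = len(fit.params) + 1  # fixed effects + random-intercept variance
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood, abs=1e-9)
        assert fit.k_params == k

    def test_affine_rescaling_of_covariate(self):
        y, X, g = simulate_glmm_data(2)
        fit1 = fit_logistic_glmm(y, X, g)
        X2 = pd.DataFrame({"x": 10.0 * X["x"] + 3.0})
        fit2 = fit_logistic_glmm(y, X2, g)
        # slope scales by 1/10; intercept absorbs the shift
        assert fit2.params["x"] == pytest.approx(fit1.params["x"] / 10.0, rel=1e-3)
        assert fit2.params["Intercept"] == pytest.approx(
            fit1.params["Intercept"] - 3.0 * fit1.params["x"] / 10.0, rel=1e-3, abs=1e-3
        )
        assert fit2.log_likelihood == pytest.approx(fit1.log_likelihood, abs=1e-4)

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's adaptive-quadrature ML fit."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        y, X, g = simulate_glmm_data(7, n=150, n_groups=8, beta0=0.3,
                                     beta1=-1.2, group_sd=0.6)
        df = pd.DataFrame({"y": y.astype(int), "x": X["x"], "g": g})
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=',')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        b0, b1, sd, ll = map(float, out.stdout.strip().split(","))
        fit = fit_logistic_glmm(y, X, g)
        assert fit.params["Intercept"] == pytest.approx(b0, abs=1e-3)
        assert fit.params["x"] == pytest.approx(b1, abs=1e-3)
        assert fit.re_sd == pytest.approx(sd, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-3)


class TestFeedingGlmm:
    def test_excludes_ambiguous_labels(self):
        feats = simulate_dive_features(n_dives=300, seed=3)
        feats.loc[:20, "label"] = "PotentialForaging"
        feats.loc[21:40, "label"] = "NoVideo"
        spec = ModelSpec("speed", ("bottom_mean_speed",))
        fit = fit_feeding_glmm(feats, spec)
        assert fit.n_obs == len(feats) - 41

    def test_speed_coefficient_negative(self):
        # slower bottom speed marks feeding: the coefficient must be negative
        feats = simulate_dive_features(n_dives=400, seed=4)
        fit = fit_feeding_glmm(feats, ModelSpec("speed", ("bottom_mean_speed",)))
        assert fit.params["bottom_mean_speed"] < 0
        assert fit.pvalues["bottom_mean_speed"] < 0.01


class TestCompareModels:
    def test_identical_specs_identical_aic(self):
        feats = simulate_dive_features(n_dives=250, seed=5)
        s = ModelSpec("a", ("bottom_mean_speed",))
        s2 = ModelSpec("b", ("bottom_mean_speed",))
        table = compare_models(feats, [s, s2])
        aics = table.set_index("model")["AIC"]
        assert abs(aics["a"] - aics["b"]) < 1e-6

    def test_true_model_beats_null(self):
        feats = simulate_dive_features(n_dives=250, seed=6)
        specs = [
            ModelSpec("NULL", ()),
            ModelSpec("truth", ("bottom_mean_speed", "tod")),
        ]
        table = compare_models(feats, specs)
        row = table.set_index("model").loc["truth"]
        assert row["dAIC"] > 0
        assert table.attrs["selected"] == "truth"

    def test_noise_covariate_rarely_selected(self):
        # AIC's 2-per-parameter penalty: a pure-noise covariate should not
        # be selected in most replicates
        wins = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            feats = simulate_dive_features(n_dives=150, seed=seed)
            feats["noise"] = rng.normal(size=len(feats))
            table = compare_models(
                feats, [ModelSpec("NULL", ()), ModelSpec("noise", ("noise",))]
            )
            if table.attrs["selected"] == "noise":
                wins += 1
        assert wins <= 0.30 * n_rep

    def test_common_observation_set_enforced(self):
        feats = simulate_dive_features(n_dives=200, seed=8)
        feats.loc[:30, "speed_change"] = np.nan
        specs = [ModelSpec("a", ("bottom_mean_speed",)),
                 ModelSpec("b", ("bottom_mean_speed", "speed_change"))]
        table = compare_models(feats, specs)
        fits = table.attrs["fits"]
        assert fits["a"].n_obs == fits["b"].n_obs  # listwise over the union


class TestPredictFeeding:
    def test_linear_predictor_zero_gives_half(self):
        y, X, g = simulate_glmm_data(9)
        fit = fit_logistic_glmm(y, X, g)
        x0 = -fit.params["Intercept"] / fit.params["x"]
        p = predict_feeding(fit, pd.DataFrame({"x": [x0]}))
        assert p.iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_dot_product_oracle(self):
        y, X, g = simulate_glmm_data(10)
        fit = fit_logistic_glmm(y, X, g)
        row = pd.DataFrame({"x": [0.7]})
        eta = fit.params["Intercept"] + fit.params["x"] * 0.7
        assert predict_feeding(fit, row).iloc[0] == pytest.approx(
            1.0 / (1.0 + np.exp(-eta))
        )

    def test_monotone_in_speed_when_coefficient_negative(self):
        feats = simulate_dive_features(n_dives=400, seed=11)
        fit = fit_feeding_glmm(feats, ModelSpec("speed", ("bottom_mean_speed",)))
        grid = pd.DataFrame({"bottom_mean_speed": [1.0, 1.4, 1.8]})
        p = predict_feeding(fit, grid)
        assert p.is_monotonic_decreasing

    def test_missing_feature_gives_nan(self):
        y, X, g = simulate_glmm_data(12)
        fit = fit_logistic_glmm(y, X, g)
        p = predict_feeding(fit, pd.DataFrame({"x": [0.1, np.nan]}))
        assert np.isfinite(p.iloc[0]) and np.isnan(p.iloc[1])


def test_candidate_set_shape():
    specs = table4_candidate_specs()
    assert [s.name for s in specs] == ["NULL", "1", "2", "3", "4"]
    assert specs[4].fixed_effects == (
        "bottom_mean_speed", "bottom_peak_jerk", "speed_change",
        "bottom_mean_roll", "bottom_mean_pitch", "tod",
    )
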
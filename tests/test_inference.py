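import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from speechsync.inference import (
    build_predictor_table,
    fdr_adjust,
    fit_binomial_glmm,
    likelihood_ratio_test,
    rate_accuracy_summary,
    variance_inflation_factors,
    zscore_columns,
)
from speechsync.synthetic import ComprehensionSpec, make_comprehension_trials


def bh_oracle(p, q):
    """Benjamini-Hochberg step-up by direct enumeration."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    # adjusted p: monotone min over tail
    adj = np.minimum.accumulate((p[order] * m
                                 / np.arange(1, m + 1))[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return reject, p_adj


class TestPredictorTable:
    def test_zscore_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(3, 2, 500)})
        out = zscore_columns(df, ["x"])
        assert abs(out["x"].mean()) < 1e-12
        assert out["x"].std(ddof=0) == pytest.approx(1.0)

    def test_orthogonal_predictors_unit_vif(self, rng):
        n = 2000
        df = pd.DataFrame({"a": np.repeat([1.0, -1.0], n // 2),
                           "b": np.tile([1.0, -1.0], n // 2)})
        vifs = variance_inflation_factors(df, ["a", "b"])
        assert vifs["a"] == pytest.approx(1.0, abs=1e-9)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_raises(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinearity"):
            variance_inflation_factors(df, ["a", "b"])

    def test_join_and_missing_key_detection(self):
        trials = pd.DataFrame({"participant": [0, 1], "item": [0, 0],
                               "correct": [1, 0]})
        cov = pd.DataFrame({"participant": [0], "motor_rate": [4.0]})
        with pytest.raises(ValueError, match="no covariates"):
            build_predictor_table(trials, participant_covariates=cov)

    def test_join_collision_detected(self):
        trials = pd.DataFrame({"participant": [0], "item": [0],
                               "motor_rate": [1.0], "correct": [1]})
        cov = pd.DataFrame({"participant": [0], "motor_rate": [4.0]})
        with pytest.raises(ValueError, match="collision"):
            build_predictor_table(trials, participant_covariates=cov)


class TestGLM:
    def test_matches_statsmodels_without_random_effects(self, rng):
        n = 600
        x = rng.normal(size=n)
        eta = 0.3 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"correct": y, "x": x})
        fit = fit_binomial_glmm(df, fixed_effects=("x",),
                                random_intercepts=())
        ref = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Binomial()).fit()
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-5)
        assert fit.standard_errors == pytest.approx(ref.bse, rel=1e-3)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-5)

    def test_odds_ratio_is_exp_coefficient(self, rng):
        df = pd.DataFrame({"correct": rng.integers(0, 2, 200),
                           "x": rng.normal(size=200)})
        fit = fit_binomial_glmm(df, fixed_effects=("x",),
                                random_intercepts=())
        assert np.array_equal(fit.odds_ratios, np.exp(fit.coefficients))

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"correct": rng.integers(0, 2, 100),
                           "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_binomial_glmm(df, fixed_effects=("a", "b"),
                              random_intercepts=())

    def test_zscoring_rescales_coefficients(self, rng):
        """Fitting on z-scored x equals raw-x coefficient times sd(x)."""
        n = 800
        x = rng.normal(2.0, 3.0, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.3 * x)))).astype(int)
        raw = pd.DataFrame({"correct": y, "x": x})
        z = zscore_columns(raw, ["x"])
        fr = fit_binomial_glmm(raw, fixed_effects=("x",),
                               random_intercepts=())
        fz = fit_binomial_glmm(z, fixed_effects=("x",),
                               random_intercepts=())
        assert fz.coefficients[1] == pytest.approx(
            fr.coefficients[1] * x.std(ddof=0), abs=1e-6)


class TestGLMM:
    def test_zero_random_effect_recovery_within_2se(self):
        """With no random variation, fixed effects recover the truth."""
        coefs = {"intercept": 0.8, "syllabic_rate": np.log(0.65),
                 "motor_rate": np.log(1.19), "perplexity": np.log(0.84)}
        df, truth = make_comprehension_trials(ComprehensionSpec(
            n_participants=80, n_items=240, coefficients=coefs,
            participant_intercept_sd=0.0, item_intercept_sd=0.0,
            rate_slope_sd=0.0, seed=42))
        tab = build_predictor_table(
            df, zscore=("syllabic_rate", "motor_rate", "perplexity"))
        fit = fit_binomial_glmm(
            tab, fixed_effects=("syllabic_rate", "motor_rate",
                                "perplexity"))
        true_vec = np.array([coefs["intercept"], coefs["syllabic_rate"],
                             coefs["motor_rate"], coefs["perplexity"]])
        z = (fit.coefficients - true_vec) / fit.standard_errors
        assert np.all(np.abs(z) < 2.0), z

    def test_matches_lme4_glmer_on_small_fixture(self, tmp_path):
        """Independent oracle: R lme4 glmer (Laplace) on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df, _ = make_comprehension_trials(ComprehensionSpec(
            n_participants=30, n_items=40, seed=7,
            coefficients={"intercept": 0.5, "syllabic_rate": -0.4,
                          "perplexity": -0.2},
            participant_intercept_sd=0.6, item_intercept_sd=0.4,
            rate_slope_sd=0.0))
        tab = build_predictor_table(df, zscore=("syllabic_rate",
                                                "perplexity"))
        fit = fit_binomial_glmm(tab, fixed_effects=("syllabic_rate",
                                                    "perplexity"))
        csv = tmp_path / "d.csv"
        tab[["correct", "syllabic_rate", "perplexity", "participant",
             "item"]].to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(correct ~ syllabic_rate + perplexity +
                       (1|participant) + (1|item), data=d, family=binomial)
            co <- summary(m)$coefficients
            vc <- as.data.frame(VarCorr(m))
            cat(co[,1], co[,2], vc$sdcor, as.numeric(logLik(m)), sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        r_coef, r_se, r_sds, r_ll = (np.array(vals[0:3]), np.array(vals[3:6]),
                                     np.array(vals[6:8]), vals[8])
        assert fit.coefficients == pytest.approx(r_coef, abs=0.03)
        assert fit.standard_errors == pytest.approx(r_se, rel=0.05)
        ours = sorted(fit.random_effect_sds.values())
        assert ours == pytest.approx(sorted(r_sds), abs=0.02)
        assert fit.log_likelihood == pytest.approx(r_ll, abs=0.5)

    def test_null_predictor_or_near_one(self):
        df, _ = make_comprehension_trials(ComprehensionSpec(
            n_participants=60, n_items=80,
            coefficients={"intercept": 0.5, "syllabic_rate": 0.0},
            participant_intercept_sd=0.3, item_intercept_sd=0.2,
            rate_slope_sd=0.0, seed=9))
        tab = build_predictor_table(df, zscore=("syllabic_rate",))
        fit = fit_binomial_glmm(tab, fixed_effects=("syllabic_rate",))
        assert fit.odds_ratios[1] == pytest.approx(1.0, abs=0.12)

    def test_aic_identity(self):
        df, _ = make_comprehension_trials(ComprehensionSpec(
            n_participants=20, n_items=20, seed=3))
        tab = build_predictor_table(df, zscore=("syllabic_rate",))
        fit = fit_binomial_glmm(tab, fixed_effects=("syllabic_rate",))
        assert fit.aic == pytest.approx(
            2 * fit.n_params - 2 * fit.log_likelihood)


class TestLRT:
    def _two_fits(self, seed=5, beta=0.6):
        df, _ = make_comprehension_trials(ComprehensionSpec(
            n_participants=40, n_items=60,
            coefficients={"intercept": 0.3, "syllabic_rate": beta},
            participant_intercept_sd=0.2, item_intercept_sd=0.2,
            rate_slope_sd=0.0, seed=seed))
        tab = build_predictor_table(df, zscore=("syllabic_rate",))
        reduced = fit_binomial_glmm(tab, fixed_effects=())
        full = fit_binomial_glmm(tab, fixed_effects=("syllabic_rate",))
        return reduced, full

    def test_identical_models_chi2_zero_p_one(self):
        reduced, _ = self._two_fits()
        stat, df, p = likelihood_ratio_test(reduced, reduced)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_df_is_parameter_difference(self):
        reduced, full = self._two_fits()
        _, df, _ = likelihood_ratio_test(reduced, full)
        assert df == 1

    def test_strong_effect_detected(self):
        reduced, full = self._two_fits(beta=0.8)
        stat, _, p = likelihood_ratio_test(reduced, full)
        assert p < 1e-4
        assert full.aic < reduced.aic

    def test_different_data_rejected(self):
        r1, _ = self._two_fits(seed=5)
        df, _ = make_comprehension_trials(ComprehensionSpec(
            n_participants=10, n_items=10, seed=1))
        tab = build_predictor_table(df)
        other = fit_binomial_glmm(tab, fixed_effects=())
        with pytest.raises(ValueError, match="different data"):
            likelihood_ratio_test(r1, other)


class TestFDR:
    def test_step_up_worked_example(self):
        reject, _ = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert reject.all()

    def test_single_p(self):
        reject, p_adj = fdr_adjust([0.03], q=0.05)
        assert reject[0]
        assert p_adj[0] == pytest.approx(0.03)

    def test_all_ones_nothing_rejected(self):
        reject, _ = fdr_adjust([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_matches_oracle_on_grids(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.6, 1.0]
        rng = np.random.default_rng(0)
        for m in range(1, 11):
            for _ in range(30):
                p = rng.choice(grid, size=m)
                rej, adj = fdr_adjust(p, q=0.05)
                orej, oadj = bh_oracle(p, 0.05)
                assert np.array_equal(rej, orej), p
                assert adj == pytest.approx(oadj)

    def test_adjusted_monotone_in_raw(self, rng):
        p = np.sort(rng.uniform(size=20))
        _, adj = fdr_adjust(p)
        assert np.all(np.diff(adj) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestRateAccuracySummary:
    def test_all_correct_bin(self):
        df = pd.DataFrame({"syllabic_rate": [5.0] * 10, "correct": [1] * 10})
        out = rate_accuracy_summary(df)
        assert out.loc[0, "accuracy"] == 1.0
        assert out.loc[0, "ci_low"] <= 1.0 <= out.loc[0, "ci_high"] + 1e-12

    def test_wilson_ci_contains_estimate(self, rng):
        df = pd.DataFrame({
            "syllabic_rate": np.repeat([5.0, 10.0, 15.0], 50),
            "correct": rng.integers(0, 2, 150)})
        out = rate_accuracy_summary(df)
        assert ((out.ci_low <= out.accuracy)
                & (out.accuracy <= out.ci_high)).all()

    def test_monotone_decline_under_negative_rate_effect(self):
        df, _ = make_comprehension_trials(ComprehensionSpec(
            n_participants=60, n_items=120,
            coefficients={"intercept": 1.0, "syllabic_rate": np.log(0.65)},
            participant_intercept_sd=0.0, item_intercept_sd=0.0,
            rate_slope_sd=0.0, seed=8))
        out = rate_accuracy_summary(df).sort_values("syllabic_rate")
        acc = out["accuracy"].to_numpy()
        # overall decline from slowest to fastest bin
        assert acc[0] > acc[-1]
        assert np.all(np.diff(acc) < 0.05)
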
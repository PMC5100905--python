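import numpy as np
import pandas as pd
import pytest

from wmhtracts.regression import (
    MarkerComparison,
    TractScreen,
    bonferroni_threshold,
    delta_r2_test,
    fit_ols,
    run_sensitivity,
    standardized_betas,
)


def make_data(rng, n=40, k=3):
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    return X


class TestFitOLS:
    def test_exact_linear_relation_r2_one(self, rng):
        X = make_data(rng, k=1)
        y = 2.0 + 3.0 * X["x0"]
        assert fit_ols(y, X).r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_r2_zero(self):
        x = pd.DataFrame({"x0": [-1.0, 1.0, -1.0, 1.0, -1.0, 1.0]})
        y = pd.Series([1.0, 1.0, 0.0, 0.0, -1.0, -1.0])
        assert fit_ols(y, x).r2 == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        X = make_data(rng, n=8, k=2)
        y = pd.Series(rng.normal(size=8))
        fit = fit_ols(y, X)
        # independent oracle: solve (D'D) b = D'y directly
        D = np.column_stack([np.ones(8), X.to_numpy()])
        b = np.linalg.solve(D.T @ D, D.T @ y.to_numpy())
        assert np.allclose([fit.params["const"], fit.params["x0"], fit.params["x1"]],
                           b, atol=1e-10)
        rss = float(((y.to_numpy() - D @ b) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        assert fit.r2 == pytest.approx(1 - rss / tss, abs=1e-10)

    def test_rank_deficiency_names_collinear_column(self, rng):
        X = make_data(rng, k=2)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(ValueError, match="dup|x0"):
            fit_ols(pd.Series(rng.normal(size=len(X))), X)

    def test_missing_values_rejected(self, rng):
        X = make_data(rng, k=1)
        y = pd.Series(rng.normal(size=len(X)))
        y.iloc[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_ols(y, X)


class TestDeltaR2:
    def test_f_matches_rss_based_oracle(self, rng):
        X = make_data(rng, n=30, k=3)
        y = pd.Series(X["x0"] * 0.5 + rng.normal(size=30))
        small = fit_ols(y, X[["x0"]])
        big = fit_ols(y, X)
        dr2, f_stat, p = delta_r2_test(small, big)
        # oracle: classical F from residual sums of squares
        f_oracle = ((small.rss - big.rss) / 2) / (big.rss / (30 - 3 - 1))
        assert f_stat == pytest.approx(f_oracle, abs=1e-10)
        assert dr2 == pytest.approx(big.r2 - small.r2, abs=1e-12)

    def test_single_predictor_p_equals_squared_t(self, rng):
        X = make_data(rng, n=25, k=2)
        y = pd.Series(rng.normal(size=25))
        small = fit_ols(y, X[["x0"]])
        big = fit_ols(y, X)
        _, _, p = delta_r2_test(small, big)
        assert p == pytest.approx(float(big.result.pvalues["x1"]), abs=1e-10)

    def test_non_nested_models_error(self, rng):
        X = make_data(rng, n=20, k=2)
        y = pd.Series(rng.normal(size=20))
        with pytest.raises(ValueError, match="nested"):
            delta_r2_test(fit_ols(y, X[["x0"]]), fit_ols(y, X[["x1"]]))

    def test_delta_r2_nonnegative_for_nested(self, rng):
        for _ in range(10):
            X = make_data(rng, n=15, k=3)
            y = pd.Series(rng.normal(size=15))
            dr2, _, _ = delta_r2_test(fit_ols(y, X[["x0"]]), fit_ols(y, X))
            assert dr2 >= -1e-12


class TestStandardizedBetas:
    def test_simple_regression_beta_is_pearson_r(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        fit = fit_ols(pd.Series(y), pd.DataFrame({"x": x}))
        beta = standardized_betas(fit).loc["x", "beta"]
        assert beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_matches_refit_on_zscored_variables(self, rng):
        X = make_data(rng, n=60, k=3)
        y = pd.Series(X @ [0.3, -0.2, 0.1] + rng.normal(size=60))
        fit = fit_ols(y, X)
        betas = standardized_betas(fit)
        Xz = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        refit = fit_ols(yz, Xz)
        for c in X.columns:
            assert betas.loc[c, "beta"] == pytest.approx(refit.params[c], abs=1e-10)

    def test_ci_uses_normal_multiplier(self, rng):
        X = make_data(rng, n=30, k=1)
        y = pd.Series(rng.normal(size=30))
        fit = fit_ols(y, X)
        row = standardized_betas(fit).loc["x0"]
        half = (row.ci_high - row.ci_low) / 2
        se = fit.result.bse["x0"] * X["x0"].std(ddof=1) / y.std(ddof=1)
        assert half == pytest.approx(1.96 * se, abs=1e-12)

    def test_null_marker_ci_covers_zero_95pct(self, rng):
        # coverage simulation: y never depends on the marker
        n, reps = 167, 500
        marker = rng.normal(size=n)
        age = rng.normal(size=n)
        covered = 0
        X = pd.DataFrame({"age": age, "marker": marker})
        for _ in range(reps):
            y = pd.Series(0.4 * age + rng.normal(size=n))
            row = standardized_betas(fit_ols(y, X)).loc["marker"]
            covered += row.ci_low <= 0 <= row.ci_high
        assert covered / reps >= 0.93


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 13, 0.05 / 13), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
    )
    def test_threshold_arithmetic(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_13_comparisons_displays_as_0038(self):
        assert f"{bonferroni_threshold(0.05, 13):.4f}" == "0.0038"


class TestTractScreen:
    def test_noiseless_single_effect_recovered_exactly(self, cohort_run):
        from wmhtracts.simulate import SynthTruth, generate_cognition

        cohort = cohort_run["cohort"]
        truth = SynthTruth(seed=0, noise_sd=0.0,
                           tract_effects={"executive": {"anterior_thalamic_radiation": -0.3}},
                           covariate_effects={"age": -0.45, "education": 0.35, "sex": 0.15})
        vols = cohort.filter(regex="^(subject_id|total_wmh_ml|wmh_)")
        covs = cohort[["subject_id", "age", "sex", "education", "lacunes_present"]]
        scores = generate_cognition(vols, cohort, truth)
        data = covs.merge(vols, on="subject_id").merge(scores, on="subject_id")
        res = TractScreen(data, outcomes=("executive",)).fit()
        true_model = res.get("3b:anterior_thalamic_radiation", "executive")
        assert true_model.r2 == pytest.approx(1.0, abs=1e-10)
        # the raw coefficient on the standardized volume equals the planted effect
        col = "wmh_anterior_thalamic_radiation_ml"
        x = data[col]
        y = data["executive"]
        fit = fit_ols(y, pd.DataFrame({"z": (x - x.mean()) / x.std(ddof=1),
                                       "age": data["age"], "sex": data["sex"],
                                       "education": data["education"]}))
        assert fit.params["z"] == pytest.approx(-0.3, abs=1e-8)

    def test_screen_layout_and_nesting(self, cohort_run):
        res = TractScreen(cohort_run["cohort"]).fit()
        df = res.to_frame()
        # 13 models per outcome, three outcomes
        assert len(df) == 13 * 3
        for outcome in ("executive", "speed", "memory"):
            block = df[df.outcome == outcome]
            assert block.iloc[0]["model"] == "1"
            assert (block["r2"] >= block.iloc[0]["r2"] - 1e-12).all()
            assert block["n"].nunique() == 1  # complete cases shared across the pair set

    def test_missing_tract_column_is_error(self, cohort_run):
        cohort = cohort_run["cohort"].drop(columns=["wmh_forceps_minor_ml"])
        with pytest.raises(KeyError, match="forceps_minor"):
            TractScreen(cohort)


class TestMarkerComparison:
    def test_bpf_only_cognition_makes_model2d_dominant(self, covariates167, rng):
        cov = covariates167.copy()
        z = (cov["bpf"] - cov["bpf"].mean()) / cov["bpf"].std(ddof=1)
        for d in ("executive", "speed", "memory"):
            cov[d] = 0.6 * z + rng.normal(0, 0.6, len(cov))
        cov["total_wmh_ml"] = rng.lognormal(2.5, 1.0, len(cov))
        cov["wmh_forceps_minor_ml"] = rng.lognormal(1.0, 1.0, len(cov))
        cov["wmh_anterior_thalamic_radiation_ml"] = rng.lognormal(1.2, 1.0, len(cov))
        res = MarkerComparison(cov).fit()
        block = [r for r in res.results if r.outcome == "executive" and r.model_id.startswith("2")]
        best = max(block, key=lambda r: r.delta_r2)
        assert best.model_id == "2d:bpf"

    def test_layout_includes_single_marker_models(self, cohort_run):
        res = MarkerComparison(cohort_run["cohort"]).fit()
        ids = {r.model_id for r in res.results}
        assert {"1", "2a:total_wmh_ml", "2b:wmh_forceps_minor_ml",
                "2c:wmh_anterior_thalamic_radiation_ml", "2d:bpf",
                "3a:total_wmh_ml"} <= ids
        singles = {r.model_id for r in res.single_marker}
        assert singles == {"single:lacunes_present", "single:microbleeds_present"}
        # microbleed models are complete-case: 4 subjects missing status
        mb = [r for r in res.single_marker if "microbleeds" in r.model_id][0]
        assert mb.n == len(cohort_run["cohort"]) - 4

    def test_bpf_association_models_report_each_wmh_measure(self, cohort_run):
        res = MarkerComparison(cohort_run["cohort"]).fit()
        ids = [r.model_id for r in res.bpf_association]
        assert ids == ["bpf~total_wmh_ml", "bpf~wmh_forceps_minor_ml",
                       "bpf~wmh_anterior_thalamic_radiation_ml"]


class TestSensitivity:
    def test_no_exclusions_identical_to_full_run(self, cohort_run):
        cohort = cohort_run["cohort"].copy()
        cohort["diagnosis"] = "other"
        full = MarkerComparison(cohort).fit().to_frame()
        sens = run_sensitivity(cohort).to_frame()
        pd.testing.assert_frame_equal(full, sens)

    def test_subset_equals_direct_run_on_subset(self, cohort_run):
        cohort = cohort_run["cohort"]
        sens = run_sensitivity(cohort).to_frame()
        direct = MarkerComparison(cohort[cohort.diagnosis != "AD"]).fit().to_frame()
        pd.testing.assert_frame_equal(sens, direct)
        assert (sens["n"] < len(cohort)).all()
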
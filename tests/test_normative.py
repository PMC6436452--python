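"""Normative regression, elimination, Z-scoring, flagging, and bands."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sr2norm import (
    GENERATIVE_COLOCATED,
    GENERATIVE_SEPARATED,
    GENERATIVE_SRM,
    CohortValidationWarning,
    ExtrapolationWarning,
    GenerativeConfig,
    NormativeModel,
    correlation_table,
    fit_all_models,
    fit_normative_model,
    fit_normative_vectors,
    flag_outliers,
    make_recovery_cohort,
    model_error,
    normative_band,
    ols_fit,
    predict_threshold,
    simulate_cohort,
    z_score,
)
from sr2norm.normative import ALL_MODEL_KEYS


def normal_equation_oracle(X, y):
    """Independent OLS oracle: explicit (X'X)^-1 X'y with an intercept column."""
    Xc = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


class TestOls:
    def test_matches_normal_equation_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = rng.integers(8, 40)
            p = rng.integers(1, 5)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = ols_fit(X, y)
            np.testing.assert_allclose(
                fit.params, normal_equation_oracle(X, y), atol=1e-8, rtol=0
            )

    def test_exact_linear_data_recovered(self):
        age = np.arange(18, 78, dtype=float)
        y = 2.0 + 0.05 * age
        fit = ols_fit(age[:, None], y, names=("age",))
        assert fit.coef("const") == pytest.approx(2.0, abs=1e-10)
        assert fit.coef("age") == pytest.approx(0.05, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_predictor_gets_zero_coefficient(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 4)
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # strip any linear dependence
        fit = ols_fit(x[:, None], y, names=("x",))
        assert fit.coef("x") == pytest.approx(0.0, abs=1e-10)

    def test_p_values_use_t_distribution(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        fit = ols_fit(X, y)
        t = fit.params / fit.bse
        manual = 2 * stats.t.sf(np.abs(t), 30 - 2 - 1)
        np.testing.assert_allclose(fit.p_values, manual, atol=1e-12)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit(X, np.arange(10.0))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            ols_fit(np.ones((3, 2)) + np.arange(6).reshape(3, 2), np.arange(3.0))


class TestFitNormativeModel:
    def test_zero_noise_separated_truth_recovered_exactly(self):
        cohort = make_recovery_cohort(GENERATIVE_SEPARATED, 400, seed=2, noise_sd=0.0)
        model = fit_normative_model(cohort, "separated", "average")
        assert set(model.predictors) == {"age", "pta"}
        assert model.constant == pytest.approx(-8.617, abs=1e-8)
        assert model.beta_age == pytest.approx(0.053, abs=1e-10)
        assert model.beta_pta == pytest.approx(0.164, abs=1e-10)
        assert model.model_error == pytest.approx(0.0, abs=1e-8)

    def test_srm_parameter_recovery_eliminates_age(self):
        cohort = make_recovery_cohort(GENERATIVE_SRM, 2000, seed=101)
        model = fit_normative_model(cohort, "srm", "average")
        assert model.predictors == ("pta",)
        # within 3 Monte-Carlo standard errors of generative truth
        fit = ols_fit(cohort.df[["pta_st"]], cohort.outcome("srm", "average"))
        assert abs(model.constant - 9.166) < 3 * fit.se("const")
        assert abs(model.beta_pta - (-0.171)) < 3 * fit.se("pta_st")
        assert model.model_error == pytest.approx(1.830, abs=0.1)

    def test_elimination_is_deterministic(self, default_cohort):
        a = fit_all_models(default_cohort)
        b = fit_all_models(default_cohort)
        assert a == b

    def test_all_predictors_eliminated_warns_intercept_only(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(18, 80, 300)
        ptav = rng.uniform(0, 45, 300)
        y = rng.normal(0, 1, 300)  # unrelated outcome
        with pytest.warns(UserWarning, match="intercept-only"):
            model = fit_normative_vectors(age, ptav, y, "srm", "average")
        assert model.predictors == ()
        assert model.constant == pytest.approx(y.mean())

    def test_recovery_replicates_at_study_size(self):
        """Over replicates at n=82 the SRM slope is unbiased and its nominal
        95% CI covers the generative truth at close to nominal rate."""
        slopes, ses, cover = [], [], 0
        n_rep = 120
        for rep in range(n_rep):
            cohort = make_recovery_cohort(GENERATIVE_SRM, 82, seed=5000 + rep)
            fit = ols_fit(cohort.df[["pta_st"]], cohort.outcome("srm", "average"))
            b, se = fit.coef("pta_st"), fit.se("pta_st")
            slopes.append(b)
            ses.append(se)
            tcrit = stats.t.ppf(0.975, 80)
            cover += abs(b - (-0.171)) <= tcrit * se
        mc_se = np.std(slopes, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(slopes) - (-0.171)) < 2 * mc_se
        assert 0.90 <= cover / n_rep <= 0.99


class TestModelError:
    def test_perfect_fit_is_zero_by_either_method(self):
        cohort = make_recovery_cohort(GENERATIVE_SRM, 200, seed=3, noise_sd=0.0)
        model = fit_normative_model(cohort, "srm", "average")
        assert model_error(model, cohort, "rmse") == pytest.approx(0.0, abs=1e-8)
        assert model_error(model, cohort, "mae") == pytest.approx(0.0, abs=1e-8)

    def test_unit_residuals_give_unit_error(self):
        cohort = make_recovery_cohort(GENERATIVE_SRM, 200, seed=3, noise_sd=0.0)
        model = fit_normative_model(cohort, "srm", "average")
        import dataclasses

        shifted = dataclasses.replace(model, constant=model.constant + 1.0)
        assert model_error(shifted, cohort, "rmse") == pytest.approx(1.0, abs=1e-8)
        assert model_error(shifted, cohort, "mae") == pytest.approx(1.0, abs=1e-8)

    def test_rmse_consistent_for_normal_noise(self):
        cohort = make_recovery_cohort(GENERATIVE_SRM, 20000, seed=6)
        model = fit_normative_model(cohort, "srm", "average")
        assert model_error(model, cohort, "rmse") == pytest.approx(1.830, abs=0.05)

    def test_unknown_method_rejected(self, default_cohort):
        model = fit_normative_model(default_cohort, "srm", "average")
        with pytest.raises(ValueError, match="model-error method"):
            model_error(model, default_cohort, "median")


class TestPrediction:
    def test_constant_only_terms(self):
        assert predict_threshold(GENERATIVE_SRM, pta=0.0) == pytest.approx(9.166)

    def test_separated_hand_arithmetic(self):
        assert predict_threshold(
            GENERATIVE_SEPARATED, age=50, pta=10
        ) == pytest.approx(-4.327, abs=1e-9)

    def test_srm_diminishes_to_near_zero_at_50_db(self):
        with pytest.warns(ExtrapolationWarning):
            val = predict_threshold(GENERATIVE_SRM, pta=50.0)
        assert val == pytest.approx(0.616, abs=1e-9)

    def test_missing_required_predictor_rejected(self):
        with pytest.raises(ValueError, match="requires a PTA"):
            predict_threshold(GENERATIVE_SRM)


class TestZScore:
    def test_observed_equals_predicted(self):
        entry = z_score(GENERATIVE_SRM, observed=9.166, pta=0.0)
        assert entry.z == pytest.approx(0.0, abs=1e-12)
        assert not entry.flagged

    def test_two_sd_boundary_is_inclusive(self):
        pred = predict_threshold(GENERATIVE_SRM, pta=10.0)
        entry = z_score(GENERATIVE_SRM, pred + 2 * 1.830, pta=10.0)
        assert entry.z == pytest.approx(2.0, abs=1e-12)
        assert entry.flagged

    def test_poor_srm_example(self):
        entry = z_score(GENERATIVE_SRM, observed=2.0, pta=10.0)
        assert entry.z == pytest.approx(-2.981, abs=1e-3)
        assert entry.flagged

    @pytest.mark.parametrize("c", [-3.0, -2.0, -0.5, 0.0, 1.5, 2.0, 2.7])
    def test_z_identity_for_any_multiple(self, c):
        model = GENERATIVE_SEPARATED
        pred = predict_threshold(model, age=60, pta=20)
        entry = z_score(model, pred + c * model.model_error, age=60, pta=20)
        assert entry.z == pytest.approx(c, rel=1e-12, abs=1e-12)
        assert entry.flagged == (abs(c) >= 2)

    def test_zero_model_error_rejected(self):
        broken = NormativeModel("srm", "average", ("pta",), 9.166,
                                beta_pta=-0.171, model_error=0.0)
        with pytest.raises(ValueError, match="model error"):
            z_score(broken, 5.0, pta=10.0)


class TestFlagOutliers:
    @staticmethod
    def _generative_nine():
        models = {}
        for meas, truth in (("colocated", GENERATIVE_COLOCATED),
                            ("separated", GENERATIVE_SEPARATED),
                            ("srm", GENERATIVE_SRM)):
            for run in ("1", "2", "average"):
                d = truth.to_dict() | {"run": run}
                models[(meas, run)] = NormativeModel.from_dict(d)
        return models

    def test_zero_noise_cohort_has_no_flags(self):
        cfg = GenerativeConfig(
            n=30, seed=2, slope=1e-9, chance=1e-9,
            deviation_sd={"colocated": 0.0, "separated": 0.0},
            practice_run2={"colocated": 0.0, "separated": 0.0},
        )
        cohort = simulate_cohort(cfg)
        flagged, reports = flag_outliers(cohort, self._generative_nine())
        assert flagged == []
        assert len(reports) == 30 * 9

    def test_flagged_fraction_within_theoretical_bounds(self):
        cohort = simulate_cohort(GenerativeConfig(n=2000, seed=13))
        models = fit_all_models(cohort)
        flagged, _ = flag_outliers(cohort, models)
        frac = len(flagged) / len(cohort)
        # union over 9 correlated two-sided tests at 2 SD
        assert 2 * stats.norm.sf(2) <= frac <= 9 * 2 * stats.norm.sf(2)

    def test_missing_model_rejected(self, default_cohort):
        models = self._generative_nine()
        del models[("srm", "2")]
        with pytest.raises(ValueError, match="missing normative models"):
            flag_outliers(default_cohort, models)


class TestCorrelationTable:
    def test_bonferroni_criterion_and_exact_critical_r(self, default_cohort):
        ct = correlation_table(default_cohort)
        assert ct.criterion == 0.0033
        n = ct.n
        tcrit = stats.t.ppf(1 - 0.0033 / 2, n - 2)
        assert ct.critical_r == pytest.approx(
            np.sqrt(tcrit**2 / (tcrit**2 + n - 2)), abs=1e-12
        )

    def test_critical_r_is_computed_not_hardcoded(self):
        cohort = simulate_cohort(GenerativeConfig(n=82, seed=3))
        ct = correlation_table(cohort)
        assert 0.31 < ct.critical_r < 0.33

    def test_perfectly_determined_outcome_has_unit_correlation(self):
        cohort = make_recovery_cohort(GENERATIVE_SRM, 100, seed=4, noise_sd=0.0)
        ct = correlation_table(cohort)
        assert ct.r.at["pta_st", "srm"] == pytest.approx(-1.0, abs=1e-9)

    def test_structural_correlations_recovered_at_large_n(self):
        cohort = simulate_cohort(GenerativeConfig(n=3000, seed=19))
        ct = correlation_table(cohort)
        assert ct.r.at["pta_st", "age"] == pytest.approx(0.51, abs=0.04)
        assert ct.r.at["age", "separated"] > 0.3
        assert ct.r.at["pta_st", "srm"] < -0.3
        assert ct.significant.at["age", "separated"]

    def test_delay_correlations_reported_but_separate(self, default_cohort):
        ct = correlation_table(default_cohort)
        assert ct.delay_correlations is not None
        assert set(ct.delay_correlations["measure"]) == {"colocated", "separated", "srm"}

    def test_constant_column_reported_as_undefined(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CohortValidationWarning)
            cohort = simulate_cohort(GenerativeConfig(n=30, seed=2, age_sd=0.0))
        ct = correlation_table(cohort)
        assert np.isnan(ct.r.at["age", "separated"])


class TestNormativeBand:
    def test_center_obeys_regression_equation(self):
        band = normative_band(GENERATIVE_SEPARATED, [0.0, 20.0, 40.0], "pta",
                              fixed_age=50.0)
        np.testing.assert_allclose(band["center"], [-5.967, -2.687, 0.593], atol=1e-9)

    def test_zero_k_collapses_band(self):
        band = normative_band(GENERATIVE_SRM, np.arange(0, 46), "pta", k=0.0)
        np.testing.assert_allclose(band["lower"], band["center"])
        np.testing.assert_allclose(band["upper"], band["center"])

    def test_band_width_constant_and_signs_monotone(self):
        srm = normative_band(GENERATIVE_SRM, np.arange(0, 46), "pta", k=1.0)
        width = srm["upper"] - srm["lower"]
        np.testing.assert_allclose(width, 2 * GENERATIVE_SRM.model_error)
        assert np.all(np.diff(srm["center"]) < 0)  # SRM shrinks with hearing loss
        colo = normative_band(GENERATIVE_COLOCATED, np.arange(18, 81), "age",
                              fixed_pta=10.0)
        assert np.all(np.diff(colo["center"]) > 0)  # thresholds worsen with age
        sep_age = normative_band(GENERATIVE_SEPARATED, np.arange(18, 81), "age",
                                 fixed_pta=10.0)
        assert np.all(np.diff(sep_age["center"]) > 0)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="band variable"):
            normative_band(GENERATIVE_SRM, [0, 1], "srt")


def test_fit_all_models_covers_nine_measures(default_cohort):
    models = fit_all_models(default_cohort)
    assert set(models) == set(ALL_MODEL_KEYS)
    for model in models.values():
        assert model.model_error > 0
        assert model.n == len(default_cohort)
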
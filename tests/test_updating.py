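"""The incremental updating ladder: cloglog refits, parameter recovery,
nesting/invariance properties and coefficient-set round-trips."""

import math

import numpy as np
import pytest

from oxval import (
    CohortSpec,
    OutcomeSpec,
    apply_recalibration,
    auc,
    fit_cloglog_recalibration,
    fit_multiplicative_value,
    linear_predictors,
    predict_risk,
    reestimate_predictor,
    run_ladder,
    sample_cohort,
    simple_validation,
    simulate_outcomes,
    update_baseline_risk,
)
from oxval.updating import bernoulli_loglik, stage_comparison_markdown
from oxval import presets


def draw_outcomes(lp, a, b, seed):
    """Bernoulli outcomes from cloglog(p) = a + b * lp."""
    rng = np.random.default_rng(seed)
    p = -np.expm1(-np.exp(a + b * lp))
    return (rng.random(len(lp)) < p).astype(float)


class TestCloglogFit:
    def test_intercept_and_slope_recovery(self, tajik_lp_50k):
        s_true = 0.7992
        a_true = math.log(-math.log(s_true))
        y = draw_outcomes(tajik_lp_50k, a_true, 1.0, seed=11)
        a, b = fit_cloglog_recalibration(tajik_lp_50k, y, free="intercept_slope")
        assert a == pytest.approx(a_true, abs=0.05)
        assert b == pytest.approx(1.0, abs=0.05)

    def test_shape_distortion_recovery(self, tajik_lp_50k):
        a_true = math.log(-math.log(0.7992))
        y = draw_outcomes(tajik_lp_50k, a_true, 0.8093, seed=12)
        _, b = fit_cloglog_recalibration(tajik_lp_50k, y, free="intercept_slope")
        assert b == pytest.approx(0.8093, abs=0.05)

    def test_constant_lp_unidentifiable(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cloglog_recalibration(
                np.zeros(100), np.r_[np.ones(30), np.zeros(70)],
                free="intercept_slope",
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_cloglog_recalibration(np.arange(10.0), np.ones(10))


class TestSimpleValidation:
    def test_null_citl_on_self_generated_data(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        params, report = simple_validation(cohort, sweden_coefs)
        assert params.stage == "simple"
        assert params.baseline_survival == sweden_coefs.baseline_survival
        assert params.shape == 1.0
        assert abs(report.calibration.citl) < 0.05

    def test_inflated_hazard_gives_positive_citl(self, tajik_cohort_50k, sweden_coefs):
        # truth has a higher baseline log-hazard than the model assumes,
        # so the model underestimates risk: CITL > 0, E:O < 1
        spec = OutcomeSpec(true_model=sweden_coefs, baseline_shift=math.log(2), seed=13)
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        _, report = simple_validation(cohort, sweden_coefs)
        assert report.calibration.citl > 0.3
        assert report.calibration.eo_ratio < 1.0

    def test_empty_cohort_rejected(self, sweden_coefs):
        cohort = sample_cohort(CohortSpec(n=5, seed=1))  # outcomes unobserved
        with pytest.raises(ValueError, match="complete"):
            simple_validation(cohort, sweden_coefs)


class TestBaselineUpdate:
    def test_recovers_original_when_calibrated(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        params = update_baseline_risk(cohort, sweden_coefs)
        assert params.stage == "baseline"
        a = math.log(-math.log(params.baseline_survival))
        a_true = math.log(-math.log(sweden_coefs.baseline_survival))
        assert a == pytest.approx(a_true, abs=0.05)

    def test_recovers_shifted_baseline(self, tajik_cohort_50k, sweden_coefs):
        shift = math.log(2)  # doubled baseline log-hazard
        spec = OutcomeSpec(true_model=sweden_coefs, baseline_shift=shift, seed=14)
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        params = update_baseline_risk(cohort, sweden_coefs)
        a = math.log(-math.log(params.baseline_survival))
        a_true = math.log(-math.log(sweden_coefs.baseline_survival)) + shift
        assert a == pytest.approx(a_true, abs=0.05)

    def test_mean_risk_matches_incidence_after_update(
        self, tajik_cohort_50k, sweden_coefs
    ):
        spec = OutcomeSpec(true_model=sweden_coefs, baseline_shift=0.5, seed=15)
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        params = update_baseline_risk(cohort, sweden_coefs)
        updated = apply_recalibration(sweden_coefs, params)
        risks = predict_risk(linear_predictors(cohort, updated), updated)
        y = cohort.outcomes
        assert risks.mean() == pytest.approx(y.mean(), abs=1e-3)
        # the cloglog score equation balances a weighted residual, so E:O
        # is only approximately 1 after the intercept refit
        assert risks.sum() / y.sum() == pytest.approx(1.0, abs=5e-3)


class TestMultiplicativeValue:
    def test_null_shape_recovery(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        params = fit_multiplicative_value(cohort, sweden_coefs)
        assert params.stage == "slope"
        assert params.shape == pytest.approx(1.0, abs=0.05)

    def test_distorted_shape_recovery(self, tajik_cohort_50k, sweden_coefs):
        spec = OutcomeSpec(true_model=sweden_coefs, slope_factor=0.8093, seed=16)
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        params = fit_multiplicative_value(cohort, sweden_coefs)
        assert params.shape == pytest.approx(0.8093, abs=0.05)

    def test_auc_invariant(self, calibrated_cohort, sweden_coefs):
        # baseline+slope recalibration is a strictly monotone transform of
        # the unchanged linear predictor, so stage-report AUCs agree exactly
        cohort, _ = calibrated_cohort
        result = run_ladder(cohort, sweden_coefs, stages=("simple", "baseline", "slope"))
        aucs = [report.auc for _, report in result.stages]
        assert max(aucs) - min(aucs) < 1e-12

    def test_calibration_restored_in_sample(self, tajik_cohort_50k, sweden_coefs):
        from oxval import build_report

        spec = OutcomeSpec(
            true_model=sweden_coefs, baseline_shift=0.4, slope_factor=0.85, seed=17
        )
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        params = fit_multiplicative_value(cohort, sweden_coefs)
        updated = apply_recalibration(sweden_coefs, params)
        risks = predict_risk(linear_predictors(cohort, updated), updated)
        rep = build_report(risks, cohort.outcomes)
        assert abs(rep.calibration.citl) < 0.02
        assert rep.calibration.slope == pytest.approx(1.0, abs=0.02)


class TestSelectiveReestimation:
    def test_recovers_shifted_dummies(self, tajik_cohort_50k, sweden_coefs):
        truth_dummies = dict(presets.TAJIK_PRISON_DUMMIES)
        spec = OutcomeSpec(
            true_model=sweden_coefs,
            coefficient_overrides={"length_of_incarceration": truth_dummies},
            seed=18,
        )
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        params = reestimate_predictor(cohort, sweden_coefs, "length_of_incarceration")
        assert params.stage == "selective"
        est = params.reestimated["length_of_incarceration"]
        # the rare reference band (<6 months, ~0.3% of the case-mix) makes
        # the dummy SEs large; a single 50k draw resolves the big shift in
        # the middle band and keeps the others within a loose band
        assert est["12to24m"] * params.shape == pytest.approx(0.5949, abs=0.45)
        for level, true_val in truth_dummies.items():
            assert est[level] * params.shape == pytest.approx(true_val, abs=0.75)

    def test_auc_changes_on_shifted_data(self, tajik_cohort_50k, sweden_coefs):
        spec = OutcomeSpec(
            true_model=sweden_coefs,
            coefficient_overrides={
                "length_of_incarceration": dict(presets.TAJIK_PRISON_DUMMIES)
            },
            seed=19,
        )
        cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
        params = reestimate_predictor(cohort, sweden_coefs, "length_of_incarceration")
        updated = apply_recalibration(sweden_coefs, params)
        y = cohort.outcomes
        before = auc(predict_risk(linear_predictors(cohort, sweden_coefs), sweden_coefs), y)
        after = auc(predict_risk(linear_predictors(cohort, updated), updated), y)
        assert abs(after - before) > 1e-6  # not a monotone transform

    def test_empty_level_rejected(self, sweden_coefs):
        margs = presets.tajik_marginals()
        margs["length_of_incarceration"] = {
            "lt6m": 0.0, "6to12m": 0.1, "12to24m": 0.2, "ge24m": 0.7,
        }
        cohort = sample_cohort(CohortSpec(n=500, marginals=margs, seed=2))
        cohort, _ = simulate_outcomes(
            cohort, OutcomeSpec(true_model=sweden_coefs, seed=3)
        )
        with pytest.raises(ValueError, match="lt6m"):
            reestimate_predictor(cohort, sweden_coefs, "length_of_incarceration")

    def test_non_categorical_rejected(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        with pytest.raises(ValueError, match="categorical"):
            reestimate_predictor(cohort, sweden_coefs, "alcohol_misuse")


@pytest.fixture(scope="module")
def distorted_cohort(tajik_cohort_50k, sweden_coefs):
    spec = OutcomeSpec(
        true_model=sweden_coefs,
        baseline_shift=0.5,
        slope_factor=0.8093,
        coefficient_overrides={
            "length_of_incarceration": dict(presets.TAJIK_PRISON_DUMMIES)
        },
        seed=21,
    )
    cohort, _ = simulate_outcomes(tajik_cohort_50k, spec)
    return cohort


class TestLadder:
    def test_simple_only_matches_simple_validation(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        result = run_ladder(cohort, sweden_coefs, stages=("simple",))
        params, report = simple_validation(cohort, sweden_coefs)
        assert result.stage_names == ["simple"]
        assert result.stages[0][0] == params
        assert result.stages[0][1].to_dict() == report.to_dict()

    def test_full_ladder_noop_on_calibrated_data(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        result = run_ladder(cohort, sweden_coefs)
        final = result.final_coefficients
        a_final = math.log(-math.log(final.baseline_survival))
        a_true = math.log(-math.log(sweden_coefs.baseline_survival))
        assert a_final == pytest.approx(a_true, abs=0.2)
        assert final.recalibration_shape == pytest.approx(1.0, abs=0.1)

    def test_final_coefficients_round_trip(self, distorted_cohort, sweden_coefs, tmp_path):
        from oxval import load_coefficient_set, save_coefficient_set

        result = run_ladder(distorted_cohort, sweden_coefs)
        final = result.final_coefficients
        path = tmp_path / "final.json"
        save_coefficient_set(final, path)
        reloaded = load_coefficient_set(path)
        r1 = predict_risk(linear_predictors(distorted_cohort, final), final)
        r2 = predict_risk(linear_predictors(distorted_cohort, reloaded), reloaded)
        np.testing.assert_allclose(r1, r2, rtol=0, atol=1e-12)

    def test_loglikelihood_nondecreasing(self, distorted_cohort, sweden_coefs):
        result = run_ladder(distorted_cohort, sweden_coefs)
        y = distorted_cohort.outcomes
        lls = []
        current = sweden_coefs
        from oxval import apply_recalibration as apply

        for params, _ in result.stages:
            if params.stage != "simple":
                current = apply(current, params)
            risks = predict_risk(linear_predictors(distorted_cohort, current), current)
            lls.append(bernoulli_loglik(risks, y))
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_rank_order_preserved_until_selective(self, distorted_cohort, sweden_coefs):
        result = run_ladder(distorted_cohort, sweden_coefs, stages=("simple", "baseline", "slope"))
        current = sweden_coefs
        lp = linear_predictors(distorted_cohort, current)
        order = np.argsort(lp, kind="stable")
        from oxval import apply_recalibration as apply

        for params, _ in result.stages[1:]:
            current = apply(current, params)
            # the linear predictor is untouched by these stages and every
            # stage's risks are a monotone transform of it
            np.testing.assert_allclose(
                linear_predictors(distorted_cohort, current), lp, atol=0
            )
            after = predict_risk(lp, current)
            assert np.all(np.diff(after[order]) >= 0)

    def test_out_of_order_stages_rejected(self, calibrated_cohort, sweden_coefs):
        cohort, _ = calibrated_cohort
        with pytest.raises(ValueError, match="order"):
            run_ladder(cohort, sweden_coefs, stages=("slope", "baseline"))

    def test_stage_comparison_markdown(self, distorted_cohort, sweden_coefs):
        result = run_ladder(distorted_cohort, sweden_coefs)
        md = stage_comparison_markdown(result)
        lines = md.splitlines()
        assert len(lines) == 2 + len(result.stages)
        assert lines[2].startswith("| simple |")
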
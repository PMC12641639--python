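"""Two-stage biomarker fitting, classification and cohort metrics."""

import numpy as np
import pytest

from nactwin.calibration import (
    CaseGeometry,
    CalibrationError,
    OnsetUnreachableError,
    PDUnreachableError,
    PatientCase,
    calibrate_case,
    classify_case,
    cohort_metrics,
    fit_growth,
    fit_onset,
    fit_pd,
    ki67_band,
)
from nactwin.cohort import clinical_cohort, sample_virtual_patient, synthesize_observations, virtual_geometry
from nactwin.kinetics import SECONDS_PER_DAY, ModelParams, build_regimen
from nactwin.solver import SolverOptions, grow_phase1

TWO_DRUG = [
    {"name": "EC", "first_dose_day": 0, "interval_days": 21, "count": 4},
    {"name": "paclitaxel", "first_dose_day": 84, "interval_days": 7, "count": 12},
]


@pytest.fixture(scope="module")
def p3_setup(coarse_geometry_factory):
    """Patient-3-like replay setup on a coarse grid."""
    case, params = [cp for cp in clinical_cohort() if cp[0].id == "patient3"][0]
    return case, params, coarse_geometry_factory(case.v0_cm3)


class TestClassifyCase:
    @pytest.mark.parametrize(
        "v_obs,v_pred,dev,within",
        [
            (4.2, 4.07, 0.031, True),  # baseline agreement, patient-1 scale
            (16.0, 12.98, 0.189, True),  # largest tolerated deviation seen
            (5.0, 5.0, 0.0, True),
            (1.0, 1.21, 0.21, False),
        ],
    )
    def test_relative_deviation_and_margin(self, v_obs, v_pred, dev, within):
        rel, flag = classify_case(v_pred, v_obs)
        assert rel == pytest.approx(dev, abs=0.002)
        assert flag is within

    def test_zero_observed_volume_rejected(self):
        with pytest.raises(CalibrationError):
            classify_case(1.0, 0.0)


class TestCohortMetrics:
    def test_all_true_positive(self):
        m = cohort_metrics(["TP", "TP", "TP"])
        assert m["precision_percent"] == 100.0
        assert m["sensitivity_percent"] == 100.0
        assert m["specificity_percent"] is None

    def test_each_miss_counts_one_fp_and_one_fn(self):
        m = cohort_metrics(["TP", "miss"])
        assert m["precision_percent"] == 50.0
        assert m["sensitivity_percent"] == 50.0

    def test_all_miss(self):
        m = cohort_metrics(["miss"])
        assert m["precision_percent"] == 0.0 and m["sensitivity_percent"] == 0.0

    def test_empty_or_invalid_rejected(self):
        with pytest.raises(CalibrationError):
            cohort_metrics([])
        with pytest.raises(CalibrationError):
            cohort_metrics(["TP", "FP"])


class TestFitOnset:
    def test_baseline_equal_to_seed_gives_onset_near_zero(self, p3_setup):
        case, params, geometry = p3_setup
        tiny = PatientCase(
            id="tiny", v0_cm3=geometry.v_i_star_cm3, dvs_cm3=0.1, regimen=case.regimen
        )
        fit = fit_onset(tiny, params, geometry, bracket_days=(-30.0, 0.0))
        assert -1.0 < fit.t_i_days <= 0.0

    def test_unreachable_baseline_fails_with_achieved_range(self, p3_setup):
        case, params, geometry = p3_setup
        impossible = PatientCase(
            id="big",
            v0_cm3=geometry.domain.roi_volume_cm3 * 2,
            dvs_cm3=0.1,
            regimen=case.regimen,
        )
        with pytest.raises(OnsetUnreachableError, match="achieved range"):
            fit_onset(impossible, params, geometry)

    def test_self_consistent_onset_recovery_within_one_day(self, p3_setup):
        case, params, geometry = p3_setup
        opts = SolverOptions()
        t_i_true = -6.0
        state, _ = grow_phase1(
            geometry.domain,
            params,
            geometry.seed_field,
            -t_i_true * SECONDS_PER_DAY,
            opts,
            geometry.operator,
        )
        synthetic = PatientCase(
            id="syn", v0_cm3=state.v_star_cm3(), dvs_cm3=0.1, regimen=case.regimen
        )
        fit = fit_onset(synthetic, params, geometry, options=opts)
        assert fit.t_i_days == pytest.approx(t_i_true, abs=1.0)
        assert fit.rel_dev < 0.01


class TestFitGrowth:
    def test_collapsed_bounds_reduce_to_fit_onset(self, p3_setup):
        case, params, geometry = p3_setup
        r_c, fit = fit_growth(case, params, geometry, (params.r_c, params.r_c))
        direct = fit_onset(case, params, geometry)
        assert r_c == params.r_c
        assert fit.t_i_days == pytest.approx(direct.t_i_days, rel=1e-12)

    def test_band_mode_reproduces_baseline_within_band(self, p3_setup):
        case, params, geometry = p3_setup
        band = ki67_band(case.ki67_percent)
        r_c, fit = fit_growth(case, params, geometry, band, n_grid=6)
        assert band[0] <= r_c <= band[1]
        assert fit.rel_dev < 0.05

    def test_bounds_far_outside_plausibility_rejected(self, p3_setup):
        case, params, geometry = p3_setup
        with pytest.raises(CalibrationError):
            fit_growth(case, params, geometry, (1e-9, 1e-8))


class TestKi67Band:
    def test_bands_partition_the_printed_range(self):
        lo_band = ki67_band(10.0)
        mid_band = ki67_band(22.0)
        hi_band = ki67_band(35.0)
        assert lo_band[0] == pytest.approx(4.0e-7)
        assert hi_band[1] == pytest.approx(6.0e-6)
        assert lo_band[1] == pytest.approx(mid_band[0])
        assert mid_band[1] == pytest.approx(hi_band[0])


@pytest.fixture(scope="module")
def baseline_state(p3_setup):
    case, params, geometry = p3_setup
    opts = SolverOptions()
    fit = fit_onset(case, params, geometry, options=opts)
    state, _ = grow_phase1(
        geometry.domain,
        params,
        geometry.seed_field,
        -fit.t_i_days * SECONDS_PER_DAY,
        opts,
        geometry.operator,
    )
    return state


class TestFitPd:
    def test_residual_volume_monotone_in_eps_pd(self, p3_setup, baseline_state):
        from nactwin.solver import treat_phase2

        case, params, _ = p3_setup
        dvs = []
        for eps in (1e-7, 1e-5, 1e-4):
            p = params.with_aggregated_eps_pd(eps)
            state, _ = treat_phase2(baseline_state, p, case.regimen)
            dvs.append(state.v_star_cm3())
        assert dvs[0] > dvs[1] > dvs[2]

    def test_matches_measured_residual_volume(self, p3_setup, baseline_state):
        case, params, _ = p3_setup
        eps, dvs_star = fit_pd(case, baseline_state, params)
        assert dvs_star == pytest.approx(case.dvs_cm3, rel=0.05)
        assert 1e-7 <= eps <= 4e-4  # printed biomarker range

    def test_target_above_no_kill_prediction_fails(self, p3_setup, baseline_state):
        case, params, _ = p3_setup
        impossible = PatientCase(
            id="grow",
            v0_cm3=case.v0_cm3,
            dvs_cm3=baseline_state.domain.roi_volume_cm3 * 3,
            regimen=case.regimen,
        )
        with pytest.raises(PDUnreachableError):
            fit_pd(impossible, baseline_state, params)

    def test_target_below_reach_of_weak_bracket_fails(self, p3_setup, baseline_state):
        case, params, _ = p3_setup
        deep_response = PatientCase(
            id="deep", v0_cm3=case.v0_cm3, dvs_cm3=0.001, regimen=case.regimen
        )
        with pytest.raises(PDUnreachableError):
            fit_pd(deep_response, baseline_state, params, eps_pd_bounds=(1e-9, 1e-8))


class TestCalibrateCase:
    def test_replay_calibration_is_deterministic(self, p3_setup):
        case, params, geometry = p3_setup
        a = calibrate_case(case, params, geometry=geometry)
        b = calibrate_case(case, params, geometry=geometry)
        assert a.to_dict() == b.to_dict()  # bit-identical rerun

    def test_ki67_mode_requires_ki67(self, p3_setup):
        case, params, geometry = p3_setup
        anon = PatientCase(id="anon", v0_cm3=1.4, dvs_cm3=1.4, regimen=case.regimen)
        with pytest.raises(CalibrationError):
            calibrate_case(anon, params, mode="ki67", geometry=geometry)

    def test_unknown_mode_rejected(self, p3_setup):
        case, params, geometry = p3_setup
        with pytest.raises(CalibrationError):
            calibrate_case(case, params, mode="bayes", geometry=geometry)


def test_end_to_end_eps_pd_recovery_on_virtual_patient():
    """Noise-free synthesized observations return the generating efficiency."""
    from nactwin.recovery import recover_eps_pd

    opts = SolverOptions(dt_growth_days=0.5)
    vp = sample_virtual_patient(1234)
    synth = synthesize_observations(vp, 0.0, geometry=virtual_geometry(), options=opts)
    eps = recover_eps_pd(synth, options=opts)
    assert eps == pytest.approx(vp.eps_pd, rel=0.02)
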
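"""Time integration: conservation, limits, equivalences, robustness."""

import numpy as np
import pytest

from nactwin.domain import ScalarField, build_sphere_domain, place_seed
from nactwin.kinetics import (
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
    DrugParams,
    ModelParams,
    build_regimen,
    gompertz_closed_form,
)
from nactwin.solver import (
    DiffusionOperator,
    SeedSpec,
    SimulationState,
    SolverError,
    SolverOptions,
    run_phases,
    simulate,
    step,
    well_mixed_drug_trajectory,
)

EC_ONLY = [{"name": "EC", "first_dose_day": 0, "interval_days": 21, "count": 4}]
TWO_DRUG = [
    {"name": "EC", "first_dose_day": 0, "interval_days": 21, "count": 4},
    {"name": "paclitaxel", "first_dose_day": 84, "interval_days": 7, "count": 12},
]


def _drugs(eps_pd=0.0):
    return (
        DrugParams(name="EC", eps_pd=eps_pd, eps_pk_per_hour=2.0),
        DrugParams(name="paclitaxel", eps_pd=eps_pd, eps_pk_per_hour=50.0),
    )


class TestStep:
    def test_pure_diffusion_conserves_mass(self, small_domain, small_operator, rng):
        params = ModelParams(r_c=1e-30, d_c=1e-10)  # negligible reaction
        field = small_domain.zeros()
        field[small_domain.mask] = rng.uniform(0, 1, small_domain.n_voxels)
        state = SimulationState.from_seed(
            small_domain, params, field, operator=small_operator
        )
        m0 = state.v_star_cm3()
        for _ in range(100):
            step(state, 6 * SECONDS_PER_HOUR)
        assert abs(state.v_star_cm3() - m0) / m0 < 1e-10

    def test_saturated_field_is_fixed_point(self, small_domain, small_operator):
        params = ModelParams(r_c=1e-6, d_c=1e-13)
        field = small_domain.mask.astype(float)  # phi = K everywhere in ROI
        state = SimulationState.from_seed(
            small_domain, params, field, operator=small_operator
        )
        before = state.phi_c.copy()
        step(state, SECONDS_PER_DAY)
        np.testing.assert_allclose(state.phi_c, before, atol=1e-12)

    def test_point_source_second_moment_grows_linearly(self):
        # implicit diffusion of a point seed: per-axis second moment grows
        # by exactly 2*D*dt per step while support stays off the boundary
        dom = build_sphere_domain(radius_mm=12.0, spacing_mm=1.0)
        op = DiffusionOperator(dom)
        d_c = 5.0e-12  # m^2/s
        params = ModelParams(r_c=1e-30, d_c=d_c)
        field = dom.zeros()
        field[dom.center_index] = 1.0
        state = SimulationState.from_seed(dom, params, field, operator=op)
        coords = np.argwhere(dom.mask).astype(float) * dom.spacing_mm
        ctr = np.array(dom.center_index, dtype=float) * dom.spacing_mm
        dt = SECONDS_PER_DAY / 4
        n_steps = 8
        for _ in range(n_steps):
            step(state, dt)
        weights = state.phi_c / state.phi_c.sum()
        var = float(((coords[:, 0] - ctr[0]) ** 2 * weights).sum())  # mm^2
        expected = 2.0 * d_c * 1e6 * dt * n_steps
        assert var == pytest.approx(expected, rel=1e-6)

    def test_invalid_dt_rejected(self, small_domain, small_operator, seeded_small):
        state = SimulationState.from_seed(
            small_domain, ModelParams(r_c=1e-6), seeded_small[0], operator=small_operator
        )
        with pytest.raises(SolverError):
            step(state, -1.0)


class TestSimulate:
    def test_gompertz_closed_form_without_diffusion(self, small_domain, small_operator):
        phi0 = 0.01
        params = ModelParams(r_c=2.0e-6, d_c=0.0)
        seed, v_i = place_seed(small_domain, small_domain.center_index, 0.5, phi0)
        region = v_i / phi0
        state = SimulationState.from_seed(
            small_domain, params, seed, t_s=0.0, operator=small_operator
        )
        traj = simulate(state, 30 * SECONDS_PER_DAY, sample_interval_s=5 * SECONDS_PER_DAY)
        expected = region * gompertz_closed_form(
            traj.times_days * SECONDS_PER_DAY, phi0, params.r_c
        )
        np.testing.assert_allclose(traj.v_star_cm3, expected, rtol=1e-3)

    def test_no_reaction_no_drug_volume_constant(self, small_domain, small_operator, seeded_small):
        params = ModelParams(r_c=1e-30, d_c=1e-13)
        state = SimulationState.from_seed(
            small_domain, params, seeded_small[0], operator=small_operator
        )
        v0 = state.v_star_cm3()
        traj = simulate(state, 20 * SECONDS_PER_DAY)
        np.testing.assert_allclose(traj.v_star_cm3, v0, rtol=1e-9)

    def test_t_end_must_advance(self, small_domain, small_operator, seeded_small):
        state = SimulationState.from_seed(
            small_domain, ModelParams(r_c=1e-6), seeded_small[0], operator=small_operator
        )
        with pytest.raises(SolverError):
            simulate(state, -1.0)


class TestRunPhases:
    def _phases(self, small_domain, small_operator, seeded_small, eps_pd, **opts):
        params = ModelParams(r_c=3e-6, drugs=_drugs(eps_pd))
        regimen = build_regimen(TWO_DRUG)
        return run_phases(
            small_domain,
            params,
            regimen,
            -20 * SECONDS_PER_DAY,
            seeded_small[0],
            SolverOptions(**opts),
            small_operator,
        )

    def test_onset_must_be_negative(self, small_domain, small_operator, seeded_small):
        params = ModelParams(r_c=3e-6, drugs=_drugs())
        with pytest.raises(SolverError):
            run_phases(
                small_domain,
                params,
                build_regimen(TWO_DRUG),
                5.0,
                seeded_small[0],
                operator=small_operator,
            )

    def test_zero_efficiency_continues_free_growth(
        self, small_domain, small_operator, seeded_small
    ):
        res = self._phases(small_domain, small_operator, seeded_small, eps_pd=0.0)
        # therapy with eps_PD = 0 cannot shrink the lesion
        assert res.dvs_star_cm3 >= res.v0_star_cm3 * (1 - 1e-12)
        v = res.trajectory.v_star_cm3
        assert (np.diff(v) >= -1e-12 * v[:-1]).all()

    def test_therapy_decreases_residual_volume(
        self, small_domain, small_operator, seeded_small
    ):
        free = self._phases(small_domain, small_operator, seeded_small, eps_pd=0.0)
        treated = self._phases(small_domain, small_operator, seeded_small, eps_pd=5e-5)
        assert treated.dvs_star_cm3 < free.dvs_star_cm3
        assert treated.v0_star_cm3 == pytest.approx(free.v0_star_cm3, rel=1e-12)

    def test_monotone_in_eps_pd(self, small_domain, small_operator, seeded_small):
        dvs = [
            self._phases(small_domain, small_operator, seeded_small, eps_pd=e).dvs_star_cm3
            for e in (0.0, 1e-6, 1e-5, 1e-4)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(dvs, dvs[1:]))

    def test_monotone_in_r_c(self, small_domain, small_operator, seeded_small):
        regimen = build_regimen(TWO_DRUG)
        v0s = []
        for r_c in (1e-6, 2e-6, 4e-6):
            res = run_phases(
                small_domain,
                ModelParams(r_c=r_c, drugs=_drugs()),
                regimen,
                -20 * SECONDS_PER_DAY,
                seeded_small[0],
                operator=small_operator,
            )
            v0s.append(res.v0_star_cm3)
        assert v0s[0] < v0s[1] < v0s[2]

    def test_step_halving_changes_volumes_below_half_percent(
        self, small_domain, small_operator, seeded_small
    ):
        # checked in the asymptotic regime (1/8 day): the lattice invasion
        # front converges linearly in dt once the leading edge is in the
        # floored-rate (linear-growth) regime
        a = self._phases(
            small_domain, small_operator, seeded_small, 1e-5, dt_growth_days=0.125
        )
        b = self._phases(
            small_domain, small_operator, seeded_small, 1e-5, dt_growth_days=0.0625
        )
        assert abs(a.v0_star_cm3 - b.v0_star_cm3) / b.v0_star_cm3 < 0.005
        assert abs(a.dvs_star_cm3 - b.dvs_star_cm3) / max(b.dvs_star_cm3, 1e-9) < 0.005

    def test_sampling_interval_does_not_alter_dynamics(
        self, small_domain, small_operator, seeded_small
    ):
        params = ModelParams(r_c=3e-6, drugs=_drugs(1e-5))
        regimen = build_regimen(TWO_DRUG)
        res = [
            run_phases(
                small_domain,
                params,
                regimen,
                -20 * SECONDS_PER_DAY,
                seeded_small[0],
                SolverOptions(),
                small_operator,
                sample_interval_s=si,
            )
            for si in (SECONDS_PER_DAY, 2 * SECONDS_PER_DAY)
        ]
        assert res[0].v0_star_cm3 == pytest.approx(res[1].v0_star_cm3, rel=1e-3)
        assert res[0].dvs_star_cm3 == pytest.approx(res[1].dvs_star_cm3, rel=1e-3)


class TestWellMixedDrug:
    def test_exponential_decay_between_pulses(self):
        regimen = build_regimen(EC_ONLY)
        drug = DrugParams(name="EC", eps_pd=0.0, eps_pk_per_hour=2.0)
        t = np.array([2.0, 4.0, 8.0]) * SECONDS_PER_HOUR  # after the 1 h infusion
        conc = well_mixed_drug_trajectory(regimen, [drug], t)[0]
        # exact exponential decay at rate eps_PK between administrations
        assert conc[1] / conc[0] == pytest.approx(np.exp(-2.0 * 2.0), rel=1e-12)
        slope = (np.log(conc[2]) - np.log(conc[0])) / ((t[2] - t[0]) / SECONDS_PER_HOUR)
        assert slope == pytest.approx(-2.0, rel=1e-12)

    def test_pde_drug_matches_well_mixed_mean(self, small_domain, small_operator, seeded_small):
        # the published drug diffusivity homogenizes the ROI within a step,
        # so the PDE drug field's spatial mean must track the exact ODE
        params = ModelParams(r_c=1e-6, drugs=_drugs(0.0))
        regimen = build_regimen(EC_ONLY)
        masses = {}
        for model in ("well_mixed", "pde"):
            state = SimulationState.from_seed(
                small_domain,
                params,
                seeded_small[0],
                t_s=0.0,
                regimen=regimen,
                options=SolverOptions(drug_model=model, exposure="pulsed"),
                operator=small_operator,
            )
            traj = simulate(state, 3 * SECONDS_PER_DAY, SECONDS_PER_HOUR)
            masses[model] = traj.drug_mass[:, 0]
        scale = masses["well_mixed"].max()
        np.testing.assert_allclose(
            masses["pde"] / scale, masses["well_mixed"] / scale, atol=0.01
        )

    def test_unsorted_grid_rejected(self):
        regimen = build_regimen(EC_ONLY)
        with pytest.raises(SolverError):
            well_mixed_drug_trajectory(
                regimen, [_drugs()[0]], np.array([2.0, 1.0])
            )


class TestExposureModels:
    def test_block_exposure_reaches_plateau_concentration(self, small_domain, small_operator):
        params = ModelParams(r_c=1e-30, drugs=_drugs(0.0))
        seed, _ = place_seed(small_domain, small_domain.center_index, 0.5, 0.01)
        state = SimulationState.from_seed(
            small_domain,
            params,
            seed,
            t_s=0.0,
            regimen=build_regimen(EC_ONLY),
            options=SolverOptions(exposure="block"),
            operator=small_operator,
        )
        simulate(state, 10 * SECONDS_PER_DAY)
        conc = state.phi_d[0]
        assert conc == pytest.approx(state.options.block_concentration, rel=1e-6)

    def test_drug_cleared_after_therapy_window(self, small_domain, small_operator, seeded_small):
        params = ModelParams(r_c=1e-6, drugs=_drugs(0.0))
        regimen = build_regimen(EC_ONLY)
        state = SimulationState.from_seed(
            small_domain,
            params,
            seeded_small[0],
            t_s=0.0,
            regimen=regimen,
            options=SolverOptions(exposure="block"),
            operator=small_operator,
        )
        simulate(state, regimen.duration_s + 5 * SECONDS_PER_DAY)
        assert state.phi_d[0] < 1e-10


def test_trajectory_frame_schema(small_domain, small_operator, seeded_small):
    params = ModelParams(r_c=2e-6, drugs=_drugs(1e-6))
    state = SimulationState.from_seed(
        small_domain,
        params,
        seeded_small[0],
        t_s=0.0,
        regimen=build_regimen(TWO_DRUG),
        operator=small_operator,
    )
    traj = simulate(state, 5 * SECONDS_PER_DAY)
    df = traj.to_frame()
    assert list(df.columns) == ["time_days", "V_star_cm3", "drug_mass_1", "drug_mass_2"]
    assert (df["V_star_cm3"] >= 0).all()
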
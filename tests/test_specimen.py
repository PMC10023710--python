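"""Virtual specimen: geometry, dynamics, generation, sensor noise."""

import numpy as np
import pandas as pd
import pytest

from shouldersim.controller import MUSCLES
from shouldersim.kinematics import CardanXZY
from shouldersim.specimen import (
    MusclePath,
    PlantState,
    SpecimenRejectionError,
    VirtualSpecimen,
    add_sensor_noise,
    generalized_muscle_torque,
    generate_specimen,
    moment_arm_torque,
    passive_equilibrium,
    reference_specimen,
    step_dynamics,
)


class TestMomentArmTorque:
    def test_line_through_cor_gives_zero_torque(self):
        path = MusclePath("MD", np.array([0.0, -100.0, 0.0]), np.array([0.0, 100.0, 0.0]))
        state = PlantState(angles=CardanXZY(0, 0, 0))
        tau = moment_arm_torque(path, state, 50.0)
        assert np.allclose(tau, 0.0, atol=1e-12)

    def test_hand_computed_cross_product(self):
        """Unit force along +X applied at r = 50 mm on +Z gives +0.05 N m
        about Y."""
        path = MusclePath("MD", np.array([0.0, 0.0, 50.0]), np.array([1000.0, 0.0, 50.0]))
        state = PlantState(angles=CardanXZY(0, 0, 0))
        tau = moment_arm_torque(path, state, 1.0)
        assert np.allclose(tau, [0.0, 0.05, 0.0], atol=1e-6)

    def test_linearity_in_force(self):
        path = MusclePath("AD", np.array([20.0, -105.0, -12.0]), np.array([70.0, 25.0, -20.0]))
        state = PlantState(angles=CardanXZY(25.0, 5.0, -10.0))
        assert np.allclose(
            moment_arm_torque(path, state, 80.0),
            2.0 * moment_arm_torque(path, state, 40.0),
        )

    def test_negative_force_rejected(self):
        path = MusclePath("MD", np.zeros(3) + [0, -1, 0], np.array([0.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="cannot push"):
            moment_arm_torque(path, PlantState(), -1.0)


class TestMomentArmSigns:
    """Anatomical moment-arm signs at 30 deg abduction, neutral F/E and
    rotation (reference specimen fixture)."""

    @pytest.mark.parametrize(
        "muscle,dof,sign",
        [("MD", 0, 1), ("SSP", 0, 1), ("AD", 1, 1), ("PD", 1, -1), ("SSC", 2, 1), ("ISP/TM", 2, -1)],
    )
    def test_sign(self, ref_specimen, muscle, dof, sign):
        forces = np.zeros(6)
        forces[MUSCLES.index(muscle)] = 1.0
        tau = generalized_muscle_torque(ref_specimen, CardanXZY(30, 0, 0), forces)
        assert tau[dof] * sign > 0


class TestDynamics:
    def test_passive_plant_settles_near_resting_posture(self, ref_specimen):
        """Gravity + pretension + capsule converge to the documented
        resting equilibrium (~10 deg abduction)."""
        eq = passive_equilibrium(ref_specimen, ref_specimen.pretension_N)
        assert 4.0 <= eq[0] <= 16.0
        state = PlantState(
            angles=CardanXZY(eq[0] + 5.0, eq[1], eq[2]),
        )
        forces = np.full(6, ref_specimen.pretension_N)
        for _ in range(4000):  # 20 s
            state = step_dynamics(ref_specimen, state, forces, 0.005)
        assert abs(state.angles.abduction_deg - eq[0]) < 0.2
        assert np.all(np.abs(state.velocity_deg_s) < 0.05)

    def test_pretension_centers_head(self, ref_specimen):
        """With centering pretension and no controller the head stays
        within a millimetre of its reference position."""
        eq = passive_equilibrium(ref_specimen, ref_specimen.pretension_N)
        state = PlantState(angles=CardanXZY(*eq))
        forces = np.full(6, ref_specimen.pretension_N)
        for _ in range(400):
            state = step_dynamics(ref_specimen, state, forces, 0.005)
        assert np.all(np.abs(state.translation_mm) < 1.0)

    def test_energy_dissipates_without_muscles(self, ref_specimen):
        """With zero muscle force and positive damping, mechanical energy
        is non-increasing between steps."""
        from shouldersim import _engine

        spec = ref_specimen
        ins, gui, mass_pos, masses = spec._pack()
        state = PlantState(angles=CardanXZY(40.0, 10.0, -5.0))
        forces = np.zeros(6)

        def energy(s):
            q = s.q_rad()
            qd = np.radians(s.velocity_deg_s)
            R = _engine.rot_xzy(q[0], q[1], q[2])
            E = _engine.rate_map(q[0], q[1])
            Iw = R @ np.diag(spec.inertia_kgm2) @ R.T
            omega = E @ qd
            kin = 0.5 * omega @ Iw @ omega
            g = 9.81 * spec.gravity_dir
            pot = -sum(
                m * g @ (R @ p) for m, p in zip(masses, mass_pos)
            )
            dq = q - np.radians(spec.capsule_rest_deg)
            elastic = 0.5 * np.sum(spec.capsule_stiffness_Nm_rad * dq**2)
            return kin + pot + elastic

        prev = energy(state)
        for _ in range(2000):
            state = step_dynamics(spec, state, forces, 0.005)
            e = energy(state)
            assert e <= prev + 1e-9
            prev = e

    def test_step_size_convergence(self, ref_specimen):
        """Halving dt changes a 20 s passive trajectory endpoint by far
        less than a thousandth of a degree."""

        def endpoint(dt):
            state = PlantState(angles=CardanXZY(25.0, 0.0, 0.0))
            forces = np.full(6, 12.0)
            for _ in range(int(round(20.0 / dt))):
                state = step_dynamics(ref_specimen, state, forces, dt)
            return state.angles.as_array()

        a = endpoint(0.005)
        b = endpoint(0.0025)
        assert np.max(np.abs(a - b)) < 1e-3

    def test_dt_bounds_enforced(self, ref_specimen):
        with pytest.raises(ValueError):
            step_dynamics(ref_specimen, PlantState(), np.full(6, 10.0), 0.05)

    def test_negative_forces_rejected(self, ref_specimen):
        forces = np.full(6, 10.0)
        forces[2] = -1.0
        with pytest.raises(ValueError, match="cannot push"):
            step_dynamics(ref_specimen, PlantState(), forces, 0.005)


class TestGenerateSpecimen:
    def test_seeded_determinism(self):
        a = generate_specimen(3, 0.10)
        b = generate_specimen(3, 0.10)
        assert a.to_dict() == b.to_dict()

    def test_zero_variability_returns_reference(self, ref_specimen):
        spec = generate_specimen(0, 0.0)
        assert np.allclose(spec.inertia_kgm2, ref_specimen.inertia_kgm2)
        for m0, m1 in zip(ref_specimen.muscles, spec.muscles):
            assert np.allclose(m0.insertion_mm, m1.insertion_mm)

    def test_different_seeds_differ_everywhere(self):
        a, b = generate_specimen(1, 0.10), generate_specimen(2, 0.10)
        assert not np.allclose(a.inertia_kgm2, b.inertia_kgm2)
        assert a.humerus_mass_kg != b.humerus_mass_kg
        assert not np.allclose(
            a.capsule_stiffness_Nm_rad, b.capsule_stiffness_Nm_rad
        )
        for ma, mb in zip(a.muscles, b.muscles):
            assert not np.allclose(ma.insertion_mm, mb.insertion_mm)

    def test_variability_bounds(self):
        with pytest.raises(ValueError):
            generate_specimen(0, 0.5)

    @pytest.mark.parametrize("seed", range(12))
    def test_generated_specimens_pass_sign_checks(self, seed):
        """Sampled specimens keep anatomical moment-arm signs (the
        generator rejects violators)."""
        spec = generate_specimen(seed, 0.10)
        forces = np.zeros(6)
        forces[MUSCLES.index("MD")] = 1.0
        tau = generalized_muscle_torque(spec, CardanXZY(20, 0, 0), forces)
        assert tau[0] > 0


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path, ref_specimen):
        path = tmp_path / "spec.yaml"
        ref_specimen.to_yaml(path)
        back = VirtualSpecimen.from_yaml(path)
        assert back.to_dict() == ref_specimen.to_dict()
        assert np.allclose(back.preload_N, ref_specimen.preload_N)

    def test_unsupported_schema_rejected(self, ref_specimen):
        d = ref_specimen.to_dict()
        d["schema_version"] = 99
        with pytest.raises(ValueError, match="schema"):
            VirtualSpecimen.from_dict(d)


class TestSensorNoise:
    def _trace(self, n=10000):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "time_s": np.arange(n) * 0.05,
                "pv_abd": np.full(n, 30.0),
                "ap_mm": np.zeros(n),
                "f_md": np.full(n, 100.0),
            }
        )

    def test_zero_sds_identity(self, ref_specimen):
        from dataclasses import replace

        spec = replace(
            ref_specimen, noise_angle_deg=0.0, noise_force_N=0.0,
            noise_translation_mm=0.0,
        )
        trace = self._trace(100)
        out = add_sensor_noise(trace, spec, seed=1)
        pd.testing.assert_frame_equal(out, trace)

    def test_seeded_reproducibility(self, ref_specimen):
        trace = self._trace(100)
        a = add_sensor_noise(trace, ref_specimen, seed=7)
        b = add_sensor_noise(trace, ref_specimen, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_sd_matches_configuration(self, ref_specimen):
        """Sample SD of (noisy - clean) angle matches the configured
        0.1 deg within estimator tolerance."""
        trace = self._trace(10000)
        out = add_sensor_noise(trace, ref_specimen, seed=3)
        sd = (out.pv_abd - trace.pv_abd).std()
        assert 0.08 <= sd <= 0.12

    def test_plant_state_columns_untouched(self, ref_specimen):
        trace = self._trace(100)
        trace["sp_abd"] = 30.0
        out = add_sensor_noise(trace, ref_specimen, seed=1)
        assert (out.sp_abd == trace.sp_abd).all()
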
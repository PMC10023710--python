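"""PID primitive, loading ratios, kinetic constraints, loading algorithms."""

import numpy as np
import pytest

from shouldersim.controller import (
    MUSCLES,
    ControlLoopState,
    LoadingRatios,
    PIDGains,
    PIDState,
    ThreeLoopController,
    adpd_couple_cap,
    cascade_step,
    default_gain_table,
    default_muscle_params,
    kinetic_constraint,
    parallel_step,
    pid_step,
    select_mode,
    ssp_ratio,
)
from shouldersim.kinematics import CardanXZY


class TestKineticConstraints:
    @pytest.mark.parametrize(
        "muscle,expected",
        [("MD", 241), ("ISP/TM", 308), ("SSC", 390), ("SSP", 132), ("AD", 118), ("PD", 136)],
    )
    def test_pcsa_times_specific_strength(self, muscle, expected):
        params = default_muscle_params()
        assert params[muscle].kinetic_constraint_N == expected

    def test_couple_cap_is_combined_deltoid_constraint(self):
        assert adpd_couple_cap() == 254

    def test_rounding_half_up(self):
        assert kinetic_constraint(12.30) == 308  # 307.5 rounds up


class TestSspRatio:
    @pytest.mark.parametrize("abd,expected", [(10.0, 0.99), (30.0, 0.52), (60.0, 0.30)])
    def test_table_knots(self, abd, expected):
        assert ssp_ratio(abd) == pytest.approx(expected)

    def test_interpolation_between_knots(self):
        assert ssp_ratio(45.0) == pytest.approx(0.41)

    def test_clamped_outside_knots(self):
        assert ssp_ratio(0.0) == pytest.approx(0.99)
        assert ssp_ratio(90.0) == pytest.approx(0.30)

    def test_table_must_decrease(self):
        with pytest.raises(ValueError):
            LoadingRatios(ssp_table=((10.0, 0.5), (30.0, 0.6), (60.0, 0.3)))


class TestPidStep:
    def test_zero_error_zero_output(self):
        gains, pid = PIDGains(2.0, 0.1, 0.0), PIDState()
        for _ in range(100):
            assert pid_step(gains, pid, 5.0, 5.0, 0.005) == 0.0

    def test_constant_error_closed_form(self):
        """With e = 1 deg, Kc = 1.4, Ti = 0.006 min, after exactly 0.36 s
        the integral term equals the proportional term: u = 2.8."""
        gains, pid = PIDGains(1.4, 0.006, 0.0), PIDState()
        dt, n = 0.005, 72  # 72 * 5 ms = 0.36 s = Ti
        for _ in range(n):
            u = pid_step(gains, pid, 1.0, 0.0, dt)
        assert u == pytest.approx(2.8, abs=1e-12)

    def test_zero_td_means_no_derivative_kick(self):
        gains, pid = PIDGains(1.0, 1.0, 0.0), PIDState()
        u1 = pid_step(gains, pid, 10.0, 0.0, 0.005)  # large error step
        gains2, pid2 = PIDGains(1.0, 1.0, 0.001), PIDState()
        u2 = pid_step(gains2, pid2, 10.0, 0.0, 0.005)
        assert u2 > u1  # derivative contributes only when Td > 0

    def test_anti_windup_freezes_integral(self):
        gains, pid = PIDGains(1.0, 0.01, 0.0), PIDState()
        pid_step(gains, pid, 1.0, 0.0, 0.005)
        pid.saturated_high = True
        acc = pid.integral_deg_s
        pid_step(gains, pid, 1.0, 0.0, 0.005)
        assert pid.integral_deg_s == acc  # frozen while clamped against error

    def test_minutes_to_seconds_conversion(self):
        g = PIDGains(1.0, 0.05, 0.002)
        assert g.Ti_s == pytest.approx(3.0)
        assert g.Td_s == pytest.approx(0.12)


def _fresh_loops():
    return {
        "abduction": ControlLoopState("abduction", mode="profile"),
        "flexion_extension": ControlLoopState("flexion_extension"),
        "internal_external_rotation": ControlLoopState("internal_external_rotation"),
    }


def _constraints():
    params = default_muscle_params()
    return {m: float(params[m].kinetic_constraint_N) for m in MUSCLES}


class TestCascadeStep:
    def test_ssp_slaved_through_ratio_at_30deg(self):
        """An MD command near 100 N at 30 deg abduction slaves SSP to
        ~0.52 x MD."""
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["abduction"].activation.preload(
            default_gain_table()["abduction"].activation_profile, 90.0, 0.0
        )
        pv = CardanXZY(30.0, 0.0, 0.0)
        sp = CardanXZY(30.0, 0.0, 0.0)
        f, diag = cascade_step(loops, ratios, _constraints(), pv, sp, 0.005)
        md, ssp = f[0], f[5]
        assert ssp == pytest.approx(md * 0.52, rel=1e-12)

    def test_couple_ratios_before_clamp(self):
        """(AD+PD)/MD = 0.60 and (SSC+ISP/TM)/MD = 1.00 in cascade mode."""
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["abduction"].activation.preload(
            default_gain_table()["abduction"].activation_profile, 150.0, 0.0
        )
        pv = sp = CardanXZY(40.0, 0.0, 0.0)
        f, diag = cascade_step(loops, ratios, _constraints(), pv, sp, 0.005)
        md = f[0]
        assert diag.total_fe_N == pytest.approx(0.60 * md, rel=1e-12)
        assert diag.total_ir_N == pytest.approx(1.00 * md, rel=1e-12)
        # split conservation is exact
        assert f[1] + f[2] == pytest.approx(diag.total_fe_N, rel=1e-12)
        assert f[3] + f[4] == pytest.approx(diag.total_ir_N, rel=1e-12)

    def test_md_clamped_to_kinetic_constraint_and_flagged(self):
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["abduction"].activation.preload(
            default_gain_table()["abduction"].activation_profile, 500.0, 0.0
        )
        pv = sp = CardanXZY(40.0, 0.0, 0.0)
        f, diag = cascade_step(loops, ratios, _constraints(), pv, sp, 0.005)
        assert f[0] == pytest.approx(241.0)
        assert diag.md_saturated

    def test_distribution_share_clamped_to_95_percent(self):
        """A huge rotation error cannot unload the antagonist below 5%."""
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["abduction"].activation.preload(
            default_gain_table()["abduction"].activation_profile, 500.0, 0.0
        )
        loops["internal_external_rotation"].distribution.preload(
            default_gain_table()["internal_external_rotation"].distribution_constant,
            5.0, 0.0,
        )
        pv = CardanXZY(40.0, 0.0, -20.0)
        sp = CardanXZY(40.0, 0.0, 0.0)
        f, diag = cascade_step(loops, ratios, _constraints(), pv, sp, 0.005)
        assert diag.share_ssc == pytest.approx(0.95)
        assert f[4] >= 10.0  # ISP/TM never unloaded

    def test_nan_pv_aborts(self):
        loops, ratios = _fresh_loops(), LoadingRatios()
        bad = CardanXZY(1.0, 2.0, 3.0)
        object.__setattr__(bad, "abduction_deg", float("nan"))
        with pytest.raises(FloatingPointError):
            cascade_step(loops, ratios, _constraints(), bad, CardanXZY(0, 0, 0), 0.005)


class TestParallelStep:
    def test_held_couples_stay_slaved_to_md(self):
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["abduction"].mode = "constant"
        loops["flexion_extension"].mode = "profile"
        loops["flexion_extension"].direction = 1.0
        loops["abduction"].activation.preload(
            default_gain_table()["abduction"].activation_constant, 120.0, 0.0
        )
        pv = sp = CardanXZY(50.0, 10.0, 0.0)
        f, diag = parallel_step(loops, ratios, _constraints(), pv, sp, 0.005)
        md = f[0]
        assert diag.total_ir_N == pytest.approx(max(1.00 * md, 20.0), rel=1e-12)

    def test_profiled_couple_total_from_own_activation(self):
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["abduction"].mode = "constant"
        loops["flexion_extension"].mode = "profile"
        loops["flexion_extension"].direction = 1.0
        g = default_gain_table()["flexion_extension"]
        loops["flexion_extension"].activation.preload(g.activation_profile, 0.5, 0.0)
        pv = sp = CardanXZY(50.0, 10.0, 0.0)
        f, diag = parallel_step(loops, ratios, _constraints(), pv, sp, 0.005)
        assert diag.total_fe_N == pytest.approx(20.0 + 0.5 * g.activation_span_N, rel=1e-9)

    def test_directional_total_cap_protects_capped_agonist(self):
        """With the agonist at its kinetic cap, the profiled couple total
        cannot grow beyond agonist cap + pretension floor."""
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["flexion_extension"].mode = "profile"
        loops["flexion_extension"].direction = 1.0
        g = default_gain_table()["flexion_extension"]
        loops["flexion_extension"].activation.preload(g.activation_profile, 10.0, 0.0)
        pv = sp = CardanXZY(50.0, 0.0, 0.0)
        f, diag = parallel_step(loops, ratios, _constraints(), pv, sp, 0.005)
        assert diag.total_fe_N <= 118.0 + 10.0 + 1e-9
        assert loops["flexion_extension"].activation.saturated_high

    def test_steady_state_forces_constant(self):
        loops, ratios = _fresh_loops(), LoadingRatios()
        loops["flexion_extension"].mode = "profile"
        pv = sp = CardanXZY(50.0, 15.0, 0.0)
        prev = None
        for _ in range(50):
            f, _ = parallel_step(loops, ratios, _constraints(), pv, sp, 0.005)
            if prev is not None:
                assert np.allclose(f, prev, atol=1e-12)
            prev = f.copy()


class TestSelectMode:
    def test_abduction_is_cascade(self):
        m = select_mode("abduction")
        assert m["algorithm"] == "cascade"
        assert m["modes"]["flexion_extension"] == "constant"
        assert m["modes"]["internal_external_rotation"] == "constant"

    def test_flexion_is_parallel_with_constant_abduction(self):
        m = select_mode("flexion")
        assert m["algorithm"] == "parallel"
        assert m["modes"]["abduction"] == "constant"
        assert m["modes"]["flexion_extension"] == "profile"

    def test_coupled_motion_has_two_profile_loops(self):
        m = select_mode("extension_internal_rotation")
        assert m["algorithm"] == "parallel"
        assert m["modes"]["flexion_extension"] == "profile"
        assert m["modes"]["internal_external_rotation"] == "profile"
        assert m["directions"]["flexion_extension"] == -1.0
        assert m["directions"]["internal_external_rotation"] == +1.0

    def test_unknown_protocol_raises(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            select_mode("baseball_pitch")


class TestGainTable:
    def test_shipped_gains(self):
        """The default gain file reproduces the tuned controller table."""
        g = default_gain_table()
        ab = g["abduction"]
        assert (ab.activation_profile.Kc, ab.activation_profile.Ti_min,
                ab.activation_profile.Td_min) == (2.600, 0.023, 0.000)
        assert (ab.activation_constant.Kc, ab.activation_constant.Ti_min,
                ab.activation_constant.Td_min) == (1.400, 0.006, 0.001)
        fe = g["flexion_extension"]
        assert (fe.distribution_profile.Kc, fe.distribution_profile.Ti_min) == (0.030, 0.050)
        assert (fe.distribution_constant.Kc, fe.distribution_constant.Ti_min) == (0.050, 0.070)
        assert (fe.activation_profile.Kc, fe.activation_profile.Ti_min) == (0.030, 0.050)
        ir = g["internal_external_rotation"]
        assert (ir.distribution_profile.Kc, ir.distribution_profile.Ti_min) == (0.030, 0.060)
        assert (ir.distribution_constant.Kc, ir.distribution_constant.Ti_min) == (0.050, 0.050)
        assert (ir.activation_profile.Kc, ir.activation_profile.Ti_min) == (0.020, 0.050)

    def test_all_profile_rows_have_zero_td(self):
        g = default_gain_table()
        for loop in g.values():
            assert loop.activation_profile.Td_min == 0.0
            if loop.distribution_profile is not None:
                assert loop.distribution_profile.Td_min == 0.0


def test_gain_table_file_round_trip(tmp_path):
    """The shipped gains can be written to and reloaded from YAML intact."""
    from shouldersim.controller import load_gain_table, save_gain_table

    path = tmp_path / "gains.yaml"
    save_gain_table(default_gain_table(), path)
    assert load_gain_table(path) == default_gain_table()


def test_controller_determinism(ref_specimen):
    """Identical seeds and configs give bit-identical force traces."""
    from shouldersim.simulate import run_trial

    t1 = run_trial(ref_specimen, "internal_rotation", seed=5)
    t2 = run_trial(ref_specimen, "internal_rotation", seed=5)
    assert t1.data.equals(t2.data)
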
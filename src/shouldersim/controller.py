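"""Three-loop muscle-force control for the glenohumeral simulator.

Three independent per-DOF loops (abduction, flexion/extension,
internal/external rotation) regulate six cable muscles.  Each loop owns an
*activation* PID (how much total force its prime mover(s) produce) and, for
the two secondary DOF, a *distribution* PID (how an agonist-antagonist
couple's total is split).  Two operating sequences exist:

cascade loading (active abduction)
    The abduction activation PID drives the middle deltoid (MD); the
    supraspinatus (SSP) is slaved to MD through an abduction-dependent
    ratio; the couple totals AD+PD and SSC+ISP/TM are slaved to MD through
    fixed prior loading ratios; the distribution PIDs split those totals to
    hold the secondary angles constant.

parallel loading (active F/E, IR/ER, and coupled motions)
    Each profiled couple's total comes from its own activation PID; the
    abduction loop holds elevation through MD (constant-mode gains) with
    SSP still slaved; couples whose DOF is merely held stay slaved to MD so
    their distribution PID retains co-contraction authority.

All muscle commands are clamped to [pretension, kinetic constraint]; the
kinetic constraint is pCSA x specific strength (25 N/cm^2).  Distribution
shares are clamped to 5-95 % of the couple total so no cable ever slackens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .kinematics import CardanXZY

__all__ = [
    "MUSCLES",
    "PIDGains",
    "PIDState",
    "LoopGains",
    "ControlLoopState",
    "LoadingRatios",
    "MuscleParams",
    "pid_step",
    "ssp_ratio",
    "kinetic_constraint",
    "default_muscle_params",
    "default_gain_table",
    "cascade_step",
    "parallel_step",
    "select_mode",
    "ThreeLoopController",
]

# Canonical muscle ordering used by every 6-vector in the package.
MUSCLES = ("MD", "AD", "PD", "SSC", "ISP/TM", "SSP")
IDX = {m: i for i, m in enumerate(MUSCLES)}

SPECIFIC_STRENGTH_N_PER_CM2 = 25.0

#: Prior loading ratios relative to MD (dimensionless).
DEFAULT_LOADING_RATIOS = {"MD": 1.0, "AD": 0.43, "PD": 0.17, "ISP/TM": 0.78, "SSC": 0.22}

#: SSP/MD ratio knots by abduction angle (deg -> ratio).
DEFAULT_SSP_TABLE = ((10.0, 0.99), (30.0, 0.52), (60.0, 0.30))

#: Physiological cross-sectional areas, cm^2.
DEFAULT_PCSA_CM2 = {
    "MD": 9.64,
    "AD": 4.70,
    "PD": 5.44,
    "ISP/TM": 12.30,
    "SSC": 15.60,
    "SSP": 5.26,
}

SHARE_MIN, SHARE_MAX = 0.05, 0.95


def kinetic_constraint(pcsa_cm2: float, specific_strength: float = SPECIFIC_STRENGTH_N_PER_CM2) -> int:
    """MVC force cap in N: pCSA x specific strength, rounded half-up."""
    return int(math.floor(pcsa_cm2 * specific_strength + 0.5))


@dataclass(frozen=True)
class MuscleParams:
    """Per-muscle static parameters."""

    name: str
    pcsa_cm2: float
    loading_ratio: float | None  # None for SSP (table-driven) and MD (prime)
    kinetic_constraint_N: int

    @classmethod
    def from_pcsa(cls, name: str, pcsa_cm2: float, loading_ratio: float | None) -> "MuscleParams":
        return cls(name, pcsa_cm2, loading_ratio, kinetic_constraint(pcsa_cm2))


def default_muscle_params() -> dict[str, MuscleParams]:
    out = {}
    for name, pcsa in DEFAULT_PCSA_CM2.items():
        ratio = DEFAULT_LOADING_RATIOS.get(name)
        out[name] = MuscleParams.from_pcsa(name, pcsa, ratio)
    return out


#: AD+PD couple-total cap: the printed combined deltoid constraint
#: (10.14 cm^2 x 25 N/cm^2 = 253.5 -> 254 N).
def adpd_couple_cap() -> int:
    return kinetic_constraint(DEFAULT_PCSA_CM2["AD"] + DEFAULT_PCSA_CM2["PD"])


@dataclass(frozen=True)
class LoadingRatios:
    """Prior loading ratios and the abduction-dependent SSP table."""

    ratios: dict = field(default_factory=lambda: dict(DEFAULT_LOADING_RATIOS))
    ssp_table: tuple = DEFAULT_SSP_TABLE

    def __post_init__(self):
        vals = [r for _, r in self.ssp_table]
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("SSP ratio table must be strictly decreasing")

    def ssp(self, abduction_deg: float) -> float:
        return ssp_ratio(abduction_deg, self.ssp_table)

    @property
    def couple_fe(self) -> float:  # AD+PD total relative to MD
        return self.ratios["AD"] + self.ratios["PD"]

    @property
    def couple_ir(self) -> float:  # SSC+ISP/TM total relative to MD
        return self.ratios["SSC"] + self.ratios["ISP/TM"]


def ssp_ratio(abduction_deg: float, table=DEFAULT_SSP_TABLE) -> float:
    """SSP/MD loading ratio: piecewise-linear through the table knots,
    clamped to the end values outside [first, last] knot."""
    if not math.isfinite(abduction_deg):
        raise ValueError("abduction angle must be finite")
    xs = [k for k, _ in table]
    ys = [v for _, v in table]
    return float(np.interp(abduction_deg, xs, ys))


# ---------------------------------------------------------------------------
# PID primitive


@dataclass(frozen=True)
class PIDGains:
    """Time-constant PID parameterization with Ti/Td in minutes."""

    Kc: float
    Ti_min: float
    Td_min: float = 0.0

    def __post_init__(self):
        if not (self.Kc > 0 and self.Ti_min > 0 and self.Td_min >= 0):
            raise ValueError("require Kc > 0, Ti > 0, Td >= 0")

    @property
    def Ti_s(self) -> float:
        return self.Ti_min * 60.0

    @property
    def Td_s(self) -> float:
        return self.Td_min * 60.0


@dataclass
class PIDState:
    """Mutable per-controller bookkeeping; reset to zero at trial start."""

    integral_deg_s: float = 0.0
    prev_error_deg: float = 0.0
    prev_output: float = 0.0
    saturated_low: bool = False
    saturated_high: bool = False

    def reset(self) -> None:
        self.integral_deg_s = 0.0
        self.prev_error_deg = 0.0
        self.prev_output = 0.0
        self.saturated_low = False
        self.saturated_high = False

    def preload(self, gains: PIDGains, u_target: float, e_deg: float = 0.0) -> None:
        """Bumpless transfer: set the integral so the output equals
        ``u_target`` at the current error under ``gains``."""
        self.integral_deg_s = (u_target / gains.Kc - e_deg) * gains.Ti_s
        self.prev_error_deg = e_deg
        self.prev_output = u_target
        self.saturated_low = self.saturated_high = False


def pid_step(gains: PIDGains, pid: PIDState, sp_deg: float, pv_deg: float, dt_s: float) -> float:
    """One PID tick: u = Kc (e + (1/Ti) int e dt + Td de/dt).

    Anti-windup is conditional integration: while the previous output was
    saturated in the direction of the current error, the accumulator is
    frozen.  Rectangular integration; derivative on the error.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    e = sp_deg - pv_deg
    windup = (pid.saturated_high and e > 0) or (pid.saturated_low and e < 0)
    if not windup:
        pid.integral_deg_s += e * dt_s
    de = (e - pid.prev_error_deg) / dt_s
    u = gains.Kc * (e + pid.integral_deg_s / gains.Ti_s + gains.Td_s * de)
    pid.prev_error_deg = e
    pid.prev_output = u
    return u


# ---------------------------------------------------------------------------
# Gain table (activation + distribution, profile + constant rows)


@dataclass(frozen=True)
class LoopGains:
    """Gain rows for one DOF loop."""

    activation_profile: PIDGains
    activation_constant: PIDGains | None
    distribution_profile: PIDGains | None
    distribution_constant: PIDGains | None
    #: actuator span, newtons of force per unit of activation output
    activation_span_N: float = 1.0


def default_gain_table() -> dict[str, LoopGains]:
    """The tuned controller parameters shipped with the simulator.

    The abduction activation controller has distinct profile/constant rows;
    the secondary loops have a single activation row (used while their DOF
    is profiled) and profile/constant distribution rows.  The activation
    span converts the dimensionless PID output to a force command and was
    fixed by closed-loop analysis of the reference specimen (see the
    methods note).
    """
    return {
        "abduction": LoopGains(
            activation_profile=PIDGains(2.600, 0.023, 0.000),
            activation_constant=PIDGains(1.400, 0.006, 0.001),
            distribution_profile=None,
            distribution_constant=None,
            activation_span_N=1.0,
        ),
        "flexion_extension": LoopGains(
            activation_profile=PIDGains(0.030, 0.050, 0.000),
            activation_constant=None,
            distribution_profile=PIDGains(0.030, 0.050, 0.000),
            distribution_constant=PIDGains(0.050, 0.070, 0.000),
            activation_span_N=200.0,
        ),
        "internal_external_rotation": LoopGains(
            activation_profile=PIDGains(0.020, 0.050, 0.000),
            activation_constant=None,
            distribution_profile=PIDGains(0.030, 0.060, 0.000),
            distribution_constant=PIDGains(0.050, 0.050, 0.000),
            activation_span_N=450.0,
        ),
    }


LOOPS = ("abduction", "flexion_extension", "internal_external_rotation")
Mode = Literal["profile", "constant"]


def save_gain_table(table: dict[str, LoopGains], path) -> None:
    """Write a gains file (YAML) mirroring the tuned controller table."""
    import yaml

    def row(g: PIDGains | None):
        if g is None:
            return None
        return {"Kc": g.Kc, "Ti_min": g.Ti_min, "Td_min": g.Td_min}

    payload = {
        name: {
            "activation_profile": row(lg.activation_profile),
            "activation_constant": row(lg.activation_constant),
            "distribution_profile": row(lg.distribution_profile),
            "distribution_constant": row(lg.distribution_constant),
            "activation_span_N": lg.activation_span_N,
        }
        for name, lg in table.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_gain_table(path) -> dict[str, LoopGains]:
    """Read a gains file written by :func:`save_gain_table` (YAML/JSON)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def row(d):
        return None if d is None else PIDGains(d["Kc"], d["Ti_min"], d.get("Td_min", 0.0))

    table = {}
    for name in LOOPS:
        d = raw[name]
        table[name] = LoopGains(
            activation_profile=row(d["activation_profile"]),
            activation_constant=row(d.get("activation_constant")),
            distribution_profile=row(d.get("distribution_profile")),
            distribution_constant=row(d.get("distribution_constant")),
            activation_span_N=float(d.get("activation_span_N", 1.0)),
        )
    return table


@dataclass
class ControlLoopState:
    """SP/PV/CV bookkeeping for one DOF loop."""

    name: str
    mode: Mode = "constant"
    direction: float = 1.0  # sign of the profiled ramp; scales activation error
    sp_deg: float = 0.0
    pv_deg: float = 0.0
    cv_N: float = 0.0
    activation: PIDState = field(default_factory=PIDState)
    distribution: PIDState = field(default_factory=PIDState)


# ---------------------------------------------------------------------------
# Loading algorithms


def _clamp_activation(pid: PIDState, raw_N: float, lo: float, hi: float) -> float:
    force = min(max(raw_N, lo), hi)
    pid.saturated_low = raw_N < lo
    pid.saturated_high = raw_N > hi
    return force


def _split_couple(
    total_N: float,
    share_agonist: float,
    pid: PIDState,
    pretension_N: float,
    cap_agonist_N: float,
    cap_antagonist_N: float,
) -> tuple[float, float]:
    """Split a couple total so the 5-95 % clamp, the pretension floor and
    the per-muscle caps all hold with exact conservation of the total."""
    lo = max(SHARE_MIN, pretension_N / total_N, 1.0 - cap_antagonist_N / total_N)
    hi = min(SHARE_MAX, 1.0 - pretension_N / total_N, cap_agonist_N / total_N)
    if lo > hi:  # total at the 2x pretension floor: forced even split
        lo = hi = 0.5
    s = min(max(share_agonist, lo), hi)
    pid.saturated_low = share_agonist < lo
    pid.saturated_high = share_agonist > hi
    return s * total_N, (1.0 - s) * total_N


@dataclass
class StepDiagnostics:
    """Per-tick controller internals recorded for invariant checking."""

    algorithm: str
    total_fe_N: float
    total_ir_N: float
    share_ad: float
    share_ssc: float
    md_saturated: bool


def _md_and_ssp(
    loops: dict[str, ControlLoopState],
    ratios: LoadingRatios,
    constraints: dict[str, float],
    gains: dict[str, LoopGains],
    pv: CardanXZY,
    sp: CardanXZY,
    dt_s: float,
    pretension_N: float,
) -> tuple[float, float]:
    ab = loops["abduction"]
    g = gains["abduction"]
    row = g.activation_profile if ab.mode == "profile" else g.activation_constant
    u = pid_step(row, ab.activation, sp.abduction_deg, pv.abduction_deg, dt_s)
    raw_md = pretension_N + g.activation_span_N * u
    f_md = _clamp_activation(ab.activation, raw_md, pretension_N, constraints["MD"])
    f_ssp = min(max(f_md * ratios.ssp(pv.abduction_deg), pretension_N), constraints["SSP"])
    ab.sp_deg, ab.pv_deg, ab.cv_N = sp.abduction_deg, pv.abduction_deg, f_md
    return f_md, f_ssp


def cascade_step(
    loops: dict[str, ControlLoopState],
    ratios: LoadingRatios,
    constraints: dict[str, float],
    pv: CardanXZY,
    sp: CardanXZY,
    dt_s: float,
    *,
    gains: dict[str, LoopGains] | None = None,
    pretension_N: float = 10.0,
    couple_cap_fe_N: float | None = None,
) -> tuple[np.ndarray, StepDiagnostics]:
    """One tick of the cascade loading algorithm (active abduction).

    Returns the six muscle forces in :data:`MUSCLES` order plus
    diagnostics.  The couple totals are MD x prior ratio *before* clamping
    (floored at 2 x pretension so the never-slack contract stays feasible).
    """
    _check_pv(pv)
    gains = gains if gains is not None else default_gain_table()
    f_md, f_ssp = _md_and_ssp(loops, ratios, constraints, gains, pv, sp, dt_s, pretension_N)
    cap_fe = couple_cap_fe_N if couple_cap_fe_N is not None else adpd_couple_cap()

    total_fe = min(max(ratios.couple_fe * f_md, 2 * pretension_N), cap_fe)
    total_ir = min(
        max(ratios.couple_ir * f_md, 2 * pretension_N),
        constraints["SSC"] + constraints["ISP/TM"],
    )

    f = np.empty(6)
    f[IDX["MD"]], f[IDX["SSP"]] = f_md, f_ssp
    share_ad, share_ssc = _distribute_secondary(
        loops, gains, constraints, pv, sp, dt_s, pretension_N, total_fe, total_ir, f
    )
    diag = StepDiagnostics(
        "cascade", total_fe, total_ir, share_ad, share_ssc,
        loops["abduction"].activation.saturated_high,
    )
    return f, diag


def parallel_step(
    loops: dict[str, ControlLoopState],
    ratios: LoadingRatios,
    constraints: dict[str, float],
    pv: CardanXZY,
    sp: CardanXZY,
    dt_s: float,
    *,
    gains: dict[str, LoopGains] | None = None,
    pretension_N: float = 10.0,
    couple_cap_fe_N: float | None = None,
    slave_ssp: bool = True,
) -> tuple[np.ndarray, StepDiagnostics]:
    """One tick of the parallel loading algorithm (active F/E / rotation).

    Profiled couples get their total from their own activation PID (signed
    by the motion direction); held couples stay slaved to MD.  The
    abduction loop drives MD with constant-mode gains; SSP remains slaved.
    """
    _check_pv(pv)
    gains = gains if gains is not None else default_gain_table()
    f_md, f_ssp = _md_and_ssp(loops, ratios, constraints, gains, pv, sp, dt_s, pretension_N)
    if not slave_ssp:
        f_ssp = pretension_N
    cap_fe = couple_cap_fe_N if couple_cap_fe_N is not None else adpd_couple_cap()
    cap_ir = constraints["SSC"] + constraints["ISP/TM"]

    def couple_total(
        loop_name: str, err_sp: float, err_pv: float, slaved: float,
        cap: float, agonist_cap: float,
    ) -> float:
        lp = loops[loop_name]
        g = gains[loop_name]
        if lp.mode == "profile":
            # Raising the total beyond (agonist cap + antagonist floor)
            # can only add antagonist force -- with the agonist muscle at
            # its kinetic constraint the extra total *opposes* the motion
            # and creates a runaway, so the cap is directional.
            cap = min(cap, agonist_cap + pretension_N)
            u = pid_step(
                g.activation_profile, lp.activation,
                lp.direction * err_sp, lp.direction * err_pv, dt_s,
            )
            raw = 2 * pretension_N + g.activation_span_N * u
            total = min(max(raw, 2 * pretension_N), cap)
            lp.activation.saturated_low = raw < 2 * pretension_N
            lp.activation.saturated_high = raw > cap
        else:
            total = min(max(slaved, 2 * pretension_N), cap)
        lp.cv_N = total
        return total

    fe_agonist = "AD" if loops["flexion_extension"].direction > 0 else "PD"
    ir_agonist = "SSC" if loops["internal_external_rotation"].direction > 0 else "ISP/TM"
    total_fe = couple_total(
        "flexion_extension", sp.flexion_deg, pv.flexion_deg,
        ratios.couple_fe * f_md, cap_fe, constraints[fe_agonist],
    )
    total_ir = couple_total(
        "internal_external_rotation", sp.rotation_deg, pv.rotation_deg,
        ratios.couple_ir * f_md, cap_ir, constraints[ir_agonist],
    )

    f = np.empty(6)
    f[IDX["MD"]], f[IDX["SSP"]] = f_md, f_ssp
    share_ad, share_ssc = _distribute_secondary(
        loops, gains, constraints, pv, sp, dt_s, pretension_N, total_fe, total_ir, f
    )
    diag = StepDiagnostics(
        "parallel", total_fe, total_ir, share_ad, share_ssc,
        loops["abduction"].activation.saturated_high,
    )
    return f, diag


def _distribute_secondary(
    loops, gains, constraints, pv, sp, dt_s, pretension_N, total_fe, total_ir, f
) -> tuple[float, float]:
    """Run both distribution PIDs and split the couple totals in place."""
    fe = loops["flexion_extension"]
    g_fe = gains["flexion_extension"]
    row = g_fe.distribution_profile if fe.mode == "profile" else g_fe.distribution_constant
    u = pid_step(row, fe.distribution, sp.flexion_deg, pv.flexion_deg, dt_s)
    # positive flexion error -> larger AD share
    f_ad, f_pd = _split_couple(
        total_fe, 0.5 + u, fe.distribution, pretension_N,
        constraints["AD"], constraints["PD"],
    )
    fe.sp_deg, fe.pv_deg = sp.flexion_deg, pv.flexion_deg
    fe.cv_N = total_fe

    ir = loops["internal_external_rotation"]
    g_ir = gains["internal_external_rotation"]
    row = g_ir.distribution_profile if ir.mode == "profile" else g_ir.distribution_constant
    u2 = pid_step(row, ir.distribution, sp.rotation_deg, pv.rotation_deg, dt_s)
    # positive internal-rotation error -> larger SSC share
    f_ssc, f_isp = _split_couple(
        total_ir, 0.5 + u2, ir.distribution, pretension_N,
        constraints["SSC"], constraints["ISP/TM"],
    )
    ir.sp_deg, ir.pv_deg = sp.rotation_deg, pv.rotation_deg
    ir.cv_N = total_ir

    f[IDX["AD"]], f[IDX["PD"]] = f_ad, f_pd
    f[IDX["SSC"]], f[IDX["ISP/TM"]] = f_ssc, f_isp
    share_ad = f_ad / total_fe if total_fe > 0 else 0.5
    share_ssc = f_ssc / total_ir if total_ir > 0 else 0.5
    return share_ad, share_ssc


def _check_pv(pv: CardanXZY) -> None:
    arr = pv.as_array()
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError("NaN/inf in process variable: trial aborted")


# ---------------------------------------------------------------------------
# Mode selection


_PROTOCOL_MODES: dict[str, dict] = {
    "abduction": {
        "algorithm": "cascade",
        "modes": {"abduction": "profile", "flexion_extension": "constant", "internal_external_rotation": "constant"},
        "directions": {},
    },
    "flexion": {
        "algorithm": "parallel",
        "modes": {"abduction": "constant", "flexion_extension": "profile", "internal_external_rotation": "constant"},
        "directions": {"flexion_extension": +1.0},
    },
    "extension": {
        "algorithm": "parallel",
        "modes": {"abduction": "constant", "flexion_extension": "profile", "internal_external_rotation": "constant"},
        "directions": {"flexion_extension": -1.0},
    },
    "internal_rotation": {
        "algorithm": "parallel",
        "modes": {"abduction": "constant", "flexion_extension": "constant", "internal_external_rotation": "profile"},
        "directions": {"internal_external_rotation": +1.0},
    },
    "external_rotation": {
        "algorithm": "parallel",
        "modes": {"abduction": "constant", "flexion_extension": "constant", "internal_external_rotation": "profile"},
        "directions": {"internal_external_rotation": -1.0},
    },
    "extension_internal_rotation": {
        "algorithm": "parallel",
        "modes": {"abduction": "constant", "flexion_extension": "profile", "internal_external_rotation": "profile"},
        "directions": {"flexion_extension": -1.0, "internal_external_rotation": +1.0},
    },
}


def select_mode(motion_spec: str) -> dict:
    """Per-loop profile/constant assignment and loading algorithm for a
    supported motion protocol."""
    try:
        entry = _PROTOCOL_MODES[motion_spec]
    except KeyError:
        raise ValueError(
            f"unknown protocol {motion_spec!r}; expected one of {sorted(_PROTOCOL_MODES)}"
        ) from None
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in entry.items()}


# ---------------------------------------------------------------------------
# Stateful facade used by the trial runner


class ThreeLoopController:
    """Stateful three-loop controller stepping at the plant rate.

    The trial runner switches phases (loading ramp / settling hold / scored
    segment); this class applies the matching gain rows with bumpless
    transfer of every PID whose role changes.
    """

    def __init__(
        self,
        *,
        gains: dict[str, LoopGains] | None = None,
        ratios: LoadingRatios | None = None,
        muscle_params: dict[str, MuscleParams] | None = None,
        pretension_N: float = 10.0,
        slave_ssp_in_parallel: bool = True,
    ):
        self.gains = gains if gains is not None else default_gain_table()
        self.ratios = ratios if ratios is not None else LoadingRatios()
        params = muscle_params if muscle_params is not None else default_muscle_params()
        self.constraints = {m: float(params[m].kinetic_constraint_N) for m in MUSCLES}
        self.couple_cap_fe = float(adpd_couple_cap())
        self.pretension_N = pretension_N
        self.slave_ssp_in_parallel = slave_ssp_in_parallel
        self.loops = {name: ControlLoopState(name) for name in LOOPS}
        self._prev_profiled: tuple[bool, bool, bool] | None = None

    def reset(self) -> None:
        for loop in self.loops.values():
            loop.activation.reset()
            loop.distribution.reset()
            loop.mode = "constant"
        self._prev_profiled = None

    def step(
        self,
        sp: CardanXZY,
        pv: CardanXZY,
        profiled: tuple[bool, bool, bool],
        directions: tuple[float, float, float],
        dt_s: float,
    ) -> tuple[np.ndarray, StepDiagnostics]:
        """One control tick.  ``profiled`` flags (abd, F/E, IR/ER) select
        the operating sequence: cascade iff no secondary DOF is profiled."""
        if profiled != self._prev_profiled:
            self._handle_transition(profiled)
        for name, want, d in zip(LOOPS, profiled, directions):
            self.loops[name].mode = "profile" if want else "constant"
            self.loops[name].direction = d if d != 0 else 1.0
        kwargs = dict(
            gains=self.gains,
            pretension_N=self.pretension_N,
            couple_cap_fe_N=self.couple_cap_fe,
        )
        if not (profiled[1] or profiled[2]):
            return cascade_step(
                self.loops, self.ratios, self.constraints, pv, sp, dt_s, **kwargs
            )
        return parallel_step(
            self.loops, self.ratios, self.constraints, pv, sp, dt_s,
            slave_ssp=self.slave_ssp_in_parallel, **kwargs,
        )

    def _handle_transition(self, profiled: tuple[bool, bool, bool]) -> None:
        """Bumpless transfer at gain-row / role switches."""
        prev = self._prev_profiled
        self._prev_profiled = profiled
        if prev is None:
            return
        # Abduction activation: profile <-> constant row swap.
        if prev[0] != profiled[0]:
            g = self.gains["abduction"]
            row = g.activation_profile if profiled[0] else g.activation_constant
            ab = self.loops["abduction"]
            u_now = (ab.cv_N - self.pretension_N) / g.activation_span_N
            ab.activation.preload(row, u_now, ab.activation.prev_error_deg)
        # Secondary loops: preload the activation PID from the current
        # (slaved) couple total when the loop becomes profiled, and the
        # distribution PID across its row swap.
        for i, name in ((1, "flexion_extension"), (2, "internal_external_rotation")):
            if prev[i] == profiled[i]:
                continue
            lp = self.loops[name]
            g = self.gains[name]
            if profiled[i]:
                u_now = (lp.cv_N - 2 * self.pretension_N) / g.activation_span_N
                lp.activation.preload(g.activation_profile, max(u_now, 0.0), 0.0)
            row = g.distribution_profile if profiled[i] else g.distribution_constant
            lp.distribution.preload(row, lp.distribution.prev_output, lp.distribution.prev_error_deg)
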
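"""Virtual cadaver specimen: geometry, inertia, muscles, noise.

The specimen is a physics stand-in for a cadaveric shoulder mounted on the
rig: a humerus (plus 3 kg forearm-replacement mass) free in its three
rotational DOF about the glenohumeral centre of rotation, six straight
cable muscles running from humeral insertions to fixed scapular guides,
a passive capsule (per-DOF stiffness and damping), and an elastic glenoid
translation model.  The scapula is rigidly mounted with 10 deg forward
inclination, applied as a constant tilt of gravity in the scapular frame.

The reference geometry is an editable, documented invention: no cadaver
coordinates are published for the rig, so insertions, guides and masses
were chosen once so that moment-arm signs are anatomical and steady-state
muscle forces fall in the physiological range the rig reports (middle
deltoid on the order of 150-200 N at 60 deg abduction, head translations
of a few millimetres).  All values can be overridden via YAML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import fsolve, linprog

from . import _engine
from .controller import MUSCLES
from .kinematics import CardanXZY

__all__ = [
    "MusclePath",
    "VirtualSpecimen",
    "PlantState",
    "SpecimenRejectionError",
    "DislocationError",
    "InstabilityError",
    "reference_specimen",
    "generate_specimen",
    "moment_arm_torque",
    "step_dynamics",
    "passive_equilibrium",
    "add_sensor_noise",
]

SCHEMA_VERSION = 1


class SpecimenRejectionError(RuntimeError):
    """A sampled specimen violated a physical validity check."""


class DislocationError(RuntimeError):
    """Humeral-head translation exceeded the dislocation limit."""


class InstabilityError(RuntimeError):
    """Angular speed exceeded the configured stability bound."""


@dataclass(frozen=True)
class MusclePath:
    """Straight-line cable from humeral insertion to scapular guide.

    The force direction is the unit vector from the (rotated) insertion
    toward the guide point.
    """

    name: str
    insertion_mm: np.ndarray  # humeral frame
    guide_mm: np.ndarray  # scapular frame

    def __post_init__(self):
        ins = np.asarray(self.insertion_mm, dtype=float)
        gui = np.asarray(self.guide_mm, dtype=float)
        if ins.shape != (3,) or gui.shape != (3,):
            raise ValueError("points must be 3-vectors")
        if np.allclose(ins, gui):
            raise ValueError("insertion must differ from guide point")
        object.__setattr__(self, "insertion_mm", ins)
        object.__setattr__(self, "guide_mm", gui)


@dataclass
class PlantState:
    """Plant state: Cardan angles (deg), rates (deg/s), translations (mm)."""

    angles: CardanXZY = field(default_factory=lambda: CardanXZY(10.0, 0.0, 0.0))
    velocity_deg_s: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def q_rad(self) -> np.ndarray:
        return np.radians(self.angles.as_array())


# Reference geometry, millimetres in the scapular frame (X anterior,
# Y superior, Z medial; right shoulder; COR at the origin).
_REF_INSERTIONS_MM = {
    "MD": (5.0, -110.0, -15.0),
    "AD": (20.0, -105.0, -12.0),
    "PD": (-20.0, -105.0, -12.0),
    "SSC": (25.0, -10.0, -10.0),
    "ISP/TM": (-22.0, -8.0, -15.0),
    "SSP": (0.0, 10.0, -28.0),
}
_REF_GUIDES_MM = {
    "MD": (0.0, 35.0, -25.0),
    "AD": (70.0, 25.0, -20.0),
    "PD": (-70.0, 25.0, -30.0),
    "SSC": (15.0, -10.0, 60.0),
    "ISP/TM": (-20.0, -15.0, 55.0),
    "SSP": (0.0, 25.0, 40.0),
}


@dataclass(frozen=True)
class VirtualSpecimen:
    """Everything the plant needs, with seeded variability provenance."""

    muscles: tuple[MusclePath, ...]
    inertia_kgm2: np.ndarray  # principal inertia about the COR, humeral axes
    humerus_mass_kg: float
    humerus_com_mm: np.ndarray
    forearm_mass_kg: float
    forearm_lever_mm: np.ndarray
    capsule_stiffness_Nm_rad: np.ndarray  # per DOF (abd, F/E, IR/ER)
    capsule_damping_Nms_rad: np.ndarray
    capsule_rest_deg: np.ndarray
    translation_stiffness_N_mm: np.ndarray  # AP/SI/ML
    #: anatomical head centre minus kinematic COR, humeral frame (mm):
    #: the head centre sweeps an arc as the joint rotates, the dominant
    #: source of measured translations on a real specimen
    head_center_offset_mm: np.ndarray
    scapular_inclination_deg: float
    noise_angle_deg: float
    noise_force_N: float
    noise_translation_mm: float
    pretension_N: float
    dislocation_limit_mm: float
    speed_limit_deg_s: float
    seed: int
    specimen_id: str = "reference"
    preload_N: np.ndarray = field(default_factory=lambda: np.zeros(3))
    #: cluster-to-anatomical alignment: the humeral anatomical frame is
    #: digitised with the arm hanging at rest, so flexion and axial
    #: rotation read zero there (set by :meth:`with_preload`)
    anatomical_cal: np.ndarray = field(default_factory=lambda: np.eye(3))
    rest_angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    #: resting-frame position of the head-centre offset (mm), so measured
    #: translations vanish at the centred rest state
    geo_ref_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    # -- packed views used by the engine (metres, SI) -------------------
    def _pack(self):
        ins = np.array([m.insertion_mm for m in self.muscles]) / 1000.0
        gui = np.array([m.guide_mm for m in self.muscles]) / 1000.0
        mass_pos = np.array([self.humerus_com_mm, self.forearm_lever_mm]) / 1000.0
        masses = np.array([self.humerus_mass_kg, self.forearm_mass_kg])
        return ins, gui, mass_pos, masses

    @property
    def gravity_dir(self) -> np.ndarray:
        """Unit gravity vector in the scapular frame; the 10 deg forward
        inclination tilts gravity toward -X (posterior lean of the arm)."""
        t = math.radians(self.scapular_inclination_deg)
        return np.array([-math.sin(t), -math.cos(t), 0.0])

    def with_preload(self) -> "VirtualSpecimen":
        """Finalize setup calibration at the pretensioned resting state:
        record the net joint load there (so translations measure
        displacement from the centred head) and the humeral anatomical
        alignment (so flexion/rotation read zero with the arm at rest)."""
        rest = passive_equilibrium(self, self.pretension_N)
        q = np.radians(rest)
        ins, gui, mass_pos, masses = self._pack()
        forces = np.full(len(self.muscles), self.pretension_N)
        _, fnet = _engine.world_loads(
            q, forces, ins, gui, mass_pos, masses, self.gravity_dir
        )
        R_rest = _engine.rot_xzy(q[0], q[1], q[2])
        ca, sa = math.cos(q[0]), math.sin(q[0])
        Rx0 = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
        cal = R_rest.T @ Rx0
        return replace(
            self, preload_N=fnet, anatomical_cal=cal, rest_angles_deg=rest,
            geo_ref_mm=R_rest @ self.head_center_offset_mm,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "specimen_id": self.specimen_id,
            "seed": int(self.seed),
            "muscles": {
                m.name: {
                    "insertion_mm": [float(v) for v in m.insertion_mm],
                    "guide_mm": [float(v) for v in m.guide_mm],
                }
                for m in self.muscles
            },
            "inertia_kgm2": [float(v) for v in self.inertia_kgm2],
            "humerus_mass_kg": float(self.humerus_mass_kg),
            "humerus_com_mm": [float(v) for v in self.humerus_com_mm],
            "forearm_mass_kg": float(self.forearm_mass_kg),
            "forearm_lever_mm": [float(v) for v in self.forearm_lever_mm],
            "capsule_stiffness_Nm_rad": [float(v) for v in self.capsule_stiffness_Nm_rad],
            "capsule_damping_Nms_rad": [float(v) for v in self.capsule_damping_Nms_rad],
            "capsule_rest_deg": [float(v) for v in self.capsule_rest_deg],
            "translation_stiffness_N_mm": [float(v) for v in self.translation_stiffness_N_mm],
            "head_center_offset_mm": [float(v) for v in self.head_center_offset_mm],
            "scapular_inclination_deg": float(self.scapular_inclination_deg),
            "noise_angle_deg": float(self.noise_angle_deg),
            "noise_force_N": float(self.noise_force_N),
            "noise_translation_mm": float(self.noise_translation_mm),
            "pretension_N": float(self.pretension_N),
            "dislocation_limit_mm": float(self.dislocation_limit_mm),
            "speed_limit_deg_s": float(self.speed_limit_deg_s),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VirtualSpecimen":
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise ValueError(f"unsupported specimen schema {d.get('schema_version')}")
        muscles = tuple(
            MusclePath(name, np.asarray(spec["insertion_mm"]), np.asarray(spec["guide_mm"]))
            for name, spec in ((m, d["muscles"][m]) for m in MUSCLES)
        )
        spec = cls(
            muscles=muscles,
            inertia_kgm2=np.asarray(d["inertia_kgm2"], dtype=float),
            humerus_mass_kg=d["humerus_mass_kg"],
            humerus_com_mm=np.asarray(d["humerus_com_mm"], dtype=float),
            forearm_mass_kg=d["forearm_mass_kg"],
            forearm_lever_mm=np.asarray(d["forearm_lever_mm"], dtype=float),
            capsule_stiffness_Nm_rad=np.asarray(d["capsule_stiffness_Nm_rad"], dtype=float),
            capsule_damping_Nms_rad=np.asarray(d["capsule_damping_Nms_rad"], dtype=float),
            capsule_rest_deg=np.asarray(d["capsule_rest_deg"], dtype=float),
            translation_stiffness_N_mm=np.asarray(d["translation_stiffness_N_mm"], dtype=float),
            head_center_offset_mm=np.asarray(d["head_center_offset_mm"], dtype=float),
            scapular_inclination_deg=d["scapular_inclination_deg"],
            noise_angle_deg=d["noise_angle_deg"],
            noise_force_N=d["noise_force_N"],
            noise_translation_mm=d["noise_translation_mm"],
            pretension_N=d["pretension_N"],
            dislocation_limit_mm=d["dislocation_limit_mm"],
            speed_limit_deg_s=d["speed_limit_deg_s"],
            seed=d.get("seed", 0),
            specimen_id=d.get("specimen_id", "custom"),
        )
        return spec.with_preload()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VirtualSpecimen":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def reference_specimen() -> VirtualSpecimen:
    """The documented reference specimen (see module docstring)."""
    spec = VirtualSpecimen(
        muscles=tuple(
            MusclePath(m, np.array(_REF_INSERTIONS_MM[m]), np.array(_REF_GUIDES_MM[m]))
            for m in MUSCLES
        ),
        inertia_kgm2=np.array([0.29, 0.006, 0.29]),
        humerus_mass_kg=2.0,
        humerus_com_mm=np.array([0.0, -140.0, 0.0]),
        forearm_mass_kg=3.0,
        forearm_lever_mm=np.array([0.0, -280.0, 0.0]),
        capsule_stiffness_Nm_rad=np.array([3.0, 2.0, 2.2]),
        capsule_damping_Nms_rad=np.array([3.0, 2.0, 0.8]),
        capsule_rest_deg=np.array([12.0, 0.0, 0.0]),
        translation_stiffness_N_mm=np.array([15.0, 18.0, 35.0]),
        head_center_offset_mm=np.array([6.0, 3.0, 4.0]),
        scapular_inclination_deg=10.0,
        noise_angle_deg=0.1,
        noise_force_N=0.5,
        noise_translation_mm=0.1,
        pretension_N=15.0,
        dislocation_limit_mm=15.0,
        speed_limit_deg_s=200.0,
        seed=0,
        specimen_id="reference",
    )
    return spec.with_preload()


# ---------------------------------------------------------------------------


def moment_arm_torque(path: MusclePath, state: PlantState, force_N: float) -> np.ndarray:
    """Torque about the COR (N m, scapular frame) of one cable muscle.

    tau = r x (F u) with r the rotated insertion point and u the unit
    vector from insertion toward the guide.
    """
    if force_N < 0:
        raise ValueError("cables cannot push: force must be >= 0")
    q = state.q_rad()
    R = _engine.rot_xzy(q[0], q[1], q[2])
    p = R @ (path.insertion_mm / 1000.0)
    d = path.guide_mm / 1000.0 - p
    u = d / np.linalg.norm(d)
    return np.cross(p, force_N * u)


def generalized_muscle_torque(
    specimen: VirtualSpecimen, angles: CardanXZY, forces: np.ndarray
) -> np.ndarray:
    """Muscle torque mapped to the Cardan coordinates (abd, F/E, IR/ER).

    Component k is the work-conjugate torque of coordinate k; its sign is
    the moment-arm sign of the combined forces in that DOF.
    """
    q = np.radians(angles.as_array())
    R = _engine.rot_xzy(q[0], q[1], q[2])
    E = _engine.rate_map(q[0], q[1])
    tau = np.zeros(3)
    for path, f in zip(specimen.muscles, forces):
        p = R @ (path.insertion_mm / 1000.0)
        d = path.guide_mm / 1000.0 - p
        u = d / np.linalg.norm(d)
        tau += np.cross(p, f * u)
    return E.T @ tau


def step_dynamics(
    specimen: VirtualSpecimen,
    state: PlantState,
    muscle_forces: np.ndarray,
    dt_s: float,
) -> PlantState:
    """Advance the plant by one RK4 step with forces held constant.

    Raises :class:`DislocationError` / :class:`InstabilityError` when the
    configured translation or angular-speed limits are exceeded.
    """
    if not (0.0 < dt_s <= 0.02):
        raise ValueError("dt must be in (0, 0.02] s")
    forces = np.asarray(muscle_forces, dtype=float)
    if forces.shape != (len(specimen.muscles),):
        raise ValueError("need one force per muscle")
    if np.any(forces < 0):
        raise ValueError("cables cannot push: forces must be >= 0")
    ins, gui, mass_pos, masses = specimen._pack()
    q = state.q_rad()
    qd = np.radians(state.velocity_deg_s)
    K = specimen.capsule_stiffness_Nm_rad
    C = specimen.capsule_damping_Nms_rad
    q_rest = np.radians(specimen.capsule_rest_deg)
    q_new, qd_new = _engine.rk4_step(
        q, qd, forces, dt_s, ins, gui, mass_pos, masses,
        specimen.gravity_dir, K, C, q_rest, specimen.inertia_kgm2,
    )
    t_mm = _engine.translation_mm(
        q_new, forces, ins, gui, mass_pos, masses, specimen.gravity_dir,
        specimen.translation_stiffness_N_mm, specimen.preload_N,
        specimen.head_center_offset_mm, specimen.geo_ref_mm,
    )
    speed = np.degrees(np.abs(qd_new))
    if np.any(speed > specimen.speed_limit_deg_s):
        raise InstabilityError(f"angular speed {speed.max():.1f} deg/s exceeds limit")
    if np.any(np.abs(t_mm) > specimen.dislocation_limit_mm):
        raise DislocationError(f"translation {np.abs(t_mm).max():.1f} mm exceeds limit")
    ang = np.degrees(q_new)
    return PlantState(
        angles=CardanXZY(ang[0], ang[1], ang[2]),
        velocity_deg_s=np.degrees(qd_new),
        translation_mm=t_mm,
    )


def passive_equilibrium(specimen: VirtualSpecimen, force_per_muscle_N: float) -> np.ndarray:
    """Static equilibrium angles (deg) under uniform cable force.

    Solves the generalized torque balance with zero velocity; used for the
    resting-posture invariant and to initialize trials.
    """
    ins, gui, mass_pos, masses = specimen._pack()
    forces = np.full(len(specimen.muscles), float(force_per_muscle_N))
    K = specimen.capsule_stiffness_Nm_rad
    C = specimen.capsule_damping_Nms_rad
    q_rest = np.radians(specimen.capsule_rest_deg)

    def residual(q):
        return _engine.generalized_torque(
            q, np.zeros(3), forces, ins, gui, mass_pos, masses,
            specimen.gravity_dir, K, C, q_rest,
        )

    q0 = np.radians([10.0, 0.0, 0.0])
    q_eq, info, ier, _ = fsolve(residual, q0, full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-8:
        raise SpecimenRejectionError("no passive equilibrium found")
    return np.degrees(q_eq)


# ---------------------------------------------------------------------------


_VARIED_FIELDS = (
    "inertia", "masses", "levers", "stiffness", "damping",
    "translation_stiffness", "insertions", "guides",
)


def generate_specimen(
    seed: int,
    variability: float = 0.10,
    *,
    base: VirtualSpecimen | None = None,
    max_tries: int = 20,
) -> VirtualSpecimen:
    """Seeded specimen with fractional inter-specimen variability.

    Every geometric and mechanical quantity of the reference specimen is
    scaled by (1 + eps), eps ~ N(0, variability) truncated at +/-2.5 SD,
    independently per component.  A sampled specimen must pass the
    physical validity checks (resting equilibrium within [4, 16] deg
    abduction; anatomical moment-arm signs at 30 deg abduction); failing
    draws are rejected and resampled, and a :class:`SpecimenRejectionError`
    carrying the reports is raised after ``max_tries`` failures.
    """
    if not (0.0 <= variability <= 0.3):
        raise ValueError("variability fraction must be in [0, 0.3]")
    base = base if base is not None else reference_specimen()
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(max_tries):
        candidate = _perturb(base, rng, variability, seed)
        try:
            _validate(candidate)
        except SpecimenRejectionError as exc:
            reports.append(str(exc))
            continue
        return candidate
    raise SpecimenRejectionError(
        f"no valid specimen in {max_tries} draws (seed={seed}): {reports}"
    )


def _perturb(base: VirtualSpecimen, rng, v: float, seed: int) -> VirtualSpecimen:
    def jitter(x):
        x = np.asarray(x, dtype=float)
        eps = np.clip(rng.normal(0.0, v, size=x.shape), -2.5 * v, 2.5 * v)
        return x * (1.0 + eps)

    muscles = tuple(
        MusclePath(m.name, jitter(m.insertion_mm), jitter(m.guide_mm))
        for m in base.muscles
    )
    spec = replace(
        base,
        muscles=muscles,
        inertia_kgm2=jitter(base.inertia_kgm2),
        humerus_mass_kg=float(jitter(base.humerus_mass_kg)),
        humerus_com_mm=jitter(base.humerus_com_mm),
        forearm_mass_kg=float(jitter(base.forearm_mass_kg)),
        forearm_lever_mm=jitter(base.forearm_lever_mm),
        capsule_stiffness_Nm_rad=jitter(base.capsule_stiffness_Nm_rad),
        capsule_damping_Nms_rad=jitter(base.capsule_damping_Nms_rad),
        translation_stiffness_N_mm=jitter(base.translation_stiffness_N_mm),
        head_center_offset_mm=jitter(base.head_center_offset_mm),
        seed=int(seed),
        specimen_id=f"generated-{seed}",
        preload_N=np.zeros(3),
    )
    return spec.with_preload()


#: expected generalized moment-arm signs at 30 deg abduction, neutral F/E
#: and rotation: (DOF index, sign) per muscle.
_SIGN_CHECKS = {
    "MD": (0, +1),
    "SSP": (0, +1),
    "AD": (1, +1),
    "PD": (1, -1),
    "SSC": (2, +1),
    "ISP/TM": (2, -1),
}


#: protocol end poses that must be statically achievable within the
#: kinetic constraints: (pose, which secondary couples are profiled)
_FEASIBILITY_POSES = (
    (CardanXZY(60.0, 0.0, 0.0), (False, False)),
    (CardanXZY(50.0, 30.0, 0.0), (True, False)),
    (CardanXZY(50.0, -30.0, 0.0), (True, False)),
    (CardanXZY(30.0, 0.0, 45.0), (False, True)),
    (CardanXZY(30.0, 0.0, -45.0), (False, True)),
    (CardanXZY(40.0, -30.0, 30.0), (True, True)),
)

# Muscle force caps (pCSA x 25 N/cm^2) and slaving ratios used by the
# feasibility screen; mirrors the controller defaults.
_CAPS = {"MD": 241.0, "AD": 118.0, "PD": 136.0, "SSC": 390.0, "ISP/TM": 308.0, "SSP": 132.0}
_FE_COUPLE_CAP = 254.0
_RATIO_FE, _RATIO_IR = 0.60, 1.00
_SSP_KNOTS = ((10.0, 0.99), (30.0, 0.52), (60.0, 0.30))


def _static_feasible(
    spec: VirtualSpecimen,
    pose: CardanXZY,
    profiled: tuple[bool, bool],
    *,
    cap_margin: float = 0.90,
    floor_N: float = 10.0,
) -> tuple[bool, float]:
    """Linear-programming check that a static muscle-force balance exists
    at ``pose`` under the controller's force structure: SSP slaved to MD,
    held couples slaved through the prior loading ratios with 5-95%
    shares, caps shrunk by ``cap_margin`` as headroom for dynamics.

    Returns (feasible, predicted head translation magnitude in mm at the
    minimum-effort balance); the translation estimate screens specimens
    that would approach their dislocation limit mid-protocol."""
    # protocol poses are anatomical; map to the plant's geometric angles
    from .kinematics import compose_orientation, decompose_orientation

    R_geom = compose_orientation(pose) @ spec.anatomical_cal.T
    geo = decompose_orientation(R_geom)
    # unit generalized torque per muscle, plus the passive/gravity load
    A = np.zeros((3, len(MUSCLES)))
    for i in range(len(MUSCLES)):
        unit = np.zeros(len(MUSCLES))
        unit[i] = 1.0
        A[:, i] = generalized_muscle_torque(spec, geo, unit)
    q = np.radians(geo.as_array())
    ins, gui, mass_pos, masses = spec._pack()
    b = _engine.generalized_torque(
        q, np.zeros(3), np.zeros(len(MUSCLES)), ins, gui, mass_pos, masses,
        spec.gravity_dir, spec.capsule_stiffness_Nm_rad,
        spec.capsule_damping_Nms_rad, np.radians(spec.capsule_rest_deg),
    )
    xs, ys = zip(*_SSP_KNOTS)
    r_ssp = float(np.interp(pose.abduction_deg, xs, ys))
    # variables: (MD, AD, PD, SSC, ISP/TM); SSP = r_ssp * MD
    A5 = A[:, :5].copy()
    A5[:, 0] += r_ssp * A[:, 5]
    bounds = [
        (floor_N, cap_margin * _CAPS["MD"]),
        (floor_N, cap_margin * _CAPS["AD"]),
        (floor_N, cap_margin * _CAPS["PD"]),
        (floor_N, cap_margin * _CAPS["SSC"]),
        (floor_N, cap_margin * _CAPS["ISP/TM"]),
    ]
    A_ub, b_ub, A_eq_extra, b_eq_extra = [], [], [], []
    # AD+PD couple cap always applies
    A_ub.append([0.0, 1.0, 1.0, 0.0, 0.0]); b_ub.append(cap_margin * _FE_COUPLE_CAP)
    if not profiled[0]:  # F/E held: AD+PD slaved to MD, shares 5-95%
        A_eq_extra.append([-_RATIO_FE, 1.0, 1.0, 0.0, 0.0]); b_eq_extra.append(0.0)
        A_ub.append([0.05 * _RATIO_FE, -1.0, 0.0, 0.0, 0.0]); b_ub.append(0.0)
        A_ub.append([-0.95 * _RATIO_FE, 1.0, 0.0, 0.0, 0.0]); b_ub.append(0.0)
    if not profiled[1]:  # rotation held: SSC+ISP/TM slaved to MD
        A_eq_extra.append([-_RATIO_IR, 0.0, 0.0, 1.0, 1.0]); b_eq_extra.append(0.0)
        A_ub.append([0.05 * _RATIO_IR, 0.0, 0.0, -1.0, 0.0]); b_ub.append(0.0)
        A_ub.append([-0.95 * _RATIO_IR, 0.0, 0.0, 1.0, 0.0]); b_ub.append(0.0)
    A_eq = np.vstack([A5] + [np.array(r)[None, :] for r in A_eq_extra])
    b_eq = np.concatenate([-b, np.array(b_eq_extra)])
    res = linprog(
        c=np.ones(5), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
    )
    if not res.success:
        return False, np.inf
    f = np.concatenate([res.x, [r_ssp * res.x[0]]])
    t = _engine.translation_mm(
        q, f, ins, gui, mass_pos, masses, spec.gravity_dir,
        spec.translation_stiffness_N_mm, spec.preload_N,
        spec.head_center_offset_mm, spec.geo_ref_mm,
    )
    return True, float(np.abs(t).max())


def _validate(spec: VirtualSpecimen) -> None:
    eq = passive_equilibrium(spec, spec.pretension_N)
    if not (4.0 <= eq[0] <= 16.0):
        raise SpecimenRejectionError(
            f"resting abduction {eq[0]:.1f} deg outside [4, 16]"
        )
    pose = CardanXZY(30.0, 0.0, 0.0)
    for i, m in enumerate(MUSCLES):
        forces = np.zeros(len(MUSCLES))
        forces[i] = 1.0
        tau = generalized_muscle_torque(spec, pose, forces)
        dof, sign = _SIGN_CHECKS[m]
        if tau[dof] * sign <= 0:
            raise SpecimenRejectionError(
                f"{m} moment-arm sign check failed: tau[{dof}] = {tau[dof]:+.4f}"
            )
    for p, prof in _FEASIBILITY_POSES:
        feasible, t_max = _static_feasible(spec, p, prof)
        label = f"({p.abduction_deg:.0f}, {p.flexion_deg:.0f}, {p.rotation_deg:.0f})"
        if not feasible:
            raise SpecimenRejectionError(
                f"static force balance infeasible at pose {label}"
            )
        if t_max > 14.0:
            raise SpecimenRejectionError(
                f"predicted head translation {t_max:.1f} mm at pose {label} "
                f"approaches the dislocation limit"
            )


# ---------------------------------------------------------------------------


_NOISE_GROUPS = (
    (("pv_abd", "pv_fe", "pv_ir"), "noise_angle_deg"),
    (("ap_mm", "si_mm", "ml_mm"), "noise_translation_mm"),
    (("f_md", "f_ad", "f_pd", "f_ssc", "f_isp_tm", "f_ssp"), "noise_force_N"),
)


def add_sensor_noise(trace, specimen: VirtualSpecimen, seed: int):
    """Additive Gaussian sensor noise on the *reported* angle, translation
    and force columns of a trace; the underlying plant state is untouched.
    Reproducible for a given seed; zero SDs return the input unchanged."""
    rng = np.random.default_rng(seed)
    out = trace.copy()
    for cols, attr in _NOISE_GROUPS:
        sd = getattr(specimen, attr)
        for c in cols:
            if c in out.columns and sd > 0:
                out[c] = out[c] + rng.normal(0.0, sd, size=len(out))
    return out
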
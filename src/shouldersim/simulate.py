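"""Software-in-the-loop trial execution: plant + controller + recording.

A *trial* is one execution of one motion protocol on one virtual specimen:
the plant starts from its passive pretensioned equilibrium, the controller
runs at the plant step rate (default 200 Hz), and a trace is recorded at
the tracking-system rate (default 20 Hz).  Measurement noise (tracker
angles, load cells, translations) is injected into the *measured* process
variables -- the controller acts on what the sensors report, exactly as
the physical rig does -- so repeated trials differ through the noise
stream of their seed.

Humeral-head translations are referenced to the pose at which measured
abduction first crosses 20 deg (the end of the initial muscle-loading
phase), so traces from different trials share a common zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .controller import ThreeLoopController
from .kinematics import CardanXZY
from .motions import MotionProfile, build_profile
from .specimen import (
    DislocationError,
    InstabilityError,
    VirtualSpecimen,
    passive_equilibrium,
)

__all__ = ["TrialTrace", "run_trial", "TRACE_COLUMNS"]

TRACE_COLUMNS = (
    ["time_s", "sp_abd", "sp_fe", "sp_ir", "pv_abd", "pv_fe", "pv_ir",
     "ap_mm", "si_mm", "ml_mm"]
    + ["f_md", "f_ad", "f_pd", "f_ssc", "f_isp_tm", "f_ssp"]
)

#: clean (noise-free, pre-referencing diagnostic) column suffixes
CLEAN_COLUMNS = (
    ["clean_abd", "clean_fe", "clean_ir"]
    + ["cmd_md", "cmd_ad", "cmd_pd", "cmd_ssc", "cmd_isp_tm", "cmd_ssp"]
    + ["total_fe", "total_ir", "share_ad", "share_ssc"]
)


@dataclass
class TrialTrace:
    """Recorded trial data plus metadata.

    ``data`` columns: time, setpoints and measured angles (deg), referenced
    translations (mm), measured muscle forces (N); with
    ``record_clean=True`` also the noise-free angles, commanded forces and
    controller internals used by the invariant checks.
    """

    data: pd.DataFrame
    protocol: str
    specimen_id: str
    repeat: int
    seed: int
    scored_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def scored(self) -> pd.DataFrame:
        return self.data.loc[self.scored_mask]

    def to_csv(self, path) -> None:
        header = dict(
            protocol=self.protocol, specimen_id=self.specimen_id,
            repeat=self.repeat, seed=self.seed, **self.meta,
        )
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps(header)}\n")
            df = self.data.copy()
            df["scored"] = self.scored_mask.astype(int)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialTrace":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
            df = pd.read_csv(fh)
        scored = df.pop("scored").to_numpy(dtype=bool) if "scored" in df else np.ones(len(df), bool)
        return cls(
            data=df,
            protocol=meta.pop("protocol", "unknown"),
            specimen_id=meta.pop("specimen_id", "unknown"),
            repeat=int(meta.pop("repeat", 0)),
            seed=int(meta.pop("seed", 0)),
            scored_mask=scored,
            meta=meta,
        )


def run_trial(
    specimen: VirtualSpecimen,
    profile: MotionProfile | str,
    *,
    repeat: int = 0,
    seed: int = 0,
    noise: bool = True,
    record_hz: float = 20.0,
    tracker_hz: float = 50.0,
    pv_filter_tau_s: float = 0.03,
    record_clean: bool = False,
    controller: ThreeLoopController | None = None,
) -> TrialTrace:
    """Execute one protocol on one specimen.

    Raises :class:`DislocationError` / :class:`InstabilityError` on plant
    failure (the campaign runner records these in its manifest).
    """
    if isinstance(profile, str):
        profile = build_profile(profile)
    dt = profile.dt_s
    n = profile.n_samples
    stride = max(1, int(round(1.0 / (record_hz * dt))))
    # The controller keeps its own run-time never-slack floor (10 N, the
    # lower end of the centering pretension range), independent of the
    # specimen's initial centering tension.
    ctrl = controller if controller is not None else ThreeLoopController()
    ctrl.reset()

    rng = np.random.default_rng(seed)
    sd_a = specimen.noise_angle_deg if noise else 0.0
    sd_f = specimen.noise_force_N if noise else 0.0
    sd_t = specimen.noise_translation_mm if noise else 0.0
    angle_noise = rng.normal(0.0, sd_a, size=(n, 3)) if sd_a > 0 else np.zeros((n, 3))

    sp = profile.sp_deg
    # Per-tick loop roles. Abduction follows its setpoint slope (profile
    # row while ramping, constant row while holding -- the cascade design).
    # A secondary DOF switches to its own activation PID when its ramp
    # starts and keeps it to the end of the trial: reverting to MD-slaved
    # totals while holding a deflected end angle would dump the couple
    # force that holds it.
    dsp = np.abs(np.diff(sp, axis=0, prepend=sp[:1])) > 1e-12
    dsp[:, 1] = np.logical_or.accumulate(dsp[:, 1])
    dsp[:, 2] = np.logical_or.accumulate(dsp[:, 2])
    directions = profile.directions

    q0 = passive_equilibrium(specimen, specimen.pretension_N)
    q = np.radians(q0)
    qd = np.zeros(3)
    ins, gui, mass_pos, masses = specimen._pack()
    K = specimen.capsule_stiffness_Nm_rad
    C = specimen.capsule_damping_Nms_rad
    q_rest = np.radians(specimen.capsule_rest_deg)
    g_dir = specimen.gravity_dir
    I_body = specimen.inertia_kgm2
    k_t = specimen.translation_stiffness_N_mm
    preload = specimen.preload_N
    c_off = specimen.head_center_offset_mm
    geo_ref = specimen.geo_ref_mm
    disl = specimen.dislocation_limit_mm
    vmax = np.radians(specimen.speed_limit_deg_s)

    n_rec = (n + stride - 1) // stride
    rec = np.empty((n_rec, len(TRACE_COLUMNS)))
    rec_clean = np.empty((n_rec, len(CLEAN_COLUMNS))) if record_clean else None
    rec_mask = np.empty(n_rec, dtype=bool)
    i_rec = 0
    raw_translations = np.empty((n_rec, 3))

    cal = specimen.anatomical_cal
    deg = 180.0 / np.pi
    # The optical tracker samples slower than the control loop: the
    # measured angles (and their noise draw) are held between tracker
    # frames, as on the physical rig.  The control path additionally
    # low-passes the measurement (first order, ``pv_filter_tau_s``) --
    # standard conditioning of optical feedback before a PID; at
    # 0.5 deg/s the induced lag is under a tenth of a degree.  Recorded
    # traces keep the raw (noisy, unfiltered) measurements.
    meas_stride = max(1, int(round(1.0 / (tracker_hz * dt))))
    alpha = dt / max(pv_filter_tau_s, dt)
    pv_clean = np.empty(3)
    pv_arr = np.empty(3)
    pv_filt: np.ndarray | None = None
    for i in range(n):
        if i % meas_stride == 0:
            pv_clean = _engine.measured_angles(q, cal) * deg
            pv_arr = pv_clean + angle_noise[i]
        if pv_filt is None:
            pv_filt = pv_arr.copy()
        else:
            pv_filt = pv_filt + alpha * (pv_arr - pv_filt)
        pv = CardanXZY(pv_filt[0], pv_filt[1], pv_filt[2])
        spi = sp[i]
        sp_c = CardanXZY(spi[0], spi[1], spi[2])
        profiled = (bool(dsp[i, 0]), bool(dsp[i, 1]), bool(dsp[i, 2]))
        forces, diag = ctrl.step(sp_c, pv, profiled, directions, dt)

        q, qd = _engine.rk4_step(
            q, qd, forces, dt, ins, gui, mass_pos, masses, g_dir, K, C, q_rest, I_body
        )
        if np.any(np.abs(qd) > vmax):
            raise InstabilityError(
                f"angular speed limit exceeded at t={i * dt:.2f}s "
                f"({np.degrees(np.abs(qd)).max():.0f} deg/s)"
            )

        if i % stride == 0:
            t_mm = _engine.translation_mm(
                q, forces, ins, gui, mass_pos, masses, g_dir, k_t, preload,
                c_off, geo_ref,
            )
            if np.any(np.abs(t_mm) > disl):
                raise DislocationError(
                    f"dislocation at t={i * dt:.2f}s (|t|={np.abs(t_mm).max():.1f} mm)"
                )
            raw_translations[i_rec] = t_mm
            t_noisy = t_mm + (rng.normal(0.0, sd_t, 3) if sd_t > 0 else 0.0)
            f_noisy = forces + (rng.normal(0.0, sd_f, 6) if sd_f > 0 else 0.0)
            rec[i_rec, 0] = i * dt
            rec[i_rec, 1:4] = spi
            rec[i_rec, 4:7] = pv_arr
            rec[i_rec, 7:10] = t_noisy
            rec[i_rec, 10:16] = f_noisy
            rec_mask[i_rec] = profile.scored[i]
            if record_clean:
                rec_clean[i_rec, 0:3] = pv_clean
                rec_clean[i_rec, 3:9] = forces
                rec_clean[i_rec, 9] = diag.total_fe_N
                rec_clean[i_rec, 10] = diag.total_ir_N
                rec_clean[i_rec, 11] = diag.share_ad
                rec_clean[i_rec, 12] = diag.share_ssc
            i_rec += 1

    rec = rec[:i_rec]
    rec_mask = rec_mask[:i_rec]
    # Reference translations at the 20 deg abduction crossing (the end of
    # the initial muscle-loading phase, which every protocol passes
    # through): the reference is the mean over a one-second window after
    # the first measured crossing, not a single noisy instant, so repeats
    # share a common zero.
    crossed = rec[:, 4] >= 20.0
    if crossed.any():
        k = int(np.argmax(crossed))
    else:  # custom protocol below 20 deg abduction: reference scored start
        k = int(np.argmax(rec_mask)) if rec_mask.any() else 0
    win = max(1, int(round(record_hz * 1.0)))
    ref_translation = raw_translations[k : min(k + win, i_rec)].mean(axis=0)
    rec[:, 7:10] -= ref_translation

    df = pd.DataFrame(rec, columns=TRACE_COLUMNS)
    if record_clean:
        df = pd.concat(
            [df, pd.DataFrame(rec_clean[:i_rec], columns=CLEAN_COLUMNS)], axis=1
        )
    return TrialTrace(
        data=df,
        protocol=profile.name,
        specimen_id=specimen.specimen_id,
        repeat=repeat,
        seed=seed,
        scored_mask=rec_mask,
        meta={"dt_s": dt, "record_hz": record_hz, "noise": bool(noise)},
    )
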
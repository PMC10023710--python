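"""Setpoint protocols: five planar motions and one coupled non-planar one.

Each protocol is a time-parameterized Cardan XZY setpoint trajectory with
three phases:

loading
    ramp from the resting posture (~10 deg abduction) to the protocol's
    start configuration; for active abduction this is the 10->20 deg
    muscle-loading phase at the protocol velocity, for the other motions a
    faster pre-positioning ramp.
settle
    a hold (default 10 s) so the constant-mode loops converge before
    scoring starts.
scored
    the evaluated segment, ramping the profiled DOF(s) at the target
    angular velocity (default 0.5 deg/s); secondary setpoints are exactly
    constant.

Profiles can also be described in YAML/JSON for custom ranges/velocities;
the six built-ins reproduce the evaluation protocols bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["MotionProfile", "build_profile", "PROTOCOLS", "load_protocol_file"]

DOFS = ("abduction", "flexion", "rotation")

#: name -> (start angles (abd, F/E, IR/ER), end angles)
_PROTOCOL_TABLE: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "abduction": ((20.0, 0.0, 0.0), (60.0, 0.0, 0.0)),
    "flexion": ((50.0, 0.0, 0.0), (50.0, 30.0, 0.0)),
    "extension": ((50.0, 0.0, 0.0), (50.0, -30.0, 0.0)),
    "internal_rotation": ((30.0, 0.0, 0.0), (30.0, 0.0, 45.0)),
    "external_rotation": ((30.0, 0.0, 0.0), (30.0, 0.0, -45.0)),
    "extension_internal_rotation": ((40.0, 0.0, 0.0), (40.0, -30.0, 30.0)),
}

PROTOCOLS = tuple(_PROTOCOL_TABLE)

RESTING_DEG = (10.0, 0.0, 0.0)


@dataclass(frozen=True)
class MotionProfile:
    """Sampled three-DOF setpoint trajectory for one trial.

    ``sp_deg`` has shape (n, 3); ``profiled`` marks, per DOF, whether the
    scored segment ramps that DOF; ``scored`` is a boolean per-sample mask
    of the scored segment.  ``directions`` is the ramp sign per DOF (0 for
    held DOF).
    """

    name: str
    dt_s: float
    velocity_deg_s: float
    sp_deg: np.ndarray
    profiled: tuple[bool, bool, bool]
    directions: tuple[float, float, float]
    scored: np.ndarray
    repeats: int = 3
    start_deg: tuple[float, float, float] = RESTING_DEG
    end_deg: tuple[float, float, float] = RESTING_DEG

    @property
    def n_samples(self) -> int:
        return self.sp_deg.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt_s

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s


def _ramp(start: np.ndarray, end: np.ndarray, speed: float, dt: float) -> np.ndarray:
    """Piecewise-linear ramp of all DOF at |slope| = speed (per-DOF ramps
    of different lengths finish at their own time; the segment lasts until
    the longest one ends)."""
    deltas = end - start
    dur = np.abs(deltas).max() / speed
    n = int(round(dur / dt))
    t = (np.arange(n) + 1) * dt
    out = np.empty((n, 3))
    for k in range(3):
        sgn = np.sign(deltas[k])
        out[:, k] = start[k] + sgn * np.minimum(speed * t, abs(deltas[k]))
    return out


def build_profile(
    name: str,
    velocity_deg_s: float = 0.5,
    dt_s: float = 0.005,
    *,
    loading_velocity_deg_s: float = 2.0,
    settle_s: float = 10.0,
    tail_s: float = 2.0,
    repeats: int = 3,
    table: dict | None = None,
) -> MotionProfile:
    """Sampled setpoint time series for one protocol.

    The scored segment ramps the profiled DOF(s) at ``velocity_deg_s``
    exactly; active abduction's loading phase (the 10->20 deg initial
    muscle loading) also runs at the protocol velocity, other protocols
    pre-position at ``loading_velocity_deg_s``.
    """
    table = table if table is not None else _PROTOCOL_TABLE
    if name not in table:
        raise ValueError(f"unknown protocol {name!r}; expected one of {sorted(table)}")
    if velocity_deg_s <= 0:
        raise ValueError("velocity must be positive")
    start, end = (np.asarray(v, dtype=float) for v in table[name])
    rest = np.asarray(RESTING_DEG)

    load_speed = velocity_deg_s if name == "abduction" else loading_velocity_deg_s
    loading = _ramp(rest, start, load_speed, dt_s)
    settle = np.tile(start, (int(round(settle_s / dt_s)), 1))
    scored = _ramp(start, end, velocity_deg_s, dt_s)
    tail = np.tile(end, (int(round(tail_s / dt_s)), 1))

    sp = np.vstack([rest[None, :], loading, settle, scored, tail])
    mask = np.zeros(sp.shape[0], dtype=bool)
    i0 = 1 + loading.shape[0] + settle.shape[0]
    mask[i0 : i0 + scored.shape[0]] = True

    deltas = end - start
    profiled = tuple(bool(abs(d) > 1e-12) for d in deltas)
    directions = tuple(float(np.sign(d)) for d in deltas)
    return MotionProfile(
        name=name,
        dt_s=dt_s,
        velocity_deg_s=velocity_deg_s,
        sp_deg=sp,
        profiled=profiled,  # type: ignore[arg-type]
        directions=directions,  # type: ignore[arg-type]
        scored=mask,
        repeats=repeats,
        start_deg=tuple(start),
        end_deg=tuple(end),
    )


def load_protocol_file(path) -> dict:
    """Custom protocol table from YAML/JSON: name -> {start: [a,f,r],
    end: [a,f,r]}; merged over the built-ins."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = dict(_PROTOCOL_TABLE)
    for name, spec in raw.items():
        table[name] = (tuple(map(float, spec["start"])), tuple(map(float, spec["end"])))
    return table
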
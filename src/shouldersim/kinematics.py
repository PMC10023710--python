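"""Glenohumeral kinematics: Cardan XZY angles, poses, and pivot calibration.

Conventions
-----------
Right-handed scapular frame for a right shoulder: X anterior, Y superior,
Z medial.  The humeral frame coincides with the scapular frame in the
reference (hanging) posture; the humeral shaft points along -Y.

Glenohumeral orientation is parameterized by the Cardan XZY sequence

    R = Rx(abduction) @ Rz(flexion) @ Ry(-rotation)

with abduction positive (arm away from the body), flexion positive /
extension negative, and internal rotation positive / external negative.
All three stored angles are clinically signed; because the clinical
positive directions (abduction up, flexion forward, internal rotation
inward) do not form a right-handed triple, the axial rotation enters the
geometric composition with a minus sign.  The XZY order keeps the
singular configuration (flexion = +/-90 deg) far from the operating range
and avoids gimbal lock at the initiation of abduction, where the
ISB-recommended YXY sequence is singular.

Angles are degrees at every public interface; translations are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CardanXZY",
    "Pose",
    "MarkerFrameSample",
    "GimbalLockError",
    "RankDeficiencyError",
    "compose_orientation",
    "decompose_orientation",
    "orthonormalize",
    "estimate_center_of_rotation",
    "relative_pose",
    "read_marker_csv",
    "write_marker_csv",
]

_GIMBAL_TOL = 1e-9


class GimbalLockError(ValueError):
    """Flexion at +/-90 deg: the XZY triple is not unique."""


class RankDeficiencyError(ValueError):
    """Marker motion does not constrain the pivot point."""


@dataclass(frozen=True)
class CardanXZY:
    """Glenohumeral rotations in the Cardan XZY sequence, degrees."""

    abduction_deg: float
    flexion_deg: float
    rotation_deg: float

    def __post_init__(self) -> None:
        for v in (self.abduction_deg, self.flexion_deg, self.rotation_deg):
            if not math.isfinite(v):
                raise ValueError("Cardan angles must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.abduction_deg, self.flexion_deg, self.rotation_deg], dtype=float
        )


@dataclass(frozen=True)
class Pose:
    """Humeral frame expressed in the scapular frame.

    ``translation_mm`` is the AP/SI/ML displacement of the humeral-head
    centre of rotation (X, Y, Z components of the scapular frame).
    """

    orientation: np.ndarray
    translation_mm: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self) -> None:
        R = np.asarray(self.orientation, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("orientation must be 3x3")
        _check_orthonormal(R)
        if t.shape != (3,) or not np.all(np.isfinite(t)):
            raise ValueError("translation must be a finite 3-vector")
        object.__setattr__(self, "orientation", R)
        object.__setattr__(self, "translation_mm", t)

    @property
    def angles(self) -> CardanXZY:
        return decompose_orientation(self.orientation)


@dataclass(frozen=True)
class MarkerFrameSample:
    """One rigid-body pose of a marker cluster at a time stamp."""

    time_s: float
    rotation: np.ndarray
    position_mm: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        p = np.asarray(self.position_mm, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if p.shape != (3,):
            raise ValueError("position must be a 3-vector")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "position_mm", p)


def _check_orthonormal(R: np.ndarray, tol: float = 1e-9) -> None:
    if not np.allclose(R.T @ R, np.eye(3), atol=tol * 10):
        raise ValueError("orientation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("orientation matrix must be proper (det=+1)")


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def compose_orientation(angles: CardanXZY) -> np.ndarray:
    """Direction-cosine matrix R = Rx(abd) @ Rz(flex) @ Ry(-rot).

    The minus sign on the axial angle makes internal rotation positive in
    storage (see module docstring); abduction and flexion are geometric.
    """
    a = math.radians(angles.abduction_deg)
    f = math.radians(angles.flexion_deg)
    r = math.radians(angles.rotation_deg)
    return _rx(a) @ _rz(f) @ _ry(-r)


def decompose_orientation(R: np.ndarray) -> CardanXZY:
    """Unique XZY Cardan triple with flexion in (-90, 90) degrees.

    Raises
    ------
    GimbalLockError
        When flexion is at +/-90 deg (|R[0,1]| within 1e-9 of 1) and the
        abduction/rotation split is no longer unique.
    """
    R = np.asarray(R, dtype=float)
    _check_orthonormal(R)
    # Row 0 of Rz@Ry is [cf*cr, -sf, cf*sr]; column 1 of R is
    # (-sf, ca*cf, sa*cf).
    sf = -R[0, 1]
    if abs(sf) >= 1.0 - _GIMBAL_TOL:
        raise GimbalLockError("flexion at +/-90 deg: XZY decomposition singular")
    f = math.asin(max(-1.0, min(1.0, sf)))
    a = math.atan2(R[2, 1], R[1, 1])
    r = -math.atan2(R[0, 2], R[0, 0])
    return CardanXZY(math.degrees(a), math.degrees(f), math.degrees(r))


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix (polar decomposition via SVD)."""
    U, _, Vt = np.linalg.svd(np.asarray(R, dtype=float))
    Rn = U @ Vt
    if np.linalg.det(Rn) < 0:
        U[:, -1] *= -1.0
        Rn = U @ Vt
    return Rn


def estimate_center_of_rotation(
    samples: Sequence[MarkerFrameSample],
    *,
    min_samples: int = 10,
    cond_limit: float = 1e8,
) -> np.ndarray:
    """Pivot-calibration estimate of the centre of rotation.

    Finds the point fixed in the moving (humeral) cluster frame whose image
    in the fixed (scapular) frame moves least across the recording -- the
    classical linear pivot calibration.  With poses (R_i, t_i) the pivot
    p_h (cluster frame) and its fixed-frame location p_s jointly minimise

        sum_i | R_i p_h + t_i - p_s |^2

    which is the stacked linear system [R_i  -I] (p_h, p_s) = -t_i.  The
    optimal p_s is the mean image of p_h, so this is exactly the
    "least-moving point" criterion.

    Returns the pivot in the fixed frame (p_s, mm).

    Raises
    ------
    RankDeficiencyError
        If fewer than ``min_samples`` poses are given or the motion leaves
        the pivot unconstrained (pure translation, or rotation about a
        single axis, which leaves the pivot ambiguous along that axis).
    """
    if len(samples) < min_samples:
        raise RankDeficiencyError(
            f"need at least {min_samples} samples, got {len(samples)}"
        )
    n = len(samples)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, s in enumerate(samples):
        A[3 * i : 3 * i + 3, :3] = s.rotation
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -s.position_mm
    # The stacked system always has a 3-dim near-null space under pure
    # translation; detect via singular values.
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 6 or sv[0] / sv[-1] > cond_limit:
        raise RankDeficiencyError(
            "marker motion does not constrain the pivot (rank-deficient system)"
        )
    return sol[3:]


def relative_pose(
    humerus: MarkerFrameSample,
    scapula: MarkerFrameSample,
    cor_offsets: "CorOffsets | None" = None,
    *,
    time_tol_s: float = 1e-6,
) -> Pose:
    """Humeral anatomical frame expressed in the scapular anatomical frame.

    ``cor_offsets`` carries the setup calibration: the centre of rotation in
    the humeral cluster frame, the scapular-frame origin offset, and the
    constant cluster-to-anatomical alignment rotations.  The returned
    translation is the COR position in the scapular anatomical frame.
    """
    if abs(humerus.time_s - scapula.time_s) > time_tol_s:
        raise ValueError(
            f"time mismatch: humerus at {humerus.time_s}s, scapula at {scapula.time_s}s"
        )
    off = cor_offsets if cor_offsets is not None else CorOffsets()
    R_s = scapula.rotation @ off.scapula_alignment
    R_h = humerus.rotation @ off.humerus_alignment
    R_rel = R_s.T @ R_h
    cor_world = humerus.rotation @ off.cor_in_humerus_cluster_mm + humerus.position_mm
    origin_world = scapula.rotation @ off.scapula_origin_in_cluster_mm + scapula.position_mm
    t_rel = R_s.T @ (cor_world - origin_world)
    return Pose(orientation=orthonormalize(R_rel), translation_mm=t_rel)


@dataclass(frozen=True)
class CorOffsets:
    """Setup calibration constants for :func:`relative_pose`.

    The scapular axis construction (how the anatomical axes relate to the
    marker-cluster axes, and where the angulus-acromialis origin sits in the
    cluster frame) is deliberately configuration, not hard-coded landmark
    algebra.
    """

    cor_in_humerus_cluster_mm: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    scapula_origin_in_cluster_mm: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    humerus_alignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    scapula_alignment: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "cor_in_humerus_cluster_mm",
            np.asarray(self.cor_in_humerus_cluster_mm, dtype=float),
        )
        object.__setattr__(
            self,
            "scapula_origin_in_cluster_mm",
            np.asarray(self.scapula_origin_in_cluster_mm, dtype=float),
        )
        object.__setattr__(
            self, "humerus_alignment", np.asarray(self.humerus_alignment, dtype=float)
        )
        object.__setattr__(
            self, "scapula_alignment", np.asarray(self.scapula_alignment, dtype=float)
        )


# ---------------------------------------------------------------------------
# CSV interchange: time_s then 12 columns per rigid body (flattened R + t).

_BODY_COLS = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]


def write_marker_csv(path, bodies: dict[str, Sequence[MarkerFrameSample]]) -> None:
    """Write marker recordings; one header row, 12 columns per body."""
    names = list(bodies)
    lengths = {len(v) for v in bodies.values()}
    if len(lengths) != 1:
        raise ValueError("all bodies must have the same number of samples")
    first = names[0]
    data = {"time_s": [s.time_s for s in bodies[first]]}
    for name in names:
        samples = bodies[name]
        for k, col in enumerate(_BODY_COLS):
            if k < 9:
                i, j = divmod(k, 3)
                data[f"{name}_{col}"] = [s.rotation[i, j] for s in samples]
            else:
                data[f"{name}_{col}"] = [s.position_mm[k - 9] for s in samples]
    pd.DataFrame(data).to_csv(path, index=False)


def read_marker_csv(path) -> dict[str, list[MarkerFrameSample]]:
    df = pd.read_csv(path)
    names = sorted({c.rsplit("_", 1)[0] for c in df.columns if c != "time_s"})
    out: dict[str, list[MarkerFrameSample]] = {}
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("time_s must be monotonically increasing")
    for name in names:
        R = df[[f"{name}_r{i}{j}" for i in range(3) for j in range(3)]].to_numpy()
        pos = df[[f"{name}_tx", f"{name}_ty", f"{name}_tz"]].to_numpy()
        out[name] = [
            MarkerFrameSample(t[k], R[k].reshape(3, 3), pos[k]) for k in range(len(df))
        ]
    return out
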
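"""Numerical core of the virtual plant.

Rigid-body rotational dynamics of the humerus (plus forearm-replacement
mass) about the glenohumeral centre of rotation, expressed in the Cardan
XZY generalized coordinates q = (abduction, flexion, rotation) in radians:

    M(q) q'' = E(q)^T tau_world(q, forces) - K (q - q_rest) - C q'

with M = E^T R I_body R^T E the generalized mass matrix, E the map from
Cardan rates to the world angular velocity, tau_world the sum of muscle
cable torques and gravity, and diagonal passive capsule stiffness/damping.
Velocity-product (Coriolis) terms are neglected: the simulator runs
quasi-statically at 0.5 deg/s, where they are many orders of magnitude
below the applied torques.  Integration is fixed-step classical RK4 with
muscle forces held over the step (zero-order hold from the controller).

Every function here is compiled with numba when available and runs as
plain Python/numpy otherwise (identical source).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


G_M_S2 = 9.81


@njit(cache=True)
def rot_xzy(a: float, f: float, r: float) -> np.ndarray:
    """R = Rx(a) @ Rz(f) @ Ry(-r), angles in radians.

    ``r`` is the clinically signed axial rotation (internal positive),
    hence the negated geometric Y angle.
    """
    ca, sa = math.cos(a), math.sin(a)
    cf, sf = math.cos(f), math.sin(f)
    cr, sr = math.cos(r), -math.sin(r)
    R = np.empty((3, 3))
    R[0, 0] = cf * cr
    R[0, 1] = -sf
    R[0, 2] = cf * sr
    R[1, 0] = ca * sf * cr + sa * sr
    R[1, 1] = ca * cf
    R[1, 2] = ca * sf * sr - sa * cr
    R[2, 0] = sa * sf * cr - ca * sr
    R[2, 1] = sa * cf
    R[2, 2] = sa * sf * sr + ca * cr
    return R


@njit(cache=True)
def rate_map(a: float, f: float) -> np.ndarray:
    """E(q): world angular velocity = E @ (da, df, dr).

    Columns are the world-frame axes of the three Cardan rates; the third
    column is negated because the stored axial rotation is clinically
    signed (internal positive = negative geometric Y angle).
    """
    ca, sa = math.cos(a), math.sin(a)
    cf, sf = math.cos(f), math.sin(f)
    E = np.empty((3, 3))
    E[0, 0] = 1.0
    E[0, 1] = 0.0
    E[0, 2] = sf
    E[1, 0] = 0.0
    E[1, 1] = -sa
    E[1, 2] = -ca * cf
    E[2, 0] = 0.0
    E[2, 1] = ca
    E[2, 2] = -sa * cf
    return E


@njit(cache=True)
def measured_angles(q: np.ndarray, cal: np.ndarray) -> np.ndarray:
    """Anatomical Cardan XZY angles (radians, clinical signs) of the
    calibrated humeral frame R(q) @ cal.

    ``cal`` is the constant cluster-to-anatomical alignment fixed during
    specimen setup so the resting (hanging) posture reads zero flexion and
    axial rotation -- mirroring how the epicondylar axis is digitised with
    the arm at rest on the physical rig.
    """
    R = rot_xzy(q[0], q[1], q[2]) @ cal
    sf = -R[0, 1]
    if sf > 1.0:
        sf = 1.0
    elif sf < -1.0:
        sf = -1.0
    out = np.empty(3)
    out[0] = math.atan2(R[2, 1], R[1, 1])
    out[1] = math.asin(sf)
    out[2] = -math.atan2(R[0, 2], R[0, 0])
    return out


@njit(cache=True)
def world_loads(
    q: np.ndarray,
    forces: np.ndarray,
    insertions: np.ndarray,
    guides: np.ndarray,
    mass_pos: np.ndarray,
    masses: np.ndarray,
    g_dir: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Net world torque about the COR and net force on the joint.

    Muscle cables pull from their (rotated) humeral insertion toward their
    fixed scapular guide; gravity acts at the humeral mass points.
    """
    R = rot_xzy(q[0], q[1], q[2])
    tau = np.zeros(3)
    fnet = np.zeros(3)
    for i in range(insertions.shape[0]):
        p = R @ insertions[i]
        d = guides[i] - p
        dn = math.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        fi = forces[i] / dn
        fx, fy, fz = fi * d[0], fi * d[1], fi * d[2]
        tau[0] += p[1] * fz - p[2] * fy
        tau[1] += p[2] * fx - p[0] * fz
        tau[2] += p[0] * fy - p[1] * fx
        fnet[0] += fx
        fnet[1] += fy
        fnet[2] += fz
    for j in range(mass_pos.shape[0]):
        c = R @ mass_pos[j]
        w = masses[j] * G_M_S2
        gx, gy, gz = w * g_dir[0], w * g_dir[1], w * g_dir[2]
        tau[0] += c[1] * gz - c[2] * gy
        tau[1] += c[2] * gx - c[0] * gz
        tau[2] += c[0] * gy - c[1] * gx
        fnet[0] += gx
        fnet[1] += gy
        fnet[2] += gz
    return tau, fnet


@njit(cache=True)
def generalized_torque(
    q: np.ndarray,
    qd: np.ndarray,
    forces: np.ndarray,
    insertions: np.ndarray,
    guides: np.ndarray,
    mass_pos: np.ndarray,
    masses: np.ndarray,
    g_dir: np.ndarray,
    K: np.ndarray,
    C: np.ndarray,
    q_rest: np.ndarray,
) -> np.ndarray:
    tau, _ = world_loads(q, forces, insertions, guides, mass_pos, masses, g_dir)
    E = rate_map(q[0], q[1])
    Q = E.T @ tau
    for k in range(3):
        Q[k] += -K[k] * (q[k] - q_rest[k]) - C[k] * qd[k]
    return Q


@njit(cache=True)
def _qdd(
    q, qd, forces, insertions, guides, mass_pos, masses, g_dir, K, C, q_rest, I_body
):
    tau, _ = world_loads(q, forces, insertions, guides, mass_pos, masses, g_dir)
    R = rot_xzy(q[0], q[1], q[2])
    E = rate_map(q[0], q[1])
    Q = E.T @ tau
    for k in range(3):
        Q[k] += -K[k] * (q[k] - q_rest[k]) - C[k] * qd[k]
    # M = E^T (R diag(I_body) R^T) E  + tiny regularization
    RI = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            RI[i, j] = R[i, j] * I_body[j]
    Iw = RI @ R.T
    M = E.T @ Iw @ E
    for k in range(3):
        M[k, k] += 1e-12
    return np.linalg.solve(M, Q)


@njit(cache=True)
def rk4_step(
    q: np.ndarray,
    qd: np.ndarray,
    forces: np.ndarray,
    dt: float,
    insertions: np.ndarray,
    guides: np.ndarray,
    mass_pos: np.ndarray,
    masses: np.ndarray,
    g_dir: np.ndarray,
    K: np.ndarray,
    C: np.ndarray,
    q_rest: np.ndarray,
    I_body: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step RK4 on (q, q') with forces held constant."""
    a1 = _qdd(q, qd, forces, insertions, guides, mass_pos, masses, g_dir, K, C, q_rest, I_body)
    q2 = q + 0.5 * dt * qd
    qd2 = qd + 0.5 * dt * a1
    a2 = _qdd(q2, qd2, forces, insertions, guides, mass_pos, masses, g_dir, K, C, q_rest, I_body)
    q3 = q + 0.5 * dt * qd2
    qd3 = qd + 0.5 * dt * a2
    a3 = _qdd(q3, qd3, forces, insertions, guides, mass_pos, masses, g_dir, K, C, q_rest, I_body)
    q4 = q + dt * qd3
    qd4 = qd + dt * a3
    a4 = _qdd(q4, qd4, forces, insertions, guides, mass_pos, masses, g_dir, K, C, q_rest, I_body)
    q_new = q + (dt / 6.0) * (qd + 2.0 * qd2 + 2.0 * qd3 + qd4)
    qd_new = qd + (dt / 6.0) * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
    return q_new, qd_new


@njit(cache=True)
def translation_mm(
    q: np.ndarray,
    forces: np.ndarray,
    insertions: np.ndarray,
    guides: np.ndarray,
    mass_pos: np.ndarray,
    masses: np.ndarray,
    g_dir: np.ndarray,
    k_t: np.ndarray,
    f_preload: np.ndarray,
    c_off_mm: np.ndarray,
    geo_ref_mm: np.ndarray,
) -> np.ndarray:
    """Humeral-head centre translation: geometric arc + elastic shear.

    Two contributions: (1) the anatomical head centre sits ``c_off_mm``
    away from the kinematic centre of rotation (humeral frame), so it
    sweeps an arc with orientation, measured from its resting position
    ``geo_ref_mm``; (2) the head displaces elastically along the net joint
    load in excess of the centering preload ``f_preload``, with per-axis
    stiffness k_t (N/mm).  Both vanish at the pretensioned resting state.
    """
    _, fnet = world_loads(q, forces, insertions, guides, mass_pos, masses, g_dir)
    R = rot_xzy(q[0], q[1], q[2])
    arc = R @ c_off_mm
    t = np.empty(3)
    for k in range(3):
        t[k] = arc[k] - geo_ref_mm[k] + (fnet[k] - f_preload[k]) / k_t[k]
    return t
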
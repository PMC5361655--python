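"""Hill-type muscle–tendon units and their joint-path geometry.

Nine muscle groups per leg actuate hip, knee and ankle in the sagittal
plane: hip flexors (HFL), glutei (GLU), hamstrings (HAM), rectus femoris
(RF), vasti (VAS), biceps femoris short head (BFSH), gastrocnemius (GAS),
soleus (SOL) and tibialis anterior (TA).  Each unit is a contractile
element (CE) with force–length and force–velocity relations in series with
a quadratic-stiffness tendon, plus parallel elasticity limiting CE stretch
and compression.

Joint angle conventions: hip flexion positive, knee flexion positive
(0 = straight), ankle dorsiflexion positive (0 = sole perpendicular to the
shank).  Muscle shortening velocity is positive.  The MTU length changes
with joint angle either through a constant moment arm (hip paths) or a
cosine-varying arm ``r(phi) = r0 * cos(phi - phi_max)`` (knee/ankle paths);
in both cases the signed moment arm equals ``d(l_mtu)/d(phi)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "MUSCLES", "MuscleTendonUnit", "default_muscles", "muscle_table",
    "muscle_force", "mtu_length", "mtu_moment_arm", "mtu_kinematics",
    "force_length", "force_velocity", "force_velocity_inverse",
    "tendon_force", "parallel_force",
]

MUSCLES = ("HFL", "GLU", "HAM", "RF", "VAS", "BFSH", "GAS", "SOL", "TA")

# CE shape constants (dimensionless)
W_FL = 0.56          # force-length width
C_FL = np.log(0.05)  # force-length residual at l = l_opt*(1 +/- W_FL)
N_ECC = 1.5          # eccentric force-velocity plateau
K_FV = 5.0           # force-velocity curvature
EPS_REF = 0.04       # tendon strain at F_max

JOINT_HIP, JOINT_KNEE, JOINT_ANKLE = 0, 1, 2
ARM_CONST, ARM_COS = 0, 1


@dataclass
class MusclePath:
    """One joint spanned by an MTU."""

    joint: int          # JOINT_HIP / JOINT_KNEE / JOINT_ANKLE
    arm_type: int       # ARM_CONST or ARM_COS
    r0: float           # peak moment arm [m]
    phi_max: float      # angle of peak arm [rad] (cosine arms)
    phi_ref: float      # angle at which the path contributes zero stretch [rad]
    rho: float          # fiber-to-joint excursion ratio
    sign: float         # +1 if increasing phi lengthens the MTU


@dataclass
class MuscleTendonUnit:
    """Constants of one Hill-type actuator."""

    name: str
    f_max: float        # maximum isometric force [N]
    l_opt: float        # optimum CE length [m]
    v_max: float        # maximum shortening velocity [l_opt/s]
    l_slack: float      # tendon slack length [m]
    paths: tuple        # MusclePath per spanned joint
    delay: float        # afferent transport delay [s]

    def __post_init__(self):
        if self.f_max <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ValueError(f"{self.name}: F_max, l_opt, v_max must be positive")


def default_muscles(body_scale: float = 1.0, mass_scale: float = 1.0) -> list:
    """Nine-muscle table for one leg.

    ``body_scale`` multiplies all lengths and moment arms (height / 1.80 m);
    ``mass_scale`` multiplies forces (mass / 80 kg).  Delays: long (20 ms)
    for ankle muscles, medium (10 ms) for knee/thigh, short (5 ms) for hip.
    """
    s, f = body_scale, mass_scale
    d_long, d_med, d_short = 0.020, 0.010, 0.005

    def P(joint, arm, r0, phi_max, phi_ref, rho, sign):
        return MusclePath(joint, arm, r0 * s, phi_max, phi_ref, rho, sign)

    return [
        MuscleTendonUnit("HFL", 2000 * f, 0.11 * s, 12, 0.10 * s,
                         (P(JOINT_HIP, ARM_CONST, 0.10, 0.0, 0.35, 0.5, -1),),
                         d_short),
        MuscleTendonUnit("GLU", 1500 * f, 0.11 * s, 12, 0.13 * s,
                         (P(JOINT_HIP, ARM_CONST, 0.10, 0.0, 0.35, 0.5, +1),),
                         d_short),
        MuscleTendonUnit("HAM", 3000 * f, 0.10 * s, 12, 0.31 * s,
                         (P(JOINT_HIP, ARM_CONST, 0.08, 0.0, 0.35, 0.5, +1),
                          P(JOINT_KNEE, ARM_CONST, 0.05, 0.0, 0.30, 0.5, -1)),
                         d_med),
        MuscleTendonUnit("RF", 1200 * f, 0.08 * s, 12, 0.35 * s,
                         (P(JOINT_HIP, ARM_CONST, 0.08, 0.0, 0.35, 0.3, -1),
                          P(JOINT_KNEE, ARM_COS, 0.06, 0.26, 1.05, 0.5, +1)),
                         d_med),
        MuscleTendonUnit("VAS", 6000 * f, 0.08 * s, 12, 0.23 * s,
                         (P(JOINT_KNEE, ARM_COS, 0.06, 0.26, 1.05, 0.6, +1),),
                         d_med),
        MuscleTendonUnit("BFSH", 350 * f, 0.12 * s, 12, 0.10 * s,
                         (P(JOINT_KNEE, ARM_CONST, 0.04, 0.0, 0.30, 0.7, -1),),
                         d_med),
        MuscleTendonUnit("GAS", 1500 * f, 0.05 * s, 12, 0.40 * s,
                         (P(JOINT_KNEE, ARM_COS, 0.05, 0.70, 0.30, 0.7, -1),
                          P(JOINT_ANKLE, ARM_COS, 0.05, -0.35, 0.17, 0.7, +1)),
                         d_long),
        MuscleTendonUnit("SOL", 4000 * f, 0.04 * s, 6, 0.26 * s,
                         (P(JOINT_ANKLE, ARM_COS, 0.05, -0.35, 0.17, 0.5, +1),),
                         d_long),
        MuscleTendonUnit("TA", 800 * f, 0.06 * s, 12, 0.24 * s,
                         (P(JOINT_ANKLE, ARM_COS, 0.04, 0.17, -0.35, 0.7, -1),),
                         d_long),
    ]


def muscle_table(muscles: list) -> dict:
    """Pack MTU constants into flat arrays for the simulation kernel."""
    n = len(muscles)
    out = {
        "f_max": np.array([m.f_max for m in muscles]),
        "l_opt": np.array([m.l_opt for m in muscles]),
        "v_max": np.array([float(m.v_max) for m in muscles]),
        "l_slack": np.array([m.l_slack for m in muscles]),
        "delay": np.array([m.delay for m in muscles]),
        "n_paths": np.array([len(m.paths) for m in muscles], dtype=np.int64),
        "joint": np.zeros((n, 2), dtype=np.int64),
        "arm_type": np.zeros((n, 2), dtype=np.int64),
        "r0": np.zeros((n, 2)),
        "phi_max": np.zeros((n, 2)),
        "phi_ref": np.zeros((n, 2)),
        "rho": np.zeros((n, 2)),
        "sign": np.zeros((n, 2)),
    }
    for i, m in enumerate(muscles):
        for j, p in enumerate(m.paths):
            out["joint"][i, j] = p.joint
            out["arm_type"][i, j] = p.arm_type
            out["r0"][i, j] = p.r0
            out["phi_max"][i, j] = p.phi_max
            out["phi_ref"][i, j] = p.phi_ref
            out["rho"][i, j] = p.rho
            out["sign"][i, j] = p.sign
    return out


# ---------------------------------------------------------------------------
# CE / tendon relations (kernel-compatible scalar functions)
# ---------------------------------------------------------------------------

@njit(cache=True)
def force_length(l_ce: float, l_opt: float) -> float:
    """Bell-shaped active force-length factor, peak 1 at l_opt."""
    x = abs((l_ce - l_opt) / (l_opt * W_FL))
    return np.exp(C_FL * x * x * x)


@njit(cache=True)
def force_velocity(v_ce: float, v_max: float) -> float:
    """Hill force-velocity factor; v_ce positive = shortening [l_opt/s].

    Zero at maximal shortening ``v_ce = v_max``, one at isometric, saturating
    at ``N_ECC`` for fast lengthening.
    """
    if v_ce >= 0.0:
        if v_ce > v_max:
            return 0.0
        return (v_max - v_ce) / (v_max + K_FV * v_ce)
    v = v_ce  # negative: lengthening branch, saturates toward N_ECC
    return N_ECC + (N_ECC - 1.0) * (v_max + v) / (7.56 * K_FV * v - v_max)


@njit(cache=True)
def force_velocity_inverse(fv: float, v_max: float) -> float:
    """Invert the force-velocity relation: factor -> v_ce (shortening +)."""
    if fv <= 0.0:
        return v_max
    if fv < 1.0:
        return v_max * (1.0 - fv) / (1.0 + K_FV * fv)
    f = fv
    if f > N_ECC - 1e-3:
        f = N_ECC - 1e-3
    return v_max * (f - 1.0) / (7.56 * K_FV * (f - N_ECC) - (N_ECC - 1.0))


@njit(cache=True)
def tendon_force(l_se: float, l_slack: float, f_max: float) -> float:
    """Series-elastic force: quadratic in strain, F_max at strain EPS_REF."""
    eps = (l_se - l_slack) / l_slack
    if eps <= 0.0:
        return 0.0
    r = eps / EPS_REF
    return f_max * r * r


@njit(cache=True)
def parallel_force(l_ce: float, l_opt: float, f_max: float) -> float:
    """Parallel elasticity: resists stretch beyond l_opt, compression below
    (1 - W_FL) * l_opt (returned negative)."""
    if l_ce > l_opt:
        x = (l_ce - l_opt) / (l_opt * W_FL)
        return f_max * x * x
    low = l_opt * (1.0 - W_FL)
    if l_ce < low:
        x = (low - l_ce) / (0.5 * l_opt * W_FL)
        return -f_max * x * x
    return 0.0


def muscle_force(activation: float, l_ce: float, v_ce: float,
                 mtu: MuscleTendonUnit) -> float:
    """Active CE force ``a * F_max * f_l(l_ce) * f_v(v_ce)`` (plus passive).

    ``v_ce`` in l_opt/s, shortening positive.  Inputs outside physical
    ranges are clamped.  The returned force is the CE force transmitted to
    the tendon, never negative.
    """
    a = min(max(float(activation), 0.0), 1.0)
    l = max(float(l_ce), 0.0)
    active = a * mtu.f_max * force_length(l, mtu.l_opt) * force_velocity(
        float(v_ce), float(mtu.v_max))
    total = active + parallel_force(l, mtu.l_opt, mtu.f_max)
    return max(total, 0.0)


# ---------------------------------------------------------------------------
# MTU path geometry
# ---------------------------------------------------------------------------

def _path_dl(p: MusclePath, phi: float) -> float:
    if p.arm_type == ARM_CONST:
        return p.sign * p.rho * p.r0 * (phi - p.phi_ref)
    return p.sign * p.rho * p.r0 * (
        np.sin(phi - p.phi_max) - np.sin(p.phi_ref - p.phi_max))


def _path_arm(p: MusclePath, phi: float) -> float:
    if p.arm_type == ARM_CONST:
        return p.sign * p.rho * p.r0
    return p.sign * p.rho * p.r0 * np.cos(phi - p.phi_max)


def mtu_length(mtu: MuscleTendonUnit, joint_angles) -> float:
    """Total MTU length at the given (hip, knee, ankle) angles [rad]."""
    l = mtu.l_opt + mtu.l_slack
    for p in mtu.paths:
        l += _path_dl(p, joint_angles[p.joint])
    return l


def mtu_moment_arm(mtu: MuscleTendonUnit, joint: int, joint_angles) -> float:
    """Signed d(l_mtu)/d(phi_joint); zero if the MTU does not span the joint."""
    arm = 0.0
    for p in mtu.paths:
        if p.joint == joint:
            arm += _path_arm(p, joint_angles[p.joint])
    return arm


def mtu_kinematics(mtu: MuscleTendonUnit, joint_angles, joint_velocities):
    """MTU length [m] and lengthening velocity [m/s] from joint state."""
    l = mtu_length(mtu, joint_angles)
    v = 0.0
    for p in mtu.paths:
        v += _path_arm(p, joint_angles[p.joint]) * joint_velocities[p.joint]
    return l, v
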
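"""Anthropometric scaling of the sagittal-plane walker.

Segment lengths scale linearly with body height and segment masses linearly
with body mass, using standard regression fractions from gait-analysis
anthropometry tables (segment mass fractions, center-of-mass locations and
radii of gyration of the foot, shank, thigh and head-arms-trunk segment).
Moments of inertia scale as ``mass * (rho * length)**2`` with the tabulated
radius-of-gyration fraction ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "Joint", "BodyModel", "scale_anthropometry"]

G = 9.81

# mass fraction of total body mass, length fraction of height,
# CoM fraction of segment length (from proximal end), radius of gyration
# fraction of segment length (about CoM)
_SEGMENTS = {
    #            mass_frac  len_frac  com_frac  rho
    "hat":     (0.678,     0.470,    0.374,    0.496),
    "thigh":   (0.100,     0.245,    0.433,    0.323),
    "shank":   (0.0465,    0.246,    0.433,    0.302),
    "foot":    (0.0145,    0.152,    0.500,    0.475),
}

# foot geometry fractions of foot length: heel behind ankle, ball ahead of
# ankle, sole depth below the ankle joint
_FOOT_HEEL_FRAC = 0.30
_FOOT_BALL_FRAC = 0.70
_FOOT_HEIGHT_FRAC = 0.26

# joint rotation limits [rad]: hip flexion +, knee flexion +, dorsiflexion +
_JOINT_LIMITS = {
    "hip": (-0.9, 2.0),
    "knee": (0.0, 2.6),
    "ankle": (-1.2, 0.8),
}
_SOFT_LIMIT_STIFFNESS = 300.0   # N m / rad beyond the limit
_SOFT_LIMIT_DAMPING = 30.0      # N m s / rad while beyond the limit


@dataclass
class Segment:
    name: str
    mass: float       # kg
    length: float     # m
    com_offset: float  # m from proximal end along the segment
    inertia: float    # kg m^2 about the CoM


@dataclass
class Joint:
    name: str
    lower: float
    upper: float
    stiffness: float = _SOFT_LIMIT_STIFFNESS
    damping: float = _SOFT_LIMIT_DAMPING


@dataclass
class BodyModel:
    """Segment/joint description of the sagittal walker (one side mirrored)."""

    height: float
    mass: float
    segments: dict = field(default_factory=dict)
    joints: dict = field(default_factory=dict)
    foot_heel: float = 0.0    # m behind the ankle
    foot_ball: float = 0.0    # m ahead of the ankle
    foot_height: float = 0.0  # ankle height above the sole

    def __post_init__(self):
        if self.segments:
            self._check()

    def _check(self):
        total = self.segments["hat"].mass + 2 * sum(
            self.segments[s].mass for s in ("thigh", "shank", "foot")
        )
        if abs(total - self.mass) > 1e-9:
            raise ValueError(
                f"segment masses sum to {total:.12g} kg, expected {self.mass:.12g}"
            )
        for seg in self.segments.values():
            if seg.mass <= 0 or seg.length <= 0 or seg.inertia <= 0:
                raise ValueError(f"non-positive property in segment {seg.name}")
        for j in self.joints.values():
            if not j.lower < j.upper:
                raise ValueError(f"joint {j.name} limits not ordered")

    @property
    def leg_length(self) -> float:
        return (self.segments["thigh"].length + self.segments["shank"].length
                + self.foot_height)

    @property
    def standing_hip_height(self) -> float:
        return self.leg_length

    @property
    def weight(self) -> float:
        return self.mass * G


def scale_anthropometry(height: float, mass: float) -> BodyModel:
    """Build a :class:`BodyModel` scaled to subject height [m] and mass [kg].

    Lengths are proportional to height; masses and inertias follow standard
    anthropometric fractions of total mass.  The mass fractions are
    renormalized so that the head-arms-trunk segment absorbs the rounding
    residual and segment masses sum exactly to total mass.
    """
    if not (1.4 <= height <= 2.2):
        raise ValueError(f"height {height} m outside supported range [1.4, 2.2]")
    if not (40.0 <= mass <= 120.0):
        raise ValueError(f"mass {mass} kg outside supported range [40, 120]")

    segments = {}
    for name, (mf, lf, cf, rho) in _SEGMENTS.items():
        m = mf * mass
        length = lf * height
        segments[name] = Segment(name, m, length, cf * length, m * (rho * length) ** 2)
    # exact mass bookkeeping: residual into the HAT segment
    limb = 2 * sum(segments[s].mass for s in ("thigh", "shank", "foot"))
    hat = segments["hat"]
    hat_mass = mass - limb
    segments["hat"] = Segment("hat", hat_mass, hat.length,
                              hat.com_offset,
                              hat_mass * (_SEGMENTS["hat"][3] * hat.length) ** 2)

    joints = {n: Joint(n, lo, hi) for n, (lo, hi) in _JOINT_LIMITS.items()}
    foot_len = segments["foot"].length
    return BodyModel(
        height=height,
        mass=mass,
        segments=segments,
        joints=joints,
        foot_heel=_FOOT_HEEL_FRAC * foot_len,
        foot_ball=_FOOT_BALL_FRAC * foot_len,
        foot_height=_FOOT_HEIGHT_FRAC * foot_len,
    )
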
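"""Phase-gated spinal reflex network: parameters, gait events, delay buffers.

The controller maps *delayed* afferent signals (normalized muscle force,
CE length and CE shortening velocity, trunk lean and leg load) to muscle
stimulations through phase-gated reflex pathways:

* stance: positive force feedback of the ankle extensors (SOL, GAS) and of
  VAS; a TA stretch reflex inhibited by SOL force; trunk-balance PD pathways
  driving GLU/HAM/HFL scaled by the leg's load share; double-support
  modulation that inhibits VAS and GLU and boosts HFL to initiate swing.
* swing: an HFL stretch reflex (with lean-dependent bias) opposed by HAM
  stretch, HAM/GLU force feedback braking the leg in late swing, the TA
  stretch reflex holding the foot, a BFSH stretch reflex flexing the knee,
  and normally-silent late-swing VAS/GAS pathways.

The stance SOL pathway carries *no velocity-afferent weight* — soleus
stance stimulation is pure delayed force feedback.  Stimulations are
clamped to [0.01, 1]; stance/swing laws are cross-faded over a short
window at contact transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import NPARAM, _stimulations

__all__ = [
    "PARAM_NAMES", "DEFAULT_PARAMS", "ReflexParameters", "GaitPhaseState",
    "detect_gait_events", "compute_stimulations", "delay_buffer_read",
]

PARAM_NAMES = (
    "G_SOL",        # SOL stance force-feedback gain
    "G_TA",         # TA stretch-reflex gain
    "loff_TA",      # TA stretch threshold [l_opt]
    "GS_TA",        # SOL-force inhibition of TA
    "G_GAS",        # GAS stance force-feedback gain
    "G_VAS",        # VAS stance force-feedback gain
    "loff_knee",    # VAS-length proxy for knee-extension inhibition [l_opt]
    "k_knee",       # knee-overextension inhibition gain
    "S0_VAS",       # VAS stance pre-stimulation
    "kp_trunk",     # trunk-balance proportional gain [1/rad]
    "kd_trunk",     # trunk-balance derivative gain [s/rad]
    "theta_ref",    # trunk forward-lean reference [rad]
    "kHAM_tr",      # HAM share of the balance signal
    "kHFL_tr",      # HFL share of the (negated) balance signal
    "dS_HFL",       # double-support HFL boost (swing initiation)
    "dS_GLU",       # double-support GLU suppression
    "S0_HFL_sw",    # HFL swing pre-stimulation
    "G_HFL",        # HFL swing stretch gain
    "loff_HFL",     # HFL stretch threshold [l_opt]
    "GHAM_HFL",     # HAM-stretch inhibition of HFL
    "loff_HAM",     # HAM stretch threshold [l_opt]
    "k_lean",       # lean-proportional HFL bias at swing
    "GHAM_sw",      # HAM swing force-feedback gain (leg braking)
    "kGLU_HAM",     # GLU swing gain on HAM force
    "G_BFSH",       # BFSH stretch gain (swing knee flexion)
    "loff_BFSH",    # BFSH stretch threshold [l_opt]
    "GVAS_lsw",     # late-swing VAS pathway gain (silent in normal gait)
    "loff_VAS_lsw",
    "GGAS_lsw",     # late-swing GAS pathway gain (silent in normal gait)
    "S0_GLU",       # GLU stance pre-stimulation
    "S0_HAM",       # HAM stance pre-stimulation
    "kDS_VAS",      # double-support VAS inhibition
)
assert len(PARAM_NAMES) == NPARAM

DEFAULT_PARAMS = {
    "G_SOL": 1.2, "G_TA": 1.1, "loff_TA": 0.71, "GS_TA": 0.3,
    "G_GAS": 1.1, "G_VAS": 1.15, "loff_knee": 0.95, "k_knee": 4.0,
    "S0_VAS": 0.09, "kp_trunk": 1.0, "kd_trunk": 0.25, "theta_ref": 0.105,
    "kHAM_tr": 0.5, "kHFL_tr": 1.0, "dS_HFL": 0.25, "dS_GLU": 0.25,
    "S0_HFL_sw": 0.01, "G_HFL": 0.35, "loff_HFL": 0.6, "GHAM_HFL": 4.0,
    "loff_HAM": 0.85, "k_lean": 1.15, "GHAM_sw": 0.25, "kGLU_HAM": 0.3,
    "G_BFSH": 2.0, "loff_BFSH": 1.05, "GVAS_lsw": 0.0, "loff_VAS_lsw": 1.0,
    "GGAS_lsw": 0.0, "S0_GLU": 0.05, "S0_HAM": 0.05, "kDS_VAS": 1.0,
}

# bounds used by the optimizer (name -> (lo, hi))
PARAM_BOUNDS = {
    "G_SOL": (0.5, 1.6), "G_TA": (0.1, 3.0), "loff_TA": (0.4, 1.1),
    "GS_TA": (0.0, 2.0), "G_GAS": (0.5, 1.2), "G_VAS": (0.2, 2.5),
    "loff_knee": (0.7, 1.2), "k_knee": (0.0, 10.0), "S0_VAS": (0.01, 0.4),
    "kp_trunk": (0.1, 5.0), "kd_trunk": (0.02, 1.0), "theta_ref": (0.0, 0.3),
    "kHAM_tr": (0.0, 2.0), "kHFL_tr": (0.0, 4.0), "dS_HFL": (0.0, 0.8),
    "dS_GLU": (0.0, 0.8), "S0_HFL_sw": (0.01, 0.4), "G_HFL": (0.0, 2.0),
    "loff_HFL": (0.3, 1.1), "GHAM_HFL": (0.0, 10.0), "loff_HAM": (0.5, 1.2),
    "k_lean": (0.0, 4.0), "GHAM_sw": (0.0, 2.0), "kGLU_HAM": (0.0, 2.0),
    "G_BFSH": (0.0, 6.0), "loff_BFSH": (0.7, 1.3), "GVAS_lsw": (0.0, 2.0),
    "loff_VAS_lsw": (0.7, 1.3), "GGAS_lsw": (0.0, 2.0),
    "S0_GLU": (0.01, 0.4), "S0_HAM": (0.01, 0.4), "kDS_VAS": (0.0, 4.0),
}


@dataclass
class ReflexParameters:
    """Named reflex gain/offset/threshold vector.

    Serializes to a flat name-value text table so optimized sets are
    diffable; the kernel consumes :meth:`vector`.
    """

    values: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self):
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown reflex parameters: {sorted(unknown)}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.values)
        self.values = merged

    def vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, v) -> "ReflexParameters":
        v = np.asarray(v, dtype=float)
        if v.size != NPARAM:
            raise ValueError(f"expected {NPARAM} parameters, got {v.size}")
        return cls({n: float(x) for n, x in zip(PARAM_NAMES, v)})

    def save(self, path):
        # full float precision: walking trajectories are chaotic, so a
        # parameter file must round-trip bit-exactly to reproduce a gait
        with open(path, "w") as fh:
            for n in PARAM_NAMES:
                fh.write(f"{n} {self.values[n]:.17g}\n")

    @classmethod
    def load(cls, path) -> "ReflexParameters":
        vals = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, val = line.split()
                vals[name] = float(val)
        return cls(vals)


@dataclass
class GaitPhaseState:
    """Per-leg gait phase bookkeeping derived from contact events."""

    stance: np.ndarray          # bool per leg
    t_heel_strike: np.ndarray   # last heel strike per leg [s]
    t_toe_off: np.ndarray       # last toe off per leg [s]
    stride_period: np.ndarray   # last completed stride period per leg [s]
    stride_fraction: np.ndarray  # in [0, 1)

    @classmethod
    def empty(cls):
        return cls(np.zeros(2, dtype=bool), np.full(2, np.nan),
                   np.full(2, np.nan), np.full(2, np.nan), np.zeros(2))


def detect_gait_events(t: np.ndarray, contact: np.ndarray,
                       min_dwell: float = 0.0):
    """Heel-strike and toe-off times from a per-leg contact indicator.

    ``contact`` is (n, 2) boolean (or load > threshold).  Heel strike is a
    swing-to-contact transition, toe off a contact release; transitions
    shorter than ``min_dwell`` are ignored.  Returns
    ``(heel_strikes, toe_offs)`` as lists of arrays per leg, timestamped on
    the input grid, plus the final :class:`GaitPhaseState`.
    """
    t = np.asarray(t, float)
    contact = np.asarray(contact, bool)
    if contact.ndim != 2 or contact.shape[1] != 2:
        raise ValueError("contact must be (n, 2)")
    hs, to = [], []
    state = GaitPhaseState.empty()
    for leg in range(2):
        c = contact[:, leg]
        hs_leg, to_leg = [], []
        last_switch = -np.inf
        cur = bool(c[0])
        for i in range(1, c.size):
            if bool(c[i]) != cur and (t[i] - last_switch) >= min_dwell:
                cur = bool(c[i])
                last_switch = t[i]
                if cur:
                    if hs_leg:
                        state.stride_period[leg] = t[i] - hs_leg[-1]
                    hs_leg.append(t[i])
                else:
                    to_leg.append(t[i])
        hs.append(np.asarray(hs_leg))
        to.append(np.asarray(to_leg))
        state.stance[leg] = cur
        if hs_leg:
            state.t_heel_strike[leg] = hs_leg[-1]
        if to_leg:
            state.t_toe_off[leg] = to_leg[-1]
        if hs_leg and np.isfinite(state.stride_period[leg]):
            state.stride_fraction[leg] = (
                (t[-1] - hs_leg[-1]) / state.stride_period[leg]) % 1.0
    return hs, to, state


def compute_stimulations(params: ReflexParameters, gate: float,
                         force_aff, length_aff, velocity_aff,
                         trunk_lean: float, trunk_lean_vel: float,
                         load_own: float, load_contra: float) -> np.ndarray:
    """Stimulations of one leg's nine muscles from delayed afferents.

    ``gate`` is the stance weight in [0, 1] (1 = pure stance law); afferent
    arrays are length 9 in muscle order HFL GLU HAM RF VAS BFSH GAS SOL TA,
    in normalized units (F/F_max, l_ce/l_opt, v_ce/v_max shortening+).
    This is the same compiled law the simulation kernel runs.
    """
    p = params.vector()
    f = np.asarray(force_aff, float)
    l = np.asarray(length_aff, float)
    v = np.asarray(velocity_aff, float)
    S = np.zeros(9)
    _stimulations(p, 0, float(gate), f, l, v, l[_kernel.VAS], v[_kernel.VAS],
                  float(trunk_lean), float(trunk_lean_vel),
                  float(load_own), float(load_contra), S)
    return S


def delay_buffer_read(signal_history: np.ndarray, dt: float, delay: float,
                      t: float, t0: float = 0.0) -> float:
    """Value of a sampled signal at time ``t - delay`` (nearest step).

    ``signal_history[i]`` is the sample at ``t0 + i*dt``.  Raises if the
    history does not cover the requested instant, naming the warm-up span.
    """
    x = np.asarray(signal_history, float)
    idx = int(round((t - delay - t0) / dt))
    if idx < 0 or idx >= x.size:
        raise ValueError(
            f"history does not cover t - delay = {t - delay:.4f} s; "
            f"need a warm-up span of at least {delay:.4f} s"
        )
    return float(x[idx])
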
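"""The five gait-disturbance protocols and the trial machinery around them.

Protocols (all injected into a running simulation at a gait-phase or
magnitude condition, on one target leg):

* ``MMR`` — 10 ms square pulses added simultaneously to every muscle's
  force, length and velocity afferents (normalized amplitudes 1.0, i.e.
  F_max, l_opt and \\|v_max\\|), emulating electrical stimulation of the
  lumbar spinal cord.  Conditions: 16 equal stride phases.
* ``TR``  — tendon-tap: an imposed MTU stretch whose size is the hammer's
  kinetic energy divided by the current muscle tension (capped), applied as
  a brief triangular ramp.  Conditions: 16 equal stride phases.
* ``SR``  — imposed ankle dorsiflexion ramp (8 deg at 250 deg/s by
  default) via a servo that prescribes the ankle coordinate exactly.
  Conditions: 8 equal stride phases.
* ``TRIP`` — a 2.2 kg free block placed so the swing foot strikes it at a
  requested swing fraction (5–75%).
* ``SLIP`` — the stance-side belt/ground surface velocity changes by
  delta_v exactly 150 ms after the detected heel strike.

Every trial restarts from the same stored limit-cycle snapshot, and each
disturbed trial is paired with a bit-identical undisturbed control run, so
activation differences are exactly zero until the disturbance acts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .analysis import ResponseTrace, ResponseTrend, extract_response
from .muscle import MUSCLES

__all__ = [
    "DisturbanceSpec", "Trial", "condition_grid", "make_snapshot",
    "run_trial", "run_protocol", "response_trend", "afferent_changes",
    "RESPONSE_WINDOWS",
]

PROTOCOLS = ("MMR", "TR", "SR", "TRIP", "SLIP")
_CODE = {"MMR": _kernel.D_MMR, "TR": _kernel.D_TR, "SR": _kernel.D_SR,
         "TRIP": _kernel.D_TRIP, "SLIP": _kernel.D_SLIP}

# response windows (s, relative to onset, before the per-muscle delay shift)
RESPONSE_WINDOWS = {
    "MMR": (0.0, 0.040),
    "TR": (0.0, 0.040),
    "SR": (0.010, 0.060),
    "TRIP": (0.020, 0.100),
    "SLIP": (0.020, 0.150),
}

# window over which afferent (proprioceptive signal) changes are compared
AFFERENT_WINDOW = 0.150


@dataclass
class DisturbanceSpec:
    """One disturbance trial: protocol, onset, magnitudes, target leg."""

    protocol: str
    t0: float = 0.0
    leg: int = 0
    # MMR
    amplitude: float = 1.0
    pulse_duration: float = 0.010
    # TR
    muscle: str = "VAS"
    hammer_mass: float = 0.090
    hammer_speed: float = 1.5
    tap_ramp: float = 0.005
    stretch_cap: float = 0.05      # of l_opt
    # SR
    angle: float = np.deg2rad(8.0)
    rate: float = np.deg2rad(250.0)
    hold: float = 0.100
    # TRIP
    obstacle_mass: float = 2.2
    obstacle_height: float = 0.10
    obstacle_width: float = 0.10
    obstacle_x: float = 0.0        # front-face x (set by placement)
    activate_at: float = 0.0
    obstacle_stiffness: float = 2.0e4
    obstacle_damping: float = 100.0
    obstacle_friction: float = 0.8
    # SLIP
    delta_v: float = 0.0
    onset_delay: float = 0.150
    accel_window: float = 0.050
    direction: float = -1.0        # surface velocity change sign (belt
    #                                speed increase = surface moves backward)

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")

    @property
    def hammer_energy(self) -> float:
        """Kinetic energy of the tapping hammer, 0.5 m v^2 [J]."""
        return 0.5 * self.hammer_mass * self.hammer_speed ** 2

    def to_array(self) -> np.ndarray:
        d = np.zeros(16)
        d[0] = _CODE[self.protocol]
        d[1] = self.t0
        d[2] = self.leg
        if self.protocol == "MMR":
            d[3] = self.amplitude
            d[4] = self.pulse_duration
        elif self.protocol == "TR":
            d[3] = self.hammer_energy
            d[4] = self.tap_ramp
            d[5] = MUSCLES.index(self.muscle)
            d[6] = self.stretch_cap
        elif self.protocol == "SR":
            d[3] = self.angle
            d[4] = self.rate
            d[5] = self.hold
        elif self.protocol == "TRIP":
            d[6] = self.obstacle_x
            d[7] = self.obstacle_height
            d[8] = self.obstacle_width
            d[9] = self.obstacle_stiffness
            d[10] = self.obstacle_damping
            d[11] = self.obstacle_mass
            d[12] = self.activate_at
            d[15] = self.obstacle_friction
        elif self.protocol == "SLIP":
            d[3] = self.delta_v
            d[4] = self.onset_delay
            d[13] = self.accel_window
            d[14] = self.direction
        return d

    def manifest(self) -> dict:
        return {k: (v if not isinstance(v, np.floating) else float(v))
                for k, v in self.__dict__.items()}


def condition_grid(protocol: str) -> np.ndarray:
    """Condition axis per protocol: stride fractions (MMR/TR: 16, SR: 8),
    swing fractions 5-75% (TRIP: 8), or belt speed changes 0.1-0.5 m/s
    (SLIP: 5)."""
    if protocol in ("MMR", "TR"):
        return np.arange(16) / 16.0
    if protocol == "SR":
        return np.arange(8) / 8.0
    if protocol == "TRIP":
        return np.linspace(0.05, 0.75, 8)
    if protocol == "SLIP":
        return np.arange(0.1, 0.51, 0.1)
    raise ValueError(f"unknown protocol {protocol!r}")


# ---------------------------------------------------------------------------
# snapshots and trials
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    """Limit-cycle state stored at a heel strike of the target leg."""

    state: object          # WalkerState
    stride_period: float
    leg: int = 0

    def save(self, path):
        d = self.state.to_dict()
        d["_stride_period"] = self.stride_period
        d["_leg"] = self.leg
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def load(cls, path):
        from .walker import WalkerState

        with open(path) as fh:
            d = json.load(fh)
        T = d.pop("_stride_period")
        leg = d.pop("_leg")
        return cls(WalkerState.from_dict(d), T, leg)


def make_snapshot(walker, params, v0: float, settle: float = 12.0,
                  leg: int = 0) -> Snapshot:
    """Walk for ``settle`` s, then store the state at the next heel strike
    of ``leg`` together with the measured stride period."""
    st = walker.initial_state(v0=v0)
    traj, st = walker.simulate(params, settle, state=st)
    if traj.fell:
        raise RuntimeError("model fell during snapshot settling")
    # advance in small chunks until a fresh heel strike of the target leg
    for _ in range(400):
        traj, st = walker.simulate(params, 0.01, state=st)
        if traj.fell:
            raise RuntimeError("model fell while waiting for heel strike")
        if len(traj.heel_strikes[leg]):
            break
    else:
        raise RuntimeError("no heel strike detected after settling")
    # measure the stride period over the next two heel strikes
    probe, _ = walker.simulate(params, 3.5, state=st.copy())
    hs = probe.heel_strikes[leg]
    if len(hs) < 2:
        raise RuntimeError("could not measure a stride period")
    T = float(np.diff(hs[:3]).mean())
    return Snapshot(st, T, leg)


@dataclass
class Trial:
    """Matched disturbed/undisturbed pair launched from one snapshot."""

    spec: DisturbanceSpec
    condition: float
    onset: float
    disturbed: object      # GaitTrajectory
    undisturbed: object    # GaitTrajectory

    def response_trace(self, muscle: str, leg: int | None = None,
                       window=None) -> ResponseTrace:
        leg = self.spec.leg if leg is None else leg
        win = window or RESPONSE_WINDOWS[self.spec.protocol]
        t = self.disturbed.t
        return ResponseTrace(
            muscle, t,
            self.disturbed.activation(leg, muscle),
            self.undisturbed.activation(leg, muscle),
            onset=self.onset, window=win,
        )


def run_trial(walker, params, snap: Snapshot, spec: DisturbanceSpec,
              duration: float | None = None, rec_dt: float = 1e-3,
              undisturbed=None):
    """Run one disturbance trial plus its undisturbed control.

    Returns a :class:`Trial`; the undisturbed control can be passed in to
    be shared across trials from the same snapshot.
    """
    dur = duration or (spec.t0 - snap.state.t + 0.6)
    if undisturbed is None:
        undisturbed, _ = walker.simulate(params, dur, state=snap.state,
                                         rec_dt=rec_dt)
    dist, _ = walker.simulate(params, dur, state=snap.state,
                              disturbance=spec, rec_dt=rec_dt)
    onset = spec.t0
    if spec.protocol == "SLIP" and dist.misc[7] > 0:
        onset = float(dist.misc[7])
    return Trial(spec, np.nan, onset, dist, undisturbed)


def _place_obstacle(walker, params, snap, frac, spec, rec_dt):
    """Place the trip block so the swing foot's ball strikes it at the
    requested swing fraction; returns (spec, nominal onset) or None if the
    geometry is unrealizable (foot passes above the block)."""
    from ._kernel import _leg_point

    dur = 2.8 * snap.stride_period
    ref, _ = walker.simulate(params, dur, state=snap.state, rec_dt=rec_dt)
    leg = spec.leg
    t_arm = snap.state.t + 0.5 * snap.stride_period
    tos = [x for x in ref.toe_offs[leg] if x > t_arm]
    if not tos:
        return None, None, ref
    to = tos[0]
    hss = [x for x in ref.heel_strikes[leg] if x > to]
    if not hss:
        return None, None, ref
    hs = hss[0]
    t_star = to + frac * (hs - to)
    i = int(np.searchsorted(ref.t, t_star))
    i = min(i, len(ref.t) - 1)
    q = ref.rec[i, _kernel.REC_Q:_kernel.REC_Q + 9]
    b = 3 + 3 * leg
    px, py = _leg_point(q, np.zeros(9), walker.SEG, b,
                        walker.SEG[16], -walker.SEG[17])[:2]
    if py > spec.obstacle_height - 0.01:
        return None, None, ref   # foot clears the block: unrealizable
    spec.obstacle_x = px + 0.01
    spec.activate_at = max(t_star - 0.05, snap.state.t)
    spec.t0 = t_star
    return spec, t_star, ref


def run_protocol(walker, params, snap: Snapshot, protocol: str,
                 conditions=None, leg: int = 0, rec_dt: float = 1e-3,
                 spec_kw: dict | None = None) -> list:
    """Run a full condition grid of one protocol from a snapshot.

    MMR/TR/SR conditions are stride fractions (onset at
    ``t_snap + (1 + c) * T``); TRIP conditions are swing fractions; SLIP
    conditions are belt speed changes [m/s].  Returns a list of
    :class:`Trial` (unrealizable TRIP conditions are skipped).
    """
    conds = condition_grid(protocol) if conditions is None else np.asarray(conditions, float)
    spec_kw = spec_kw or {}
    T = snap.stride_period
    t_base = snap.state.t + T
    dur = 2.2 * T + 0.7
    undisturbed, _ = walker.simulate(params, dur, state=snap.state,
                                     rec_dt=rec_dt)
    trials = []
    for c in conds:
        if protocol in ("MMR", "TR", "SR"):
            spec = DisturbanceSpec(protocol, t0=t_base + c * T, leg=leg,
                                   **spec_kw)
            tr = run_trial(walker, params, snap, spec, duration=dur,
                           rec_dt=rec_dt, undisturbed=undisturbed)
        elif protocol == "TRIP":
            spec = DisturbanceSpec(protocol, leg=leg, **spec_kw)
            spec, t_star, ref = _place_obstacle(walker, params, snap, c,
                                                spec, rec_dt)
            if spec is None:
                continue
            # the block only exists when its mass is positive
            spec.to_array()[0]
            tr = run_trial(walker, params, snap, spec, duration=dur,
                           rec_dt=rec_dt, undisturbed=undisturbed)
        elif protocol == "SLIP":
            spec = DisturbanceSpec(protocol, t0=t_base, leg=leg, delta_v=c,
                                   **spec_kw)
            tr = run_trial(walker, params, snap, spec, duration=dur,
                           rec_dt=rec_dt, undisturbed=undisturbed)
        else:
            raise ValueError(protocol)
        tr.condition = float(c)
        trials.append(tr)
    return trials


def response_trend(trials: list, muscle: str, mode: str = "peak",
                   delay_shift: bool = True) -> ResponseTrend:
    """Condition-indexed scalar responses of one muscle across trials.

    With ``delay_shift`` the response window is shifted by the muscle's
    afferent transport delay (long/medium/short for ankle/knee/hip groups).
    """
    from .muscle import default_muscles

    delays = {m.name: m.delay for m in default_muscles()}
    conds, resp = [], []
    for tr in trials:
        win = RESPONSE_WINDOWS[tr.spec.protocol]
        if delay_shift:
            d = delays[muscle]
            win = (win[0] + d, win[1] + d)
        trace = tr.response_trace(muscle, window=win)
        conds.append(tr.condition)
        resp.append(extract_response(trace, mode=mode))
    order = np.argsort(conds)
    return ResponseTrend(muscle, trials[0].spec.protocol,
                         np.asarray(conds)[order], np.asarray(resp)[order])


def afferent_changes(trial: Trial, window: float = AFFERENT_WINDOW,
                     smooth: float = 0.005) -> dict:
    """Peak |disturbed - undisturbed| afferent change per (muscle, signal).

    Signals are the normalized proprioceptive afferents: ``force``
    (F/F_max), ``length`` (l_ce/l_opt) and ``velocity`` (v_ce/v_max),
    evaluated on the target leg within ``window`` seconds after onset.
    Each series is smoothed over ``smooth`` seconds first: afferent
    information is rate-coded with finite bandwidth, and the smoothing
    suppresses single-step numerical chatter of the CE velocity solve
    that would otherwise dominate the peaks.
    """
    from scipy.ndimage import uniform_filter1d

    leg = trial.spec.leg
    # a whole-body disturbance may end the trial early (fall); compare on
    # the overlapping part of the grids
    n = min(len(trial.disturbed.t), len(trial.undisturbed.t))
    t = trial.disturbed.t[:n]
    dt = t[1] - t[0] if n > 1 else 1.0
    width = max(1, int(round(smooth / dt)))
    sel = (t >= trial.onset) & (t <= trial.onset + window)
    out = {}
    for m in MUSCLES:
        for sig, accessor in (("force", "force_afferent"),
                              ("length", "length_afferent"),
                              ("velocity", "velocity_afferent")):
            d = getattr(trial.disturbed, accessor)(leg, m)[:n]
            u = getattr(trial.undisturbed, accessor)(leg, m)[:n]
            if width > 1:
                d = uniform_filter1d(d, width)
                u = uniform_filter1d(u, width)
            diff = np.abs(d[sel] - u[sel])
            out[(m, sig)] = float(np.max(diff)) if diff.size else 0.0
    return out
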
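"""High-level replications of the headline disturbance analyses.

These compose the protocol machinery and the comparison statistics into the
three model-only quantities the evaluation reports:

* :func:`mmr_spike_widths` — duration of the activation spikes evoked by
  simultaneous afferent pulses (electrical-stimulation analogue).
* :func:`proprioceptive_comparison` — how much larger the joint-level
  ankle perturbation's proprioceptive footprint is than that of the
  whole-body trip and slip disturbances.
* :func:`stance_velocity_feedback` — the correlation-based estimate of the
  velocity-feedback share of soleus stance activation, computed exactly
  like the experimental analysis even though the model's soleus stance
  pathway carries no velocity gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import spike_width, velocity_feedback_contribution, \
    proprioceptive_change_ratio
from .disturbances import (
    AFFERENT_WINDOW,
    DisturbanceSpec,
    RESPONSE_WINDOWS,
    Snapshot,
    afferent_changes,
    run_trial,
)
from .muscle import default_muscles

__all__ = ["mmr_spike_widths", "proprioceptive_comparison",
           "stance_velocity_feedback", "VelocityFeedbackResult"]


def _trial_duration(snap: Snapshot, frac: float) -> float:
    return (1.0 + frac) * snap.stride_period + 0.5


def mmr_spike_widths(walker, params, snap: Snapshot,
                     stride_fraction: float = 0.3,
                     muscles=("SOL", "GAS"), threshold: float = 0.2,
                     rec_dt: float = 5e-4) -> dict:
    """Evoked-spike durations [s] for an afferent-pulse trial.

    A 10 ms square pulse of normalized amplitude 1 is added to every
    muscle's force, length and velocity afferents at the given stride
    fraction (0.3 = mid-stance of the target leg); the spike duration of
    each requested muscle's activation excess is returned.
    """
    t0 = snap.state.t + snap.stride_period * (1.0 + stride_fraction)
    spec = DisturbanceSpec("MMR", t0=t0, leg=snap.leg)
    dur = _trial_duration(snap, stride_fraction)
    tr = run_trial(walker, params, snap, spec, duration=dur, rec_dt=rec_dt)
    return {m: spike_width(tr.response_trace(m, window=(0.0, 0.100)),
                           threshold=threshold)
            for m in muscles}


def proprioceptive_comparison(walker, params, snap: Snapshot,
                              sr_fraction: float = 0.25,
                              trip_fractions=(0.15, 0.3, 0.45, 0.6),
                              slip_delta_v: float = 0.5,
                              window: float = AFFERENT_WINDOW,
                              rec_dt: float = 1e-3):
    """Afferent-change footprints of SR vs TRIP vs SLIP, "up to" max ratio.

    Runs the protocols at their stated magnitudes (8 deg at 250 deg/s
    ankle ramp; 2.2 kg obstacle struck at several swing fractions;
    0.5 m/s belt change 150 ms after heel strike), computes the peak
    |disturbed - undisturbed| of every normalized afferent, and returns
    ``(max_ratio, tables)``: the largest SR-to-TRIP / SR-to-SLIP factor
    observed over muscles, signal types and trip conditions — the
    "changes up to N times larger" statistic — together with the
    per-protocol change tables (TRIP: the condition realizing the max).
    """
    from .disturbances import run_protocol

    T = snap.stride_period
    t_base = snap.state.t + T
    dur = 2.2 * T + 0.7
    leg = snap.leg

    sr = run_trial(walker, params, snap,
                   DisturbanceSpec("SR", t0=t_base + sr_fraction * T, leg=leg),
                   duration=dur, rec_dt=rec_dt)
    trips = run_protocol(walker, params, snap, "TRIP",
                         conditions=trip_fractions, leg=leg, rec_dt=rec_dt)
    if not trips:
        raise RuntimeError("all TRIP conditions unrealizable for this gait")
    slip = run_trial(walker, params, snap,
                     DisturbanceSpec("SLIP", t0=t_base, leg=leg,
                                     delta_v=slip_delta_v),
                     duration=dur, rec_dt=rec_dt)
    ch_sr = afferent_changes(sr, window=window)
    ch_slip = afferent_changes(slip, window=window)
    best = 0.0
    best_trip = None
    for tr in trips:
        ch_trip = afferent_changes(tr, window=window)
        r = proprioceptive_change_ratio(ch_sr, ch_trip, ch_slip)
        if r > best:
            best = r
            best_trip = ch_trip
    return best, {"SR": ch_sr, "TRIP": best_trip, "SLIP": ch_slip}


@dataclass
class VelocityFeedbackResult:
    """Correlation-based velocity-feedback attribution for SOL in stance."""

    contribution_percent: float
    slope: float                  # activation per (rad/s) velocity change
    velocity_changes: np.ndarray  # imposed ankle velocity changes [rad/s]
    amplitudes: np.ndarray        # SOL response amplitudes
    n_trials: int

    def summary(self) -> str:
        return (
            f"velocity-feedback attribution: {self.contribution_percent:.1f}% "
            f"of SOL stance activation ({self.n_trials} trials, "
            f"slope {self.slope:.4g} per rad/s)"
        )


def stance_velocity_feedback(walker, params, snap: Snapshot,
                             stance_fraction: float = 0.3,
                             rates_deg=(31.25, 62.5, 93.75, 125.0),
                             ramp_duration: float = 0.080,
                             rec_dt: float = 1e-3) -> VelocityFeedbackResult:
    """Replicate the correlation analysis of ankle-perturbation studies.

    Constant-velocity dorsiflexion ramps are imposed at one mid-stance
    phase at several rates spanning the physiological range of stance
    dorsiflexion velocities.  The ramps last ``ramp_duration`` (80 ms, so
    the imposed velocity is constant across the whole response window and
    the independent variable of the regression is unambiguous).  For each
    trial the *achieved* ankle angular-velocity change during the ramp
    (imposed minus undisturbed) and the SOL response amplitude (peak
    activation excess in the delay-shifted short-latency window) are
    collected.  A straight line of amplitude against velocity change is
    fitted, its slope applied to the dorsiflexion-velocity profile of
    undisturbed stance, and the attributed activation expressed as a
    percentage of mean total SOL stance activation.
    """
    T = snap.stride_period
    t_base = snap.state.t + T
    dur = 2.2 * T + 0.7
    leg = snap.leg
    und, _ = walker.simulate(params, dur, state=snap.state, rec_dt=rec_dt)

    delay = {m.name: m.delay for m in default_muscles()}["SOL"]
    w_lo, w_hi = RESPONSE_WINDOWS["SR"]
    t0 = t_base + stance_fraction * T
    dvs, amps = [], []
    for rdeg in rates_deg:
        rate = np.deg2rad(rdeg)
        spec = DisturbanceSpec("SR", t0=t0, leg=leg,
                               angle=rate * ramp_duration, rate=rate)
        tr = run_trial(walker, params, snap, spec, duration=dur,
                       rec_dt=rec_dt, undisturbed=und)
        n = min(len(tr.disturbed.t), len(und.t))
        t = tr.disturbed.t[:n]
        sel = (t >= t0) & (t <= t0 + ramp_duration)
        dv = float(np.mean(tr.disturbed.ankle_velocity(leg)[:n][sel]
                           - und.ankle_velocity(leg)[:n][sel]))
        selw = (t >= t0 + w_lo + delay) & (t <= t0 + w_hi + delay)
        amp = float(np.max(tr.disturbed.activation(leg, "SOL")[:n][selw]
                           - und.activation(leg, "SOL")[:n][selw]))
        dvs.append(dv)
        amps.append(amp)
    dvs = np.asarray(dvs)
    amps = np.asarray(amps)

    # undisturbed stance profile of the stride after t_base
    hs = [x for x in und.heel_strikes[leg] if x >= t_base - 0.2 * T]
    if not hs:
        raise RuntimeError("no stance phase found in the undisturbed trial")
    to = [x for x in und.toe_offs[leg] if x > hs[0]]
    t_end = to[0] if to else hs[0] + 0.6 * T
    t = und.t
    sel = (t >= hs[0]) & (t <= t_end)
    vel = und.ankle_velocity(leg)[sel]
    act = und.activation(leg, "SOL")[sel]

    contrib = velocity_feedback_contribution(dvs, amps, vel, act)
    slope = float(np.polyfit(dvs, amps, 1)[0])
    return VelocityFeedbackResult(contrib, slope, dvs, amps, len(dvs))
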
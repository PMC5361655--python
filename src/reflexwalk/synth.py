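"""Synthetic reference response trends and EMG-like trial traces.

Human reference data in gait-disturbance studies are peak-normalized mean ±
1 s.d. response trends over 5–16 conditions (stride phases or disturbance
magnitudes).  This module generates structurally similar data with known
ground truth — a latent trend, a true scale factor, and a controllable
number of conditions that no admissible scaling can bring into the band —
so every comparison statistic is testable without digitized experimental
curves.

Trends are mixtures of smooth bumps over the condition axis, mirroring the
smooth phase-dependence of real reflex-response curves; trial traces are
band-limited stochastic "EMG envelopes" with an injected response bump of
known height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .analysis import ReferenceBand, ResponseTrace, normalize_reference

__all__ = ["SynthSpec", "generate_reference_band", "generate_emg_trials"]


@dataclass
class SynthSpec:
    """Recipe for one synthetic reference band.

    Parameters
    ----------
    n_conditions : int
        Number of conditions on the axis (scaled to [0, 1]).
    centers, widths, heights : sequences
        Bump mixture defining the latent trend
        ``g(c) = sum_j h_j * exp(-(c - c_j)^2 / (2 w_j^2))``.
    sd_rel : float or sequence
        Band half-width per condition, relative to the normalized peak
        response (so 0.2 means ±0.2 around a curve whose peak is 1).
    k_true : float
        Ground-truth scale: the band mean equals ``k_true * latent`` before
        normalization, and the latent trend is returned for recovery tests.
    n_out_of_band : int
        Number of conditions made unreachable for *any* non-negative scale
        (their mean is moved across zero by more than one s.d.).
    in_band_noise : float
        Uniform perturbation of the latent trend, as a fraction of the local
        s.d.; values < 1 keep the perturbed conditions inside the band at
        the true scale.
    seed : int
        Seed for full reproducibility.
    """

    n_conditions: int = 16
    centers: tuple = (0.25, 0.7)
    widths: tuple = (0.12, 0.18)
    heights: tuple = (1.0, 0.6)
    sd_rel: float = 0.2
    k_true: float = 1.0
    n_out_of_band: int = 0
    in_band_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_conditions < 1:
            raise ValueError("need at least one condition")
        if self.n_out_of_band > self.n_conditions:
            raise ValueError("cannot force more conditions out of band than exist")
        if self.k_true <= 0:
            raise ValueError("ground-truth scale must be positive")


def _latent_trend(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    c = np.linspace(0.0, 1.0, spec.n_conditions)
    g = np.zeros_like(c)
    for cj, wj, hj in zip(spec.centers, spec.widths, spec.heights):
        g += hj * np.exp(-0.5 * ((c - cj) / wj) ** 2)
    if np.max(np.abs(g)) == 0:
        raise ValueError("degenerate (all-zero) trend shape")
    return c, g


def generate_reference_band(spec: SynthSpec):
    """Build a normalized reference band with known ground truth.

    Returns ``(band, latent, k_eff, out_idx)`` where ``band`` is the
    normalized :class:`ReferenceBand`, ``latent`` the unscaled model-side
    trend, ``k_eff`` the scale that maps ``latent`` onto the band mean for
    the in-band conditions (equal to ``spec.k_true`` by construction), and
    ``out_idx`` the indices forced out of band.

    Construction: the latent trend is the bump mixture rescaled so that
    ``max |k_true * latent| = 1``; the raw band mean is ``k_true * latent``
    (already peak-normalized, so normalization leaves ``k_true``
    recoverable).  Out-of-band conditions get their mean flipped across zero
    with margin: for those, ``k * latent_i >= 0`` can never re-enter
    ``mean_i ± sd_i``, so exactly ``n - n_out_of_band`` conditions are
    coverable — and they are covered simultaneously at ``k = k_true``.
    """
    rng = np.random.default_rng(spec.seed)
    c, g = _latent_trend(spec)
    latent = g / (spec.k_true * np.max(np.abs(g)))
    mean = spec.k_true * latent  # peak |mean| = 1 by construction
    sd = np.broadcast_to(np.asarray(spec.sd_rel, float), mean.shape).copy()

    if spec.in_band_noise > 0:
        bump = rng.uniform(-1.0, 1.0, size=mean.shape) * spec.in_band_noise * sd
        latent = latent + bump / spec.k_true

    out_idx = np.array([], dtype=int)
    if spec.n_out_of_band > 0:
        # pick the largest-response conditions so the flip is unambiguous
        order = np.argsort(np.abs(mean))[::-1]
        out_idx = np.sort(order[: spec.n_out_of_band])
        # flip across zero by a bit more than one s.d.: unreachable for k >= 0,
        # and small enough not to move the normalization peak
        mean = mean.copy()
        mean[out_idx] = -np.sign(latent[out_idx] + 1e-300) * (sd[out_idx] + 0.1)

    band = normalize_reference(c, mean, sd)
    return band, latent, spec.k_true, out_idx


def generate_emg_trials(
    n_trials: int,
    response_height: float,
    onset: float = 0.5,
    duration: float = 1.0,
    dt: float = 0.001,
    noise_sd: float = 0.0,
    baseline: float = 0.2,
    bump_width: float = 0.015,
    muscle: str = "SOL",
    seed: int = 0,
    window: tuple = (0.0, 0.06),
) -> list[ResponseTrace]:
    """EMG-envelope-like trial pairs with an injected response of known height.

    Each trial consists of an undisturbed and a disturbed activation trace.
    The background is a smooth positive envelope plus band-limited (0–15 Hz)
    noise, drawn independently for the two traces when ``noise_sd > 0`` —
    emulating that control and disturbed strides are different physical
    trials.  The disturbed trace additionally carries a Gaussian bump of
    amplitude ``response_height`` centered ``bump_width`` after onset.  With
    ``noise_sd = 0`` both traces share the deterministic background, so the
    extracted response equals the height exactly.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    envelope = baseline * (1.0 + 0.3 * np.sin(2 * np.pi * t / duration))
    b, a = _signal.butter(2, 15.0, fs=1.0 / dt, btype="low")

    def background():
        if noise_sd == 0.0:
            return envelope.copy()
        white = rng.standard_normal(t.size)
        colored = _signal.lfilter(b, a, white)
        scale = np.std(colored)
        colored = colored / scale * noise_sd if scale > 0 else colored
        return np.clip(envelope + colored, 0.0, 1.0)

    bump = response_height * np.exp(-0.5 * ((t - onset - bump_width) / bump_width) ** 2)
    trials = []
    for _ in range(n_trials):
        undisturbed = background()
        disturbed = np.clip(background() + bump, 0.0, 1.0) if noise_sd > 0 \
            else envelope + bump
        trials.append(
            ResponseTrace(muscle, t, disturbed, undisturbed, onset, window)
        )
    return trials
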
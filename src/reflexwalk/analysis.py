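"""Muscle response extraction and comparison statistics for gait-disturbance trials.

Given matched disturbed/undisturbed trials launched from the same limit-cycle
snapshot, this module extracts scalar muscle responses, assembles them into
condition-indexed trends (stride phase or disturbance magnitude on the x-axis),
and compares them against reference response bands (mean ± 1 s.d. per
condition, peak-normalized) the way gait-disturbance studies report their
results:

* ``scale_to_band`` — linearly scale a model trend by a single non-negative
  factor so that as many conditions as possible fall within the ±1 s.d. band,
  and report the percentage that do.
* ``amplitude_ratio`` — compare response magnitudes (after background
  normalization) between model and reference.
* ``proprioceptive_change_ratio`` — how much more a joint-level perturbation
  changes the proprioceptive afferents (muscle force/length/velocity) than
  whole-body disturbances do.
* ``velocity_feedback_contribution`` — the correlation-based estimate of how
  much of soleus stance activation is attributable to velocity feedback,
  obtained by regressing response amplitude on imposed ankle-velocity change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseTrace",
    "ResponseTrend",
    "ReferenceBand",
    "SimilarityResult",
    "extract_response",
    "normalize_reference",
    "scale_to_band",
    "amplitude_ratio",
    "proprioceptive_change_ratio",
    "velocity_feedback_contribution",
    "TrendComparison",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ResponseTrace:
    """Disturbed and undisturbed activation of one muscle on a shared grid.

    Parameters
    ----------
    muscle : str
        Muscle name (e.g. ``"SOL"``).
    t : ndarray
        Time grid [s], strictly increasing, shared by both series.
    disturbed, undisturbed : ndarray
        Activation series in [0, 1], same length as ``t``.
    onset : float
        Disturbance onset time [s].
    window : tuple of float
        Response window ``(start, stop)`` [s] relative to ``onset``;
        must lie after the onset.
    """

    muscle: str
    t: np.ndarray
    disturbed: np.ndarray
    undisturbed: np.ndarray
    onset: float
    window: tuple = (0.0, 0.040)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.disturbed = np.asarray(self.disturbed, dtype=float)
        self.undisturbed = np.asarray(self.undisturbed, dtype=float)
        if self.disturbed.shape != self.t.shape or self.undisturbed.shape != self.t.shape:
            raise ValueError("disturbed/undisturbed series must match the time grid")
        if self.window[1] <= self.window[0]:
            raise ValueError("response window must have positive length")


@dataclass
class ResponseTrend:
    """Scalar response per condition for one muscle and one experiment."""

    muscle: str
    experiment: str
    conditions: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.conditions.shape != self.responses.shape:
            raise ValueError("one response per condition required")
        if self.conditions.size > 1 and not np.all(np.diff(self.conditions) > 0):
            raise ValueError("condition axis must be strictly increasing")


@dataclass
class ReferenceBand:
    """Peak-normalized reference responses: mean ± 1 s.d. per condition."""

    conditions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.conditions.shape == self.mean.shape == self.sd.shape):
            raise ValueError("conditions, mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be non-negative")


@dataclass
class SimilarityResult:
    """Outcome of scaling a model trend into a reference band."""

    scale: float
    n_within: int
    n_total: int
    muscle: str = ""
    experiment: str = ""
    sse: float = field(default=np.nan)

    @property
    def percent(self) -> float:
        return 100.0 * self.n_within / self.n_total

    def summary(self) -> str:
        tag = f"{self.muscle} {self.experiment}".strip()
        return (
            f"{tag + ': ' if tag else ''}k = {self.scale:.4g}, "
            f"{self.n_within}/{self.n_total} conditions within +/-1 s.d. "
            f"({self.percent:.1f}%)"
        )


# ---------------------------------------------------------------------------
# response extraction and normalization
# ---------------------------------------------------------------------------

def extract_response(trace: ResponseTrace, mode: str = "peak") -> float:
    """Scalar muscle response of a disturbed trial relative to its control.

    The response is the signed peak (default) or the mean of the activation
    difference ``disturbed - undisturbed`` inside the response window.
    "Signed peak" means the value of the difference at the sample where its
    absolute value is largest, so purely symmetric noise averages to zero
    across trials.
    """
    lo = trace.onset + trace.window[0]
    hi = trace.onset + trace.window[1]
    if hi > trace.t[-1] + 1e-12 or lo < trace.t[0] - 1e-12:
        raise ValueError(
            f"response window [{lo:.4f}, {hi:.4f}] s exceeds the trace span "
            f"[{trace.t[0]:.4f}, {trace.t[-1]:.4f}] s"
        )
    sel = (trace.t >= lo - 1e-12) & (trace.t <= hi + 1e-12)
    diff = trace.disturbed[sel] - trace.undisturbed[sel]
    if diff.size == 0:
        raise ValueError("response window contains no samples")
    if mode == "peak":
        return float(diff[np.argmax(np.abs(diff))])
    if mode == "mean":
        return float(np.mean(diff))
    raise ValueError(f"unknown response mode {mode!r}")


def normalize_reference(
    conditions: np.ndarray, raw_mean: np.ndarray, raw_sd: np.ndarray
) -> ReferenceBand:
    """Normalize a raw reference trend so that max |mean| = 1.

    The s.d. profile is divided by the same factor so band widths stay
    proportional; normalizing twice is a no-op.
    """
    raw_mean = np.asarray(raw_mean, dtype=float)
    raw_sd = np.asarray(raw_sd, dtype=float)
    peak = np.max(np.abs(raw_mean))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero reference trend")
    return ReferenceBand(np.asarray(conditions, float), raw_mean / peak, raw_sd / peak)


def spike_width(trace: ResponseTrace, threshold: float = 0.2,
                search: float = 0.100) -> float:
    """Duration [s] of the evoked activation spike above background.

    Standard burst-duration measure: the contiguous interval around the
    peak of the activation excess (disturbed - undisturbed) during which
    the excess stays above ``threshold`` (default 20%) of its peak value.
    The peak is searched within ``search`` seconds after onset.  Restricting
    to the contiguous segment containing the peak excludes later
    mechanically-mediated after-responses from the spike itself.
    """
    t = trace.t
    sel = (t >= trace.onset) & (t <= trace.onset + search)
    ex = trace.disturbed[sel] - trace.undisturbed[sel]
    tt = t[sel]
    if ex.size == 0 or np.max(ex) <= 0:
        return 0.0
    ipk = int(np.argmax(ex))
    thr = threshold * ex[ipk]
    i0 = ipk
    while i0 > 0 and ex[i0 - 1] > thr:
        i0 -= 1
    i1 = ipk
    while i1 < ex.size - 1 and ex[i1 + 1] > thr:
        i1 += 1
    return float(tt[i1] - tt[i0])


# ---------------------------------------------------------------------------
# band-overlap similarity
# ---------------------------------------------------------------------------

def _overlap_count(k: float, m: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> int:
    return int(np.sum(np.abs(k * m - mu) <= sd + 1e-12))


def scale_to_band(
    model_trend: ResponseTrend,
    band: ReferenceBand,
    allow_offset: bool = False,
) -> SimilarityResult:
    """Scale a model trend into a reference band, maximizing conditions in band.

    Finds the single non-negative factor ``k`` maximizing the number of
    conditions with ``|k*model_i - mean_i| <= sd_i``.  The search is exact:
    for every condition with a nonzero model response the set of admissible
    ``k`` is the closed interval ``[(mean_i - sd_i)/model_i,
    (mean_i + sd_i)/model_i]`` (endpoints swapped for negative responses)
    intersected with ``k >= 0``, so the maximum of the piecewise-constant
    count is attained at one of the interval endpoints.  Ties in the count
    are broken by the minimum sum of squared residuals to the band mean.

    With ``allow_offset=True`` an additive offset is fitted alongside ``k``
    by profiling the offset on a fine grid (sensitivity analysis only;
    responses are baseline-subtracted changes, so zero should map to zero
    and the default is scale-only).
    """
    m = np.asarray(model_trend.responses, dtype=float)
    mu = np.asarray(band.mean, dtype=float)
    sd = np.asarray(band.sd, dtype=float)
    if m.shape != mu.shape:
        raise ValueError(
            f"model trend has {m.size} conditions but band has {mu.size}"
        )
    if allow_offset:
        return _scale_to_band_offset(model_trend, band)

    n = m.size
    nz = m != 0.0
    # endpoints of the admissible-k interval per nonzero condition
    cands = [0.0]
    for mi, mui, sdi in zip(m[nz], mu[nz], sd[nz]):
        a = (mui - sdi) / mi
        b = (mui + sdi) / mi
        lo, hi = (a, b) if a <= b else (b, a)
        if hi >= 0.0:
            cands.append(max(lo, 0.0))
            cands.append(hi)
    cands = np.unique(np.asarray(cands))

    counts = np.array([_overlap_count(k, m, mu, sd) for k in cands])
    best = counts.max()
    # least-squares k over all conditions, used for the SSE tie-break
    denom = float(np.dot(m, m))
    k_ls = float(np.dot(m, mu)) / denom if denom > 0 else 0.0
    k_ls = max(k_ls, 0.0)

    # Maximizing set is a union of closed segments between candidate
    # endpoints; inside each maximizing segment SSE is quadratic in k, so the
    # best k is the LS solution clamped to the segment.
    best_k, best_sse = None, np.inf
    ext = np.append(cands, cands[-1] + max(1.0, abs(k_ls)) + 1.0)
    for i, kc in enumerate(cands):
        if counts[i] == best:
            for k_try in (kc,):
                sse = float(np.sum((k_try * m - mu) ** 2))
                if sse < best_sse - 1e-15:
                    best_k, best_sse = k_try, sse
        # open segment to the right of kc
        lo_seg, hi_seg = ext[i], ext[i + 1]
        mid = 0.5 * (lo_seg + hi_seg)
        if hi_seg > lo_seg and _overlap_count(mid, m, mu, sd) == best:
            k_try = min(max(k_ls, lo_seg), hi_seg)
            sse = float(np.sum((k_try * m - mu) ** 2))
            if sse < best_sse - 1e-15:
                best_k, best_sse = k_try, sse
    # region beyond the last endpoint (count there equals count at +inf)
    k_try = max(k_ls, float(cands[-1]))
    if _overlap_count(k_try + 1.0, m, mu, sd) == best:
        sse = float(np.sum((k_try * m - mu) ** 2))
        if sse < best_sse - 1e-15:
            best_k, best_sse = k_try, sse

    return SimilarityResult(
        scale=float(best_k),
        n_within=int(best),
        n_total=n,
        muscle=model_trend.muscle,
        experiment=model_trend.experiment,
        sse=best_sse,
    )


def _scale_to_band_offset(model_trend: ResponseTrend, band: ReferenceBand) -> SimilarityResult:
    m, mu, sd = model_trend.responses, band.mean, band.sd
    span = float(np.max(np.abs(mu)) + np.max(sd) + 1e-9)
    best = SimilarityResult(0.0, -1, m.size, model_trend.muscle, model_trend.experiment)
    for off in np.linspace(-span, span, 201):
        shifted = ResponseTrend(model_trend.muscle, model_trend.experiment,
                                model_trend.conditions, m)
        r = scale_to_band(shifted, ReferenceBand(band.conditions, mu - off, sd))
        if r.n_within > best.n_within or (
            r.n_within == best.n_within and r.sse < best.sse
        ):
            r.sse = float(np.sum((r.scale * m + off - mu) ** 2))
            best = r
    return best


# ---------------------------------------------------------------------------
# amplitude statistics
# ---------------------------------------------------------------------------

def amplitude_ratio(
    model_trend: ResponseTrend,
    reference_trend: ResponseTrend,
    model_background: float = 1.0,
    reference_background: float = 1.0,
) -> float:
    """Model-to-reference response amplitude, in percent.

    Both trends are first expressed relative to their own peak background
    activation (``*_background``), then the ratio of peak absolute responses
    is returned as a percentage.  Meaningful only for mechanically replicated
    disturbances (imposed joint rotation, trip, slip) where model and
    experiment share physical units of perturbation.
    """
    if model_background <= 0 or reference_background <= 0:
        raise ValueError("background normalizations must be positive")
    ref_peak = float(np.max(np.abs(reference_trend.responses))) / reference_background
    if ref_peak == 0:
        raise ValueError("reference trend has zero peak response")
    mod_peak = float(np.max(np.abs(model_trend.responses))) / model_background
    return 100.0 * mod_peak / ref_peak


def proprioceptive_change_ratio(
    sr_changes: dict,
    trip_changes: dict,
    slip_changes: dict,
    return_table: bool = False,
):
    """Fold-change of afferent perturbation: joint-level vs whole-body.

    Each argument maps ``(muscle, signal)`` — signal one of ``"force"``,
    ``"length"``, ``"velocity"`` (normalized afferent units) — to the peak
    absolute change ``max_t |disturbed - undisturbed|`` of that afferent in
    the corresponding experiment.  Returns the maximum over muscles and
    signal types of the ratios SR/TRIP and SR/SLIP.  Keys whose whole-body
    change is zero (or missing) are excluded from that ratio.
    """
    rows = []
    best = 0.0
    for key, sr_val in sr_changes.items():
        for name, other in (("TRIP", trip_changes), ("SLIP", slip_changes)):
            denom = other.get(key, 0.0)
            if denom > 0.0:
                ratio = sr_val / denom
                rows.append((key[0], key[1], name, ratio))
                best = max(best, ratio)
    if not rows:
        raise ValueError("no comparable afferent changes (all denominators zero)")
    if return_table:
        import pandas as pd

        return best, pd.DataFrame(rows, columns=["muscle", "signal", "versus", "fold"])
    return best


# ---------------------------------------------------------------------------
# correlation-based velocity-feedback estimate
# ---------------------------------------------------------------------------

def velocity_feedback_contribution(
    velocity_changes: np.ndarray,
    response_amplitudes: np.ndarray,
    stance_velocity_profile: np.ndarray,
    stance_activation_profile: np.ndarray,
) -> float:
    """Apparent velocity-feedback share of soleus stance activation, percent.

    Reproduces the correlation-based analysis used in ankle-perturbation
    experiments: across trials with different imposed ankle dorsiflexion
    velocity changes, fit a straight line of response amplitude against the
    imposed velocity change, then apply the fitted slope to the undisturbed
    stance dorsiflexion-velocity profile (positive part, since only stretch
    excites the pathway) to predict the "velocity-attributed" activation.
    The contribution is the mean attributed activation divided by the mean
    total stance activation, in percent.

    Note this is an *attribution by correlation*: a pathway driven purely by
    force feedback still yields a positive estimate, because imposed stretch
    velocity and muscle force co-vary.
    """
    dv = np.asarray(velocity_changes, dtype=float)
    amp = np.asarray(response_amplitudes, dtype=float)
    if dv.size < 2 or dv.size != amp.size:
        raise ValueError("need >= 2 matched (velocity change, amplitude) trials")
    if np.ptp(dv) <= 0:
        raise ValueError("degenerate spread of imposed velocity changes")
    slope, _intercept = np.polyfit(dv, amp, 1)
    vel = np.asarray(stance_velocity_profile, dtype=float)
    act = np.asarray(stance_activation_profile, dtype=float)
    attributed = slope * np.clip(vel, 0.0, None)
    total = float(np.mean(act))
    if total <= 0:
        raise ValueError("total stance activation must be positive")
    return 100.0 * float(np.mean(attributed)) / total


# ---------------------------------------------------------------------------
# model-style front end
# ---------------------------------------------------------------------------

def plot_band_comparison(result: SimilarityResult, model_trend: ResponseTrend,
                         band: ReferenceBand, ax=None):
    """Reference mean ± 1 s.d. band with the scaled model trend overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    c = band.conditions
    ax.fill_between(c, band.mean - band.sd, band.mean + band.sd,
                    color="0.8", label="reference ±1 s.d.")
    ax.plot(c, band.mean, color="0.45", lw=1.5, label="reference mean")
    ax.plot(model_trend.conditions, result.scale * model_trend.responses,
            "k.-", label=f"model × {result.scale:.2g}")
    ax.set_title(f"{result.percent:.0f}% within ±1 s.d.", fontsize=10)
    ax.set_xlabel("condition")
    ax.set_ylabel("normalized response")
    ax.legend(fontsize=8)
    return ax


class TrendComparison:
    """Model object comparing a response trend against a reference band.

    ``fit()`` runs the exact band-overlap maximization and returns the
    :class:`SimilarityResult`; mirrors the model/results split used by
    statistical modelling packages.
    """

    def __init__(self, model_trend: ResponseTrend, band: ReferenceBand,
                 allow_offset: bool = False):
        self.model_trend = model_trend
        self.band = band
        self.allow_offset = allow_offset

    def fit(self) -> SimilarityResult:
        return scale_to_band(self.model_trend, self.band, self.allow_offset)
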
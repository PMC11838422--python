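"""Per-trace and per-event fluorescence statistics.

Implements the full catalogue of trace metrics used to characterise calcium
indicators: baseline (F0) estimators, dF/F0, peak dF/F0 and peak SNR,
half-rise/half-decay times from single-exponential fits, full decay time,
responsiveness classifiers (trial-based rank-sum and z-score), orientation
selectivity, isolated-spike selection, event-triggered averaging, and the
saturating dynamic response dF_max/F_min.

Conventions pinned for reproducibility: sample standard deviation (ddof=1)
everywhere; sliding windows are centred and truncated (not padded) at the
edges; percentiles use the linear-interpolation definition; decision
thresholds (z > 2.5, r2 < 0.8) are strict inequalities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import splev, splrep
from scipy.optimize import curve_fit

from geciquant.transients import Trace

__all__ = [
    "BaselineSpec",
    "DffTrace",
    "TransientMetrics",
    "TuningCurve",
    "estimate_baseline",
    "dff",
    "peak_dff",
    "peak_snr",
    "half_times",
    "full_decay_time",
    "classify_responsive_pre_post",
    "classify_responsive_zscore",
    "osi",
    "isolate_single_spikes",
    "event_triggered_average",
    "dmax_over_fmin",
]

#: Sentinel returned when the baseline has zero variance (noiseless trace).
INF_SNR = float("inf")


@dataclass(frozen=True)
class BaselineSpec:
    """How to estimate the baseline fluorescence F0.

    methods
    -------
    ``pre_window_mean``
        Mean of ``window`` frames immediately before the event onset (e.g. the
        1 s of baseline before a stimulus).
    ``sliding_percentile``
        Per-frame running percentile over a centred window (e.g. 20th
        percentile over 200 frames, or 10th percentile over 60 s).
    ``spline_fit``
        Smoothing-spline fit to the whole trace (slow drift / photobleaching
        baseline).
    ``pre_spike_spline``
        B-spline through the ``window`` frames (default 3) before the event
        onset, evaluated at the onset.
    """

    method: str = "sliding_percentile"
    window: float = 200.0  # frames, or seconds if window_unit == "s"
    percentile: float = 20.0
    window_unit: str = "frames"  # {"frames", "s"}
    smoothing: float | None = None  # spline_fit smoothing factor

    def __post_init__(self) -> None:
        if self.method not in (
            "pre_window_mean",
            "sliding_percentile",
            "spline_fit",
            "pre_spike_spline",
        ):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")
        if self.window <= 0:
            raise ValueError("window must be > 0")

    def window_frames(self, frame_rate: float) -> int:
        n = self.window * frame_rate if self.window_unit == "s" else self.window
        return max(int(round(n)), 1)


@dataclass(frozen=True)
class DffTrace:
    """A baseline-normalised trace: dF/F0 = (F - F0)/F0 per frame."""

    values: np.ndarray
    f0: np.ndarray | float
    frame_rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("dF/F0 values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class TransientMetrics:
    """Per-event summary: amplitude, SNR, kinetics and fit quality."""

    peak_dff: float = float("nan")
    peak_snr: float = float("nan")
    t_half_rise: float = float("nan")
    t_half_decay: float = float("nan")
    full_decay: float = float("nan")
    fit_r2: float = float("nan")
    excluded: bool = False


@dataclass(frozen=True)
class TuningCurve:
    """Mean responses to 8 grating orientations (0–157.5 deg, step 22.5)."""

    orientations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.orientations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "orientations", o)
        object.__setattr__(self, "responses", r)
        if o.size != r.size or o.size < 2:
            raise ValueError("need matched orientations/responses (>= 2)")

    @property
    def r_pref(self) -> float:
        """Response at the preferred (maximal) orientation."""
        return float(np.max(self.responses))

    @property
    def r_orth(self) -> float:
        """Response at the orientation 90 deg from preferred."""
        i = int(np.argmax(self.responses))
        target = (self.orientations[i] + 90.0) % 180.0
        j = int(np.argmin(np.abs((self.orientations - target + 90) % 180 - 90)))
        return float(self.responses[j])


def _as_values(trace) -> np.ndarray:
    return np.asarray(trace.values if hasattr(trace, "values") else trace, dtype=float)


def estimate_baseline(
    trace: Trace,
    spec: BaselineSpec,
    event_onset: int | None = None,
) -> float | np.ndarray:
    """Estimate F0 per the requested method (scalar or per-frame array)."""
    v = _as_values(trace)
    frame_rate = getattr(trace, "frame_rate", 1.0)
    w = spec.window_frames(frame_rate)

    if spec.method == "pre_window_mean":
        if event_onset is None:
            raise ValueError("pre_window_mean requires event_onset")
        lo = max(event_onset - w, 0)
        if lo == event_onset:
            raise ValueError("no frames before event_onset for baseline")
        return float(np.mean(v[lo:event_onset]))

    if spec.method == "pre_spike_spline":
        if event_onset is None:
            raise ValueError("pre_spike_spline requires event_onset")
        lo = max(event_onset - w, 0)
        seg = v[lo:event_onset]
        if seg.size == 0:
            raise ValueError("no frames before event_onset for baseline")
        if seg.size == 1:
            return float(seg[0])
        x = np.arange(lo, event_onset, dtype=float)
        k = min(2, seg.size - 1)
        tck = splrep(x, seg, k=k, s=0)
        return float(splev(event_onset, tck))

    if spec.method == "sliding_percentile":
        half = w // 2
        out = np.empty_like(v)
        for i in range(v.size):
            lo = max(i - half, 0)
            hi = min(i + (w - half), v.size)
            out[i] = np.percentile(v[lo:hi], spec.percentile)
        return out

    # spline_fit: smoothing spline over the full trace (drift/photobleaching)
    x = np.arange(v.size, dtype=float)
    s = spec.smoothing if spec.smoothing is not None else v.size * np.var(v) * 0.1
    k = min(3, v.size - 1)
    tck = splrep(x, v, k=k, s=s)
    return np.asarray(splev(x, tck), dtype=float)


def dff(trace, baseline) -> DffTrace:
    """dF/F0 = (F - F0)/F0, elementwise."""
    v = _as_values(trace)
    f0 = np.asarray(baseline, dtype=float)
    bad = np.flatnonzero(~(f0 > 0))
    if bad.size:
        raise ValueError(f"non-positive baseline at frame {int(bad[0])}")
    out = (v - f0) / f0
    return DffTrace(values=out, f0=baseline, frame_rate=getattr(trace, "frame_rate", 1.0))


def peak_dff(dff_trace, search_window: slice | None = None) -> float:
    """Maximal dF/F0 within the search window (not clipped at zero)."""
    v = _as_values(dff_trace)
    if search_window is not None:
        v = v[search_window]
    if v.size == 0:
        raise ValueError("empty search window")
    return float(np.max(v))


def peak_snr(
    trace,
    baseline_window: slice,
    peak_window: slice | None = None,
    noise_basis: str = "raw_f_sd",
    low_quantile: float = 20.0,
) -> float:
    """Peak SNR: maximal fluorescence change over the baseline noise SD.

    ``raw_f_sd`` uses the sample SD of the frames in ``baseline_window`` (e.g.
    the 1 s of baseline before the stimulus). ``low_quantile_sd`` instead uses
    the SD of the frames of the whole trace whose values fall at or below the
    ``low_quantile``-th percentile (the quiet-frame noise estimate for
    recordings without a clean pre-stimulus window). Returns an infinite
    sentinel with a warning when the baseline has zero variance.
    """
    v = _as_values(trace)
    base = v[baseline_window]
    if base.size < 2:
        raise ValueError("baseline window needs >= 2 frames")
    f0 = float(np.mean(base))
    if noise_basis == "raw_f_sd":
        sd = float(np.std(base, ddof=1))
    elif noise_basis == "low_quantile_sd":
        thr = np.percentile(v, low_quantile)
        quiet = v[v <= thr]
        sd = float(np.std(quiet, ddof=1)) if quiet.size >= 2 else 0.0
    else:
        raise ValueError(f"unknown noise_basis {noise_basis!r}")
    peak = float(np.max(v[peak_window] if peak_window is not None else v))
    if sd == 0.0:
        warnings.warn("zero baseline SD; returning infinite SNR sentinel")
        return INF_SNR
    return (peak - f0) / sd


def _exp_decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _exp_rise(t, a, tau, c):
    return c + a * (1.0 - np.exp(-t / tau))


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float | None:
    """First linear-interpolated crossing of ``level`` along (t, y)."""
    for k in range(1, y.size):
        y0, y1 = y[k - 1], y[k]
        hit = (y0 < level <= y1) if rising else (y0 > level >= y1)
        if hit:
            if y1 == y0:
                return float(t[k])
            frac = (level - y0) / (y1 - y0)
            return float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return None


def half_times(
    dff_epoch: DffTrace,
    fit: str = "exponential",
    r2_exclude: float = 0.8,
) -> TransientMetrics:
    """Half-rise and half-decay times of a single-peaked dF/F0 epoch.

    ``exponential`` fits the rise and decay segments to single exponentials
    and interpolates the half-maximum crossings linearly on the fitted curve
    sampled at the frame times; ``interpolation_only`` interpolates the raw
    samples directly. The epoch is flagged ``excluded`` when the exponential
    fit quality r2 falls below 0.8 (the standard exclusion rule for transients
    that fail to recover to baseline or fit poorly).
    """
    v = dff_epoch.values
    if v.size < 3:
        raise ValueError("epoch too short")
    ipk = int(np.argmax(v))
    if ipk == 0 or ipk == v.size - 1:
        raise ValueError("peak at epoch boundary: rise/decay phase undefined")
    fr = dff_epoch.frame_rate
    t = np.arange(v.size) / fr
    peak = float(v[ipk])
    base_rise = float(v[0])
    half_rise_level = base_rise + 0.5 * (peak - base_rise)
    half_decay_level = 0.5 * peak

    m = TransientMetrics(peak_dff=peak)
    if fit == "interpolation_only":
        tr = _interp_crossing(t[: ipk + 1], v[: ipk + 1], half_rise_level, rising=True)
        td = _interp_crossing(t[ipk:], v[ipk:], half_decay_level, rising=False)
        m.t_half_rise = float("nan") if tr is None else tr
        m.t_half_decay = float("nan") if td is None else td - t[ipk]
        m.fit_r2 = float("nan")
        return m
    if fit != "exponential":
        raise ValueError(f"unknown fit mode {fit!r}")

    # decay fit: A exp(-t/tau) + C from the peak onwards
    td_t = t[ipk:] - t[ipk]
    td_v = v[ipk:]
    tau0 = max(td_t[-1] / 3.0, 1.0 / fr)
    fit_ok = True
    try:
        popt_d, _ = curve_fit(
            _exp_decay, td_t, td_v,
            p0=[peak - td_v[-1], tau0, td_v[-1]],
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        decay_curve = _exp_decay(td_t, *popt_d)
        ss_res_d = float(np.sum((td_v - decay_curve) ** 2))
    except RuntimeError:
        fit_ok = False
        decay_curve = td_v
        ss_res_d = 0.0

    # rise fit: C + A(1 - exp(-t/tau)) up to the peak
    tr_t = t[: ipk + 1]
    tr_v = v[: ipk + 1]
    try:
        popt_r, _ = curve_fit(
            _exp_rise, tr_t, tr_v,
            p0=[peak - base_rise, max(tr_t[-1] / 3.0, 1.0 / fr), base_rise],
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        rise_curve = _exp_rise(tr_t, *popt_r)
        ss_res_r = float(np.sum((tr_v - rise_curve) ** 2))
    except RuntimeError:
        fit_ok = False
        rise_curve = tr_v
        ss_res_r = 0.0

    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    m.fit_r2 = 1.0 - (ss_res_r + ss_res_d) / ss_tot if ss_tot > 0 else 1.0
    if not fit_ok:
        m.fit_r2 = float("-inf")

    # half levels referenced on the fitted curves (robust to single-frame
    # noise on the raw peak sample)
    half_rise_level = rise_curve[0] + 0.5 * (rise_curve[-1] - rise_curve[0])
    half_decay_level = 0.5 * decay_curve[0]
    tr = _interp_crossing(tr_t, rise_curve, half_rise_level, rising=True)
    td = _interp_crossing(td_t, decay_curve, half_decay_level, rising=False)
    # extrapolate on the fitted decay when the epoch ends above half-peak
    if td is None and fit_ok and popt_d[0] > 0:
        a, tau, c = popt_d
        if half_decay_level > c:
            td = float(tau * math.log(a / (half_decay_level - c)))
            if td < 0:
                td = None
    m.t_half_rise = float("nan") if tr is None else tr
    m.t_half_decay = float("nan") if td is None else td
    m.excluded = bool(m.fit_r2 < r2_exclude)
    return m


def full_decay_time(dff_spike: DffTrace) -> tuple[float, bool]:
    """Time from the peak to the first post-peak zero crossing of dF/F0.

    Returns ``(time_s, censored)``; ``censored`` is True when the trace ends
    before dF/F0 returns to zero (the crossing is then undefined). The
    crossing is linearly interpolated between frames. Note the underlying
    definition ("first time point that reached the negative dF/F0 of the
    spike") is read here as the first zero crossing after the peak.
    """
    v = dff_spike.values
    ipk = int(np.argmax(v))
    t = np.arange(v.size) / dff_spike.frame_rate
    post_t, post_v = t[ipk:], v[ipk:]
    cross = None
    for k in range(1, post_v.size):
        if post_v[k] <= 0.0 < post_v[k - 1]:
            if post_v[k] == 0.0:
                cross = float(post_t[k])
            else:
                frac = post_v[k - 1] / (post_v[k - 1] - post_v[k])
                cross = float(post_t[k - 1] + frac * (post_t[k] - post_t[k - 1]))
            break
    if cross is None:
        return float("nan"), True
    return cross - float(t[ipk]), False


def classify_responsive_pre_post(
    trials: list[np.ndarray] | list[DffTrace],
    pre_window: slice,
    post_window: slice,
    alpha: float = 0.05,
    amp_sd_factor: float = 4.0,
) -> tuple[bool, float]:
    """Trial-based responsiveness: rank-sum p-value plus amplitude criterion.

    A neuron is responsive iff (a) the Wilcoxon rank-sum test of the per-trial
    mean activity after onset vs before onset gives p < ``alpha``, and (b) the
    trial-averaged peak response exceeds ``amp_sd_factor`` sample SDs of the
    trial-averaged baseline. The exact null distribution is used for fewer
    than 8 trials, the tie-corrected normal approximation otherwise.
    """
    if len(trials) < 5:
        raise ValueError("need >= 5 trials for the rank-sum responsiveness test")
    arrs = [_as_values(tr) for tr in trials]
    pre = np.array([np.mean(a[pre_window]) for a in arrs])
    post = np.array([np.mean(a[post_window]) for a in arrs])
    if np.array_equal(pre, post):
        p = 1.0
    else:
        method = "exact" if len(arrs) < 8 else "asymptotic"
        p = float(
            stats.mannwhitneyu(post, pre, alternative="two-sided", method=method).pvalue
        )
    mean_trace = np.mean(np.stack(arrs), axis=0)
    base = mean_trace[pre_window]
    sd = float(np.std(base, ddof=1))
    amp = float(np.max(mean_trace[post_window]) - np.mean(base))
    amp_ok = amp > amp_sd_factor * sd
    return bool(p < alpha and amp_ok), p


def classify_responsive_zscore(
    dff_trace: DffTrace,
    onset: int,
    window_s: float = 3.0,
    threshold: float = 2.5,
) -> bool:
    """Responsive iff the z-score exceeds ``threshold`` within ``window_s``
    of onset, with z computed against the pre-onset mean and sample SD
    (strict inequality at the threshold)."""
    v = dff_trace.values
    if onset < 10:
        raise ValueError("need >= 10 baseline frames before onset")
    base = v[:onset]
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    if sd == 0.0:
        warnings.warn("zero baseline SD in z-score classifier")
        return False
    hi = min(onset + int(round(window_s * dff_trace.frame_rate)) + 1, v.size)
    z = (v[onset:hi] - mu) / sd
    return bool(np.max(z) > threshold)


def osi(curve: TuningCurve) -> float:
    """Orientation selectivity index (R_pref - R_orth)/(R_pref + R_orth).

    Values above 1 arise when R_orth is negative; they are returned as-is so
    the caller can apply the standard OSI > 1 exclusion.
    """
    rp, ro = curve.r_pref, curve.r_orth
    if rp + ro == 0:
        raise ZeroDivisionError("OSI undefined: R_pref + R_orth = 0")
    return (rp - ro) / (rp + ro)


def isolate_single_spikes(spike_times: np.ndarray, min_gap: float) -> np.ndarray:
    """Indices of events whose neighbours are farther than ``min_gap`` away.

    The first/last events only need isolation on their single inner side.
    ``min_gap`` shares units with ``spike_times`` (seconds or frames).
    """
    t = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted")
    if t.size <= 1:
        return np.arange(t.size)
    keep = []
    for i in range(t.size):
        ok_prev = i == 0 or (t[i] - t[i - 1]) > min_gap
        ok_next = i == t.size - 1 or (t[i + 1] - t[i]) > min_gap
        if ok_prev and ok_next:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def event_triggered_average(
    dff_trace,
    events: np.ndarray,
    pre: int,
    post: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and sample SD of snippets aligned to events (frame indices).

    Snippets span ``[event - pre, event + post)``; events whose snippet falls
    partly outside the trace are dropped. Returns (mean, sd, n_used); SD is
    zero-filled when only one snippet is usable.
    """
    v = _as_values(dff_trace)
    snippets = []
    for e in np.asarray(events, dtype=int):
        lo, hi = e - pre, e + post
        if lo < 0 or hi > v.size:
            continue
        snippets.append(v[lo:hi])
    if not snippets:
        raise ValueError("no events with a full snippet inside the trace")
    stack = np.stack(snippets)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return mean, sd, stack.shape[0]


def dmax_over_fmin(trace, response_window: slice | None = None) -> float:
    """Saturating dynamic response (F_max - F_min)/F_min within a window.

    F_min is the single-frame minimum before the rise (the pre-influx
    minimum); F_max the single-frame maximum of the response.
    """
    v = _as_values(trace)
    if response_window is not None:
        v = v[response_window]
    if v.size == 0:
        raise ValueError("empty response window")
    imax = int(np.argmax(v))
    fmin = float(np.min(v[: imax + 1]))
    if fmin <= 0:
        raise ValueError("F_min must be > 0")
    return (float(v[imax]) - fmin) / fmin
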
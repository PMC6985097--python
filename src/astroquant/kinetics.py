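"""Decomposition of ATP-evoked Ca2+ fluorescence transients.

A raw ROI trace is normalized to its pre-stimulus baseline (F/F0, baseline
window 0-20 s), screened for a response (excursion above baseline mean +
k*SD sustained for m samples), and decomposed into latency, 10-90% rise time
(RT), peak amplitude, area under the curve (AUC), and a decay time constant
tau from a least-squares fit of

    f(t') = a * exp(-t'/tau) + c,      t' = time since peak,

on the baseline-subtracted tail; c ~= 0 for a transient that returns to
baseline and absorbs the sustained plateau of biphasic responses.  The fit
window ends at 300 s (or the recording end) and shrinks until the normalized
RMSE of the fit drops below 10%.  Waveforms are classed monophasic or
biphasic by whether the decay sustains at or above half of peak amplitude.

Kinetic features are measured on the unfiltered normalized trace: the
threshold crossings are linearly interpolated and the decay fit is a least
squares average, both tolerant of the noise levels this pipeline targets,
whereas a zero-phase low-pass (available as :func:`lowpass`) rounds the rise
corners and acausally smears the onset.  The filter is used where a smooth
waveform genuinely helps: the monophasic/biphasic shape decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import butter, sosfiltfilt

from .errors import (
    InvalidParameterError,
    NormalizationError,
    UndefinedFeatureError,
)
from .stats import mean_sem

__all__ = [
    "CalciumTrace",
    "NormalizedTrace",
    "DecayFit",
    "TransientFeatures",
    "normalize_f_f0",
    "lowpass",
    "detect_response",
    "find_peak",
    "rise_time",
    "fit_decay",
    "compute_auc",
    "classify_phase",
    "extract_features",
    "extract_features_batch",
    "summarize_response_rates",
]

BASELINE_LEVEL = 1.0  # F/F0 over the baseline window is 1 by construction


@dataclass
class CalciumTrace:
    """One ROI fluorescence time series with its stimulus annotation."""

    time_s: np.ndarray
    f: np.ndarray
    stimulus_time_s: float = 20.0
    roi_id: str = "roi"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time_s.shape != self.f.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and f must be 1-D arrays of equal length")
        if self.time_s.size < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not self.time_s[0] <= self.stimulus_time_s <= self.time_s[-1]:
            raise ValueError("stimulus_time_s outside the recording")


@dataclass
class NormalizedTrace:
    """F/F0 trace; mean over the baseline window is 1 by construction."""

    time_s: np.ndarray
    f_over_f0: np.ndarray
    f0: float
    stimulus_time_s: float
    roi_id: str = "roi"
    metadata: dict = field(default_factory=dict)


@dataclass
class DecayFit:
    """Result of the exponential decay fit on the post-peak tail."""

    a: Optional[float]
    tau_s: Optional[float]
    offset: float
    fit_error: float  # RMSE / peak amplitude (normalized RMSE)
    t_end_s: float
    success: bool


@dataclass
class TransientFeatures:
    """Kinetic decomposition of one ROI trace; None fields are undefined."""

    roi_id: str
    responder: Optional[bool]
    latency_s: Optional[float] = None
    rise_time_s: Optional[float] = None
    peak_amplitude: Optional[float] = None
    peak_time_s: Optional[float] = None
    auc: Optional[float] = None
    decay_tau_s: Optional[float] = None
    decay_a: Optional[float] = None
    decay_offset: Optional[float] = None
    fit_error: Optional[float] = None
    t_end_s: Optional[float] = None
    phase: str = "none"  # monophasic | biphasic | none
    error: Optional[str] = None
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def normalize_f_f0(
    trace: CalciumTrace, baseline_window: tuple[float, float] = (0.0, 20.0)
) -> NormalizedTrace:
    """Divide fluorescence by the mean intensity over the pre-stimulus window."""
    t0, t1 = baseline_window
    sel = (trace.time_s >= t0) & (trace.time_s < t1)
    if sel.sum() < 2:
        raise NormalizationError("fewer than 2 samples in the baseline window")
    f0 = float(trace.f[sel].mean())
    if f0 <= 0:
        raise NormalizationError(f"non-positive baseline mean F0={f0}")
    return NormalizedTrace(
        time_s=trace.time_s.copy(),
        f_over_f0=trace.f / f0,
        f0=f0,
        stimulus_time_s=trace.stimulus_time_s,
        roi_id=trace.roi_id,
        metadata=dict(trace.metadata),
    )


def _resample_uniform(norm: NormalizedTrace) -> tuple[NormalizedTrace, float]:
    """Return a uniformly sampled copy (linear interpolation) and its interval."""
    dt_all = np.diff(norm.time_s)
    dt = float(np.median(dt_all))
    if np.ptp(dt_all) <= 1e-9 * dt:
        return norm, dt
    n = int(np.floor((norm.time_s[-1] - norm.time_s[0]) / dt)) + 1
    t_new = norm.time_s[0] + dt * np.arange(n)
    f_new = np.interp(t_new, norm.time_s, norm.f_over_f0)
    out = NormalizedTrace(
        t_new, f_new, norm.f0, norm.stimulus_time_s, norm.roi_id, dict(norm.metadata)
    )
    return out, dt


def lowpass(norm: NormalizedTrace, cutoff_hz: float = 0.2) -> NormalizedTrace:
    """Zero-phase second-order Butterworth low-pass; DC is preserved.

    Non-uniformly sampled traces are linearly resampled to their median
    interval first.  ``cutoff_hz`` must be below the Nyquist frequency.
    """
    uni, dt = _resample_uniform(norm)
    fs = 1.0 / dt
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz not in (0, Nyquist={fs / 2} Hz)"
        )
    sos = butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = min(3 * (2 * 2 + 1), uni.f_over_f0.size - 1)
    filtered = sosfiltfilt(sos, uni.f_over_f0, padlen=padlen)
    return NormalizedTrace(
        uni.time_s.copy(),
        filtered,
        uni.f0,
        uni.stimulus_time_s,
        uni.roi_id,
        dict(uni.metadata),
    )


# ---------------------------------------------------------------------------
# response detection and feature extraction
# ---------------------------------------------------------------------------


def _interp_crossing(t: np.ndarray, f: np.ndarray, level: float, i: int) -> float:
    """Time where f crosses ``level`` between samples i-1 and i (upward)."""
    if i == 0 or f[i - 1] > level:
        return float(t[i])
    if f[i] == f[i - 1]:
        return float(t[i])
    return float(t[i - 1] + (level - f[i - 1]) / (f[i] - f[i - 1]) * (t[i] - t[i - 1]))


def detect_response(
    norm: NormalizedTrace, *, k: float = 3.0, m: int = 3
) -> tuple[bool, Optional[float]]:
    """Decide whether a transient occurred and locate its onset.

    A trace responds when the post-stimulus signal exceeds (baseline mean +
    k * baseline SD) for at least ``m`` consecutive samples.  The onset is the
    threshold crossing, linearly interpolated between the last sub-threshold
    sample and the first sample of the excursion, clamped to the stimulus time.
    """
    t = norm.time_s
    f = norm.f_over_f0
    base = f[t < norm.stimulus_time_s]
    if base.size < 2:
        raise NormalizationError("no baseline samples before the stimulus")
    thr = float(base.mean() + k * base.std())
    post = np.flatnonzero(t >= norm.stimulus_time_s)
    above = f[post] > thr
    run = 0
    start = None
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= m:
            start = post[j - m + 1]
            break
    if start is None:
        return False, None
    onset = _interp_crossing(t, f, thr, int(start))
    return True, max(onset, float(norm.stimulus_time_s))


def find_peak(norm: NormalizedTrace, onset: float) -> tuple[int, float, float]:
    """First global maximum of F/F0 after onset: (index, time, value)."""
    sel = np.flatnonzero(norm.time_s >= onset)
    if sel.size == 0:
        raise UndefinedFeatureError("onset beyond the recording")
    i = int(sel[np.argmax(norm.f_over_f0[sel])])
    return i, float(norm.time_s[i]), float(norm.f_over_f0[i])


def rise_time(
    norm: NormalizedTrace, onset: float, peak_idx: Optional[int] = None
) -> float:
    """10% -> 90% rise time of the transient, crossings linearly interpolated.

    Amplitude is peak F/F0 minus the baseline level (1 by construction).
    """
    if peak_idx is None:
        peak_idx, _, _ = find_peak(norm, onset)
    t, f = norm.time_s, norm.f_over_f0
    amp = f[peak_idx] - BASELINE_LEVEL
    if amp <= 0:
        raise UndefinedFeatureError("non-positive amplitude; no rise to measure")
    lo = BASELINE_LEVEL + 0.1 * amp
    hi = BASELINE_LEVEL + 0.9 * amp
    i0 = int(np.searchsorted(t, onset))
    t10 = t90 = None
    for i in range(i0, peak_idx + 1):
        if t10 is None and f[i] >= lo:
            t10 = _interp_crossing(t, f, lo, i)
        if f[i] >= hi:
            t90 = _interp_crossing(t, f, hi, i)
            break
    if t10 is None or t90 is None:
        raise UndefinedFeatureError("could not locate 10%/90% crossings")
    return max(0.0, t90 - t10)


def fit_decay(
    norm: NormalizedTrace,
    peak_time: float,
    *,
    t_max: float = 300.0,
    error_tol: float = 0.10,
    tau_bound: float = 1e4,
    min_points: int = 5,
) -> DecayFit:
    """Fit a*exp(-t'/tau) + c to the baseline-subtracted tail after the peak.

    The window starts at the peak and ends at min(``t_max``, recording end).
    If the normalized RMSE (RMSE divided by peak amplitude) is >= ``error_tol``
    the window shrinks from the end until the error drops below tolerance,
    and the final window is reported.  A tau diverging beyond ``tau_bound`` or
    a vanishing decay amplitude raises the failure flag (tau absent).
    """
    t, f = norm.time_s, norm.f_over_f0
    sel = np.flatnonzero((t >= peak_time) & (t <= t_max))
    if sel.size < min_points:
        raise UndefinedFeatureError("fewer than 5 samples after the peak")
    tp = t[sel] - t[sel[0]]
    y = f[sel] - BASELINE_LEVEL
    amp = y[0] if y[0] > 0 else float(np.max(np.abs(y))) or 1.0

    def model(x, a, tau, c):
        return a * np.exp(-x / tau) + c

    def fit_window(n: int) -> tuple[Optional[tuple[float, float, float]], float]:
        xs, ys = tp[:n], y[:n]
        a0 = max(ys[0] - ys[-1], 1e-6)
        c0 = max(ys[-1], 0.0)
        tau0 = max((xs[-1] - xs[0]) / 3.0, 1e-3)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model,
                    xs,
                    ys,
                    p0=(a0, tau0, c0),
                    bounds=([0.0, 1e-3, 0.0], [np.inf, 1e6, np.inf]),
                    maxfev=5000,
                )
        except (RuntimeError, ValueError):
            return None, np.inf
        resid = ys - model(xs, *popt)
        nrmse = float(np.sqrt(np.mean(resid**2)) / amp)
        return (float(popt[0]), float(popt[1]), float(popt[2])), nrmse

    n = sel.size
    params, nrmse = fit_window(n)
    while nrmse >= error_tol:
        n_new = max(min_points, int(n * 0.9))
        if n_new == n:
            break
        n = n_new
        params, nrmse = fit_window(n)
    t_end = float(t[sel[0]] + tp[n - 1])
    if params is None:
        return DecayFit(None, None, 0.0, float(nrmse), t_end, False)
    a, tau, c = params
    if tau >= tau_bound or a < 1e-3 * amp:
        return DecayFit(None, None, c, float(nrmse), t_end, False)
    return DecayFit(a, tau, c, float(nrmse), t_end, True)


def compute_auc(norm: NormalizedTrace, onset: float, t_end: float) -> float:
    """Trapezoidal area of (F/F0 - baseline, clipped at 0) from onset to t_end."""
    if t_end <= onset:
        return 0.0
    t, f = norm.time_s, norm.f_over_f0
    grid = t[(t > onset) & (t < t_end)]
    ts = np.concatenate(([onset], grid, [t_end]))
    ys = np.clip(np.interp(ts, t, f) - BASELINE_LEVEL, 0.0, None)
    return float(np.trapezoid(ys, ts))


def classify_phase(
    norm: NormalizedTrace,
    peak_idx: int,
    t_end: float,
    *,
    d_sustain_s: float = 20.0,
) -> str:
    """Monophasic/biphasic decision on the decay shape.

    After the trace first falls to half of peak amplitude, a biphasic waveform
    stays at (or re-rises to) >= half amplitude for at least ``d_sustain_s``
    seconds; a waveform that never reaches half amplitude before ``t_end`` is
    sustained throughout and is biphasic provided the decay window itself is
    at least ``d_sustain_s`` long.
    """
    t, f = norm.time_s, norm.f_over_f0
    amp = f[peak_idx] - BASELINE_LEVEL
    if amp <= 0:
        raise UndefinedFeatureError("non-positive amplitude; no decay phase")
    half = BASELINE_LEVEL + 0.5 * amp
    sel = np.flatnonzero((t >= t[peak_idx]) & (t <= t_end))
    fs = f[sel]
    ts = t[sel]
    below = np.flatnonzero(fs <= half)
    if below.size == 0:
        # never decays to half-amplitude: sustained through the window
        return "biphasic" if (ts[-1] - ts[0]) >= d_sustain_s else "monophasic"
    start = below[0]
    # longest consecutive run at/above half amplitude after the first drop
    best = 0.0
    run_start = None
    for i in range(start, fs.size):
        if fs[i] >= half:
            if run_start is None:
                run_start = i
            best = max(best, ts[i] - ts[run_start])
        else:
            run_start = None
    return "biphasic" if best >= d_sustain_s else "monophasic"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def extract_features(
    trace: CalciumTrace,
    *,
    baseline_window: tuple[float, float] = (0.0, 20.0),
    cutoff_hz: float = 0.2,
    k: float = 3.0,
    m: int = 3,
    t_max: float = 300.0,
    error_tol: float = 0.10,
    d_sustain_s: float = 20.0,
) -> TransientFeatures:
    """Full kinetic decomposition of one trace; never raises.

    Non-responders short-circuit with phase ``"none"`` and absent kinetic
    fields; any stage failure is captured in the ``error`` field.
    """
    meta = dict(trace.metadata)
    try:
        if not np.all(np.isfinite(trace.f)):
            raise ValueError("trace contains non-finite samples")
        norm = normalize_f_f0(trace, baseline_window)
        responder, onset = detect_response(norm, k=k, m=m)
        if not responder:
            return TransientFeatures(
                trace.roi_id, False, phase="none", metadata=meta
            )
        peak_idx, peak_time, peak_val = find_peak(norm, onset)
        rt = rise_time(norm, onset, peak_idx)
        decay = fit_decay(
            norm, peak_time, t_max=t_max, error_tol=error_tol
        )
        auc = compute_auc(norm, onset, decay.t_end_s)
        try:
            smooth = lowpass(norm, cutoff_hz)
            sm_peak_idx, _, _ = find_peak(smooth, onset)
            phase = classify_phase(
                smooth, sm_peak_idx, decay.t_end_s, d_sustain_s=d_sustain_s
            )
        except InvalidParameterError:
            phase = classify_phase(norm, peak_idx, decay.t_end_s, d_sustain_s=d_sustain_s)
        return TransientFeatures(
            roi_id=trace.roi_id,
            responder=True,
            latency_s=max(0.0, onset - trace.stimulus_time_s),
            rise_time_s=rt,
            peak_amplitude=peak_val - BASELINE_LEVEL,
            peak_time_s=peak_time,
            auc=auc,
            decay_tau_s=decay.tau_s,
            decay_a=decay.a,
            decay_offset=decay.offset,
            fit_error=decay.fit_error,
            t_end_s=decay.t_end_s,
            phase=phase,
            metadata=meta,
        )
    except Exception as exc:  # noqa: BLE001 - per-trace diagnostics, not aborts
        return TransientFeatures(
            trace.roi_id, None, phase="none", error=str(exc), metadata=meta
        )


def extract_features_batch(
    traces: Iterable[CalciumTrace], **params
) -> list[TransientFeatures]:
    """Run :func:`extract_features` over a batch; corrupt traces are flagged."""
    return [extract_features(tr, **params) for tr in traces]


def summarize_response_rates(
    features: Sequence[TransientFeatures],
    by: Sequence[str] = ("div", "treatment"),
) -> pd.DataFrame:
    """Per-group response rates and mean +/- SEM of the kinetic features.

    Groups are formed from the listed ``metadata`` keys of each trace.  The
    percentage of non-responsive traces counts responder == False; traces that
    errored out are excluded from the denominator.  SEM is NaN for n = 1.
    """
    rows = []
    keyed: dict[tuple, list[TransientFeatures]] = {}
    for ft in features:
        key = tuple(ft.metadata.get(k, "") for k in by)
        keyed.setdefault(key, []).append(ft)
    feat_names = ("latency_s", "rise_time_s", "peak_amplitude", "auc", "decay_tau_s")
    for key in sorted(keyed):
        fts = [f for f in keyed[key] if f.responder is not None]
        if not fts:
            warnings.warn(f"group {key} has no analyzable traces; omitted")
            continue
        n = len(fts)
        n_non = sum(1 for f in fts if f.responder is False)
        row = dict(zip(by, key))
        row.update(
            n_traces=n,
            n_nonresponders=n_non,
            percent_nonresponsive=100.0 * n_non / n,
        )
        for name in feat_names:
            vals = [getattr(f, name) for f in fts if getattr(f, name) is not None]
            if vals:
                mean, sem, nn = mean_sem(vals)
                row[f"{name}_mean"] = mean
                row[f"{name}_sem"] = np.nan if sem is None else sem
                row[f"{name}_n"] = nn
            else:
                row[f"{name}_mean"] = np.nan
                row[f"{name}_sem"] = np.nan
                row[f"{name}_n"] = 0
        rows.append(row)
    return pd.DataFrame(rows)
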
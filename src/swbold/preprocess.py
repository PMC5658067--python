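"""Photometry trace preprocessing: downsampling, df/f, baseline, filtering.

The recording chain delivers raw fluorescence at 2 kHz; detection operates
on baseline-corrected, low-pass filtered df/f at 1 kHz. Baseline correction
estimates the slowly varying background in shifted windows of 2500 samples,
interpolates the window estimates with a spline and subtracts the result,
taking care that the suprathreshold calcium transients themselves do not
drag the estimate upward.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from swbold.types import CalciumTrace


def downsample_by_averaging(trace: CalciumTrace, factor: int) -> CalciumTrace:
    """Average ``factor`` adjacent samples (2 kHz -> 1 kHz with factor 2).

    Trailing samples that do not fill a complete group are dropped.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return trace.copy_with(trace.values.copy())
    if factor > trace.n_samples:
        raise ValueError("factor exceeds the trace length")
    n_out = trace.n_samples // factor
    vals = trace.values[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    return trace.copy_with(vals, fs_hz=trace.fs_hz / factor)


def _windowed_statistic(values: np.ndarray, window: int, stride: int, stat) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``stat`` to shifted windows; return (centers, estimates)."""
    n = values.size
    starts = np.arange(0, max(n - window, 0) + 1, stride)
    if starts.size == 0:
        starts = np.array([0])
    centers = np.minimum(starts + window, n) / 2.0 + starts / 2.0
    est = np.array([stat(values[s: s + window]) for s in starts])
    return centers, est


def _interpolate_baseline(centers: np.ndarray, est: np.ndarray, n: int) -> np.ndarray:
    """Monotone spline through the knots; linear beyond the knot range."""
    if centers.size == 1:
        return np.full(n, est[0])
    interp = PchipInterpolator(centers, est, extrapolate=False)
    x = np.arange(n, dtype=float)
    out = interp(x)
    deriv = interp.derivative()
    left = x < centers[0]
    right = x > centers[-1]
    out[left] = est[0] + float(deriv(centers[0])) * (x[left] - centers[0])
    out[right] = est[-1] + float(deriv(centers[-1])) * (x[right] - centers[-1])
    return out


def estimate_baseline(
    values: np.ndarray,
    window_samples: int = 2500,
    quantile: float = 0.10,
    refine: bool = True,
) -> np.ndarray:
    """Slowly varying baseline of a trace carrying positive-going transients.

    In each shifted window (stride = half a window) the estimate is the
    median of the *floor cohort*: the samples within twice the
    sample-to-sample noise scale of the window's low quantile (default
    10th percentile). Positive-going transients and their decay tails lie
    far above the floor and are excluded; windows whose floor cohort
    covers less than 20% of the window (the window sits inside a
    transient) contribute no knot and are bridged by the monotone spline.
    The estimator is translation-equivariant, so repeated application is
    idempotent up to interpolation error. If almost no window exposes a
    floor (e.g. a noiseless drifting trace, where the cohort degenerates
    to the quantile itself), the baseline falls back to the median in long
    windows (ten times ``window_samples``), which tracks slow drift but
    cannot follow individual transients.
    """
    n = values.size
    window = int(min(window_samples, n))
    stride = max(1, window // 2)
    if not refine:
        centers, est = _windowed_statistic(
            values, window, stride, lambda w: np.quantile(w, quantile)
        )
        return _interpolate_baseline(centers, est, n)

    d = np.diff(values)
    # sample-to-sample noise scale: first differences are insensitive to
    # transients and slow structure
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    iqr = np.quantile(values, 0.75) - np.quantile(values, 0.25)
    eps = 1e-9 + 1e-6 * iqr   # tolerance for exactly-flat (noiseless) floors

    def floor_estimate(w: np.ndarray) -> tuple[float, float]:
        lo = np.quantile(w, quantile)
        cohort = w <= lo + 2.0 * sigma + eps
        return float(np.median(w[cohort])), float(cohort.mean())

    starts = np.arange(0, max(n - window, 0) + 1, stride)
    if starts.size == 0:
        starts = np.array([0])
    knots_x, knots_y = [], []
    for s in starts:
        w = values[s: min(s + window, n)]
        est, frac = floor_estimate(w)
        if frac < 0.2:
            continue
        # a decaying transient tail moves between the window halves; a
        # genuine baseline floor does not
        half = w.size // 2
        m1, _ = floor_estimate(w[:half])
        m2, _ = floor_estimate(w[half:])
        if abs(m1 - m2) > 2.0 * sigma + eps:
            continue
        knots_x.append(s + w.size / 2.0)
        knots_y.append(est)

    # coarse long-window median: tracks slow drift, blind to transients;
    # anchors the trace ends (so the spline never extrapolates far) and
    # serves as fallback when no window exposes a quiescent floor
    w_long = int(min(10 * window, n))
    c0, e0 = _windowed_statistic(values, w_long, max(1, w_long // 2), np.median)
    if len(knots_x) < 2:
        return _interpolate_baseline(c0, e0, n)
    coarse = _interpolate_baseline(c0, e0, n)
    if knots_x[0] > stride:
        offset = coarse[0] - (coarse[int(knots_x[0])] - knots_y[0])
        knots_x.insert(0, 0.0)
        knots_y.insert(0, float(offset))
    if knots_x[-1] < n - 1 - stride:
        offset = coarse[n - 1] - (coarse[int(knots_x[-1])] - knots_y[-1])
        knots_x.append(float(n - 1))
        knots_y.append(float(offset))
    return _interpolate_baseline(np.asarray(knots_x), np.asarray(knots_y), n)


def baseline_correct(trace: CalciumTrace, window_samples: int = 2500,
                     quantile: float = 0.10) -> CalciumTrace:
    """Subtract the windowed-spline baseline estimate from the trace."""
    if window_samples >= trace.n_samples:
        raise ValueError("baseline window must be shorter than the trace")
    baseline = estimate_baseline(trace.values, window_samples, quantile)
    return trace.copy_with(trace.values - baseline)


def compute_dff(trace: CalciumTrace, baseline_window_s: float = 30.0,
                quantile: float = 0.10) -> CalciumTrace:
    """Convert raw fluorescence to df/f against a rolling low-percentile f0."""
    if trace.units != "raw":
        raise ValueError("compute_dff expects a raw-fluorescence trace")
    window = int(max(2, round(baseline_window_s * trace.fs_hz)))
    window = min(window, trace.n_samples)
    f0 = estimate_baseline(trace.values, window, quantile)
    if np.any(f0 <= 0):
        raise ValueError("baseline fluorescence f0 is non-positive; cannot form df/f")
    return trace.copy_with((trace.values - f0) / f0, units="dff")


def lowpass_filter(trace: CalciumTrace, cutoff_hz: float = 100.0,
                   order: int = 4) -> CalciumTrace:
    """Zero-phase (forward-backward) Butterworth low-pass with unit DC gain."""
    nyq = trace.fs_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = sps.butter(order, cutoff_hz / nyq, btype="low", output="sos")
    vals = sps.sosfiltfilt(sos, trace.values)
    return trace.copy_with(vals)


def standard_preprocess(trace: CalciumTrace, downsample_factor: int = 2,
                        baseline_window: int = 2500,
                        lowpass_cutoff_hz: float = 100.0) -> CalciumTrace:
    """Acquisition-to-detection chain: 2 kHz -> 1 kHz, baseline, low-pass."""
    out = downsample_by_averaging(trace, downsample_factor)
    out = baseline_correct(out, baseline_window)
    return lowpass_filter(out, lowpass_cutoff_hz)
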
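"""EMA-filter slow-wave detection and per-wave quantification.

Detection separates slow-wave events from network quiescence on the
preprocessed 1 kHz trace: an exponential moving average (25 ms window)
smooths the signal, an onset threshold at 70% of a robust reference
amplitude marks wave starts, and segments end where the signal drops below
50% of that threshold. Three post-processing rules follow, in order:

1. segments separated by less than 100 ms are merged into one wave,
2. waves shorter than 600 ms are discarded,
3. waves whose peak does not reach the 90% point of the cumulative
   amplitude histogram of the whole filtered trace are discarded.

Because the EMA is tuned for onsets, terminations can optionally be
re-anchored to the noise level (last sample above baseline + 2 sigma before
the signal stays below that level for 50 ms).

Wave parameters are measured per the conventions of population calcium
recordings: rise time is onset-to-half-maximum, duration the full width at
half maximum, amplitude the df/f difference between the pre-onset baseline
(200 ms) and the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from swbold.types import CalciumTrace, EventArray, SlowWaveVector


@dataclass
class DetectionConfig:
    """Parameters of the EMA slow-wave detector."""

    ema_window_ms: float = 25.0
    onset_threshold_frac: float = 0.70
    termination_frac_of_threshold: float = 0.50
    merge_gap_ms: float = 100.0
    min_duration_ms: float = 600.0
    intensity_percentile: float = 0.90
    reference_percentile: float = 0.95
    noise_refine: bool = True
    refine_persistence_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.onset_threshold_frac <= 1:
            raise ValueError("onset threshold fraction must lie in (0, 1]")
        if not 0 < self.termination_frac_of_threshold <= 1:
            raise ValueError("termination fraction must lie in (0, 1]")
        for name in ("ema_window_ms", "merge_gap_ms", "min_duration_ms",
                     "refine_persistence_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.intensity_percentile < 1:
            raise ValueError("intensity percentile must lie in (0, 1)")
        if not 0 < self.reference_percentile < 1:
            raise ValueError("reference percentile must lie in (0, 1)")


def ema_filter(trace: CalciumTrace, window_ms: float = 25.0) -> CalciumTrace:
    """Recursive exponential moving average, y_t = a*x_t + (1-a)*y_{t-1}.

    ``a = 2/(N+1)`` with ``N`` the window in samples; ``y_0 = x_0``.
    """
    n_win = max(1, int(round(window_ms * trace.fs_hz / 1000.0)))
    alpha = 2.0 / (n_win + 1)
    x = trace.values
    y, _ = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], x,
                       zi=np.array([(1.0 - alpha) * x[0]]))
    return trace.copy_with(y)


def compute_threshold(trace: CalciumTrace,
                      config: DetectionConfig | None = None) -> tuple[float, float]:
    """Onset and termination thresholds from the amplitude histogram.

    The reference amplitude is a high percentile (default 95th) of the
    baseline-corrected, EMA-filtered samples: the upper edge of the bulk of
    the amplitude histogram, insensitive both to single-sample artifacts and
    to how much of the recording the decay tails of individual waves occupy.
    The onset threshold is 70% of that reference; the termination threshold
    is 50% of the onset threshold.
    """
    config = config or DetectionConfig()
    v = trace.values
    if np.ptp(v) == 0:
        raise ValueError("no dynamic range: the trace is constant")
    reference = float(np.quantile(v, config.reference_percentile))
    if reference <= 0:
        raise ValueError("no dynamic range: non-positive reference amplitude")
    onset_thr = config.onset_threshold_frac * reference
    term_thr = config.termination_frac_of_threshold * onset_thr
    return onset_thr, term_thr


def _raw_segments(values: np.ndarray, onset_thr: float,
                  term_thr: float) -> list[tuple[int, int]]:
    """Hysteresis segmentation: up-cross of onset_thr to down-cross of term_thr.

    Returns half-open sample index pairs (start, stop).
    """
    above_on = values >= onset_thr
    starts_all = np.flatnonzero(above_on & ~np.concatenate([[False], above_on[:-1]]))
    below_term = np.flatnonzero(values < term_thr)
    segments: list[tuple[int, int]] = []
    pos = 0
    for s in starts_all:
        if segments and s < segments[-1][1]:
            continue
        pos = np.searchsorted(below_term, s)
        stop = below_term[pos] if pos < below_term.size else values.size
        segments.append((int(s), int(stop)))
    return segments


def postprocess_events(raw: EventArray, trace: CalciumTrace,
                       config: DetectionConfig | None = None) -> EventArray:
    """Apply the merge / minimum-duration / intensity rules, in that order.

    ``trace`` must be the EMA-filtered trace the segments were detected on.
    The intensity rule keeps a wave only if its peak reaches the
    ``intensity_percentile`` point of the cumulative amplitude histogram of
    the whole filtered trace, discarding low-intensity activity.
    """
    config = config or DetectionConfig()
    if raw.n_events == 0:
        return raw
    onsets = raw.onsets_s.copy()
    ends = raw.ends_s.copy()

    # (1) merge waves separated by less than merge_gap_ms (strict <)
    gap = config.merge_gap_ms / 1000.0
    m_on, m_end = [onsets[0]], [ends[0]]
    for o, e in zip(onsets[1:], ends[1:]):
        if o - m_end[-1] < gap - 1e-12:
            m_end[-1] = e
        else:
            m_on.append(o)
            m_end.append(e)
    onsets, ends = np.asarray(m_on), np.asarray(m_end)

    # (2) discard waves shorter than min_duration_ms (strict <)
    keep = (ends - onsets) >= config.min_duration_ms / 1000.0 - 1e-12
    onsets, ends = onsets[keep], ends[keep]

    # (3) discard activity below the cumulative-histogram intensity point.
    # The cutoff is capped at the onset threshold: a wave that crossed 70%
    # of the reference maximum already belongs to the signal population, so
    # the histogram rule acts as a floor on weak activity admitted at
    # permissive thresholds (e.g. during threshold calibration scans)
    # rather than cutting into the detected waves themselves.
    if onsets.size:
        cutoff = float(np.quantile(trace.values, config.intensity_percentile))
        try:
            onset_thr, _ = compute_threshold(trace, config)
            cutoff = min(cutoff, onset_thr)
        except ValueError:
            pass
        fs, t0 = trace.fs_hz, trace.t0_s
        peaks = np.array([
            trace.values[int(round((o - t0) * fs)): max(int(round((e - t0) * fs)), int(round((o - t0) * fs)) + 1)].max()
            for o, e in zip(onsets, ends)
        ])
        keep = peaks >= cutoff
        onsets, ends = onsets[keep], ends[keep]

    if onsets.size == 0:
        return EventArray.empty(raw.session_duration_s)
    return EventArray(onsets, ends - onsets, raw.session_duration_s)


def estimate_noise_sd(trace: CalciumTrace, events: EventArray,
                      pre_pad_s: float = 0.5, post_pad_s: float = 6.0) -> float:
    """Robust noise SD from event-free portions of the trace.

    Samples within any event (padded backward by ``pre_pad_s`` and forward by
    ``post_pad_s`` to exclude rise feet and decay tails) are masked out; the
    spread of the remainder is the MAD-based sigma of its first differences,
    which is insensitive to residual slow structure. Falls back to the whole
    trace if masking leaves too little data.
    """
    mask = np.ones(trace.n_samples, dtype=bool)
    fs, t0 = trace.fs_hz, trace.t0_s
    for o, e in zip(events.onsets_s, events.ends_s):
        i0 = max(0, int((o - pre_pad_s - t0) * fs))
        i1 = min(trace.n_samples, int((e + post_pad_s - t0) * fs))
        mask[i0:i1] = False
    vals = trace.values[mask] if mask.sum() > 100 else trace.values
    d = np.diff(vals)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def refine_terminations(events: EventArray, trace: CalciumTrace,
                        noise_sd: float, baseline: float = 0.0,
                        persistence_ms: float = 50.0) -> EventArray:
    """Re-anchor terminations to the noise level.

    Each event ends at the last sample exceeding ``baseline + 2*noise_sd``
    before the signal first stays below that level for ``persistence_ms``.
    Terminations are clamped to the next event onset and the session end, so
    the output never overlaps.
    """
    if events.n_events == 0 or noise_sd <= 0:
        return events
    level = baseline + 2.0 * noise_sd
    fs, t0 = trace.fs_hz, trace.t0_s
    n = trace.n_samples
    pers = max(1, int(round(persistence_ms / 1000.0 * fs)))
    new_ends = []
    next_onsets = np.append(events.onsets_s[1:], events.session_duration_s)
    for o, e, nxt in zip(events.onsets_s, events.ends_s, next_onsets):
        i0 = max(0, int(round((o - t0) * fs)))
        limit = min(n, int(round((nxt - t0) * fs)))
        x = trace.values[i0:limit]
        below = x < level
        # first run of >= pers consecutive below-level samples (or a run
        # that persists to the window end)
        run = 0
        j_end = None
        for j, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= pers:
                j_end = j - pers + 1
                break
        if j_end is None:
            if run > 0 and below[-1]:
                j_end = len(below) - run
            else:
                j_end = len(below)
        new_end = (i0 + j_end) / fs + t0
        new_ends.append(min(max(new_end, o + 1.0 / fs), nxt))
    new_ends = np.asarray(new_ends)
    return EventArray(events.onsets_s, new_ends - events.onsets_s,
                      events.session_duration_s)


def detect_events(trace: CalciumTrace,
                  config: DetectionConfig | None = None) -> EventArray:
    """Detect slow-wave events on a preprocessed (1 kHz) trace.

    The trace is EMA-filtered, thresholds are computed from its amplitude
    histogram, hysteresis segmentation yields raw segments and the three
    post-processing rules are applied. If ``config.noise_refine`` is set,
    terminations are then corrected with regard to the noise level,
    estimated from the event-free trace portions.
    """
    config = config or DetectionConfig()
    filt = ema_filter(trace, config.ema_window_ms)
    onset_thr, term_thr = compute_threshold(filt, config)
    segments = _raw_segments(filt.values, onset_thr, term_thr)
    T = trace.duration_s
    if not segments:
        return EventArray.empty(T)
    fs, t0 = trace.fs_hz, trace.t0_s
    onsets = np.array([t0 + s / fs for s, _ in segments])
    ends = np.minimum(np.array([t0 + e / fs for _, e in segments]), T)
    raw = EventArray(onsets, ends - onsets, T)
    events = postprocess_events(raw, filt, config)
    if config.noise_refine and events.n_events:
        noise_sd = estimate_noise_sd(trace, events)
        events = refine_terminations(events, trace, noise_sd,
                                     persistence_ms=config.refine_persistence_ms)
    return events


def calibrate_threshold(trace: CalciumTrace, bold, candidate_fracs,
                        config: DetectionConfig | None = None,
                        alpha: float = 0.05) -> float:
    """Pick the onset-threshold fraction at the inflection of the voxel-count curve.

    For each candidate fraction, events are detected, binarized to TR
    resolution, an FIR design is fitted voxel-wise and the suprathreshold
    voxels (F-test over all bins, p < ``alpha``) are counted. The returned
    fraction maximizes the discrete second difference of the count curve; a
    flat curve falls back to the 0.70 default with a warning.
    """
    from swbold.glm import f_test, fit_glm
    from swbold.hrf import FIRConfig, build_fir_design

    config = config or DetectionConfig()
    fracs = np.asarray(list(candidate_fracs), dtype=float)
    if fracs.size < 4:
        raise ValueError("need >=4 candidate fractions for a second difference")
    counts = []
    for frac in fracs:
        cfg = replace(config, onset_threshold_frac=float(frac))
        try:
            events = detect_events(trace, cfg)
        except ValueError:
            counts.append(0)
            continue
        if events.n_events == 0:
            counts.append(0)
            continue
        sw = binarize_to_tr(events, bold.tr_s, bold.n_volumes)
        if sw.onset_volumes.size == 0:
            counts.append(0)
            continue
        design = build_fir_design(sw, FIRConfig())
        glm = fit_glm(bold, design.matrix,
                      regressor_names=[f"fir_{i}" for i in range(design.matrix.shape[1])])
        _, p_map = f_test(glm, np.arange(design.matrix.shape[1]))
        counts.append(int((p_map[glm.mask] < alpha).sum()))
    counts = np.asarray(counts, dtype=float)
    if np.ptp(counts) == 0:
        warnings.warn("voxel-count curve is flat; falling back to the 0.70 default")
        return 0.70
    d2 = counts[2:] - 2 * counts[1:-1] + counts[:-2]
    return float(fracs[int(np.argmax(d2)) + 1])


def binarize_to_tr(events: EventArray, tr_s: float, n_volumes: int) -> SlowWaveVector:
    """Mark every volume whose acquisition interval overlaps an event.

    Volume ``v`` covers the half-open interval ``[v*tr, (v+1)*tr)``.
    """
    if events.n_events and events.ends_s.max() > n_volumes * tr_s + 1e-9:
        raise ValueError("events extend beyond the BOLD session")
    bins = np.zeros(n_volumes, dtype=np.int8)
    for o, e in zip(events.onsets_s, events.ends_s):
        if e <= o:
            continue
        v0 = int(np.floor(o / tr_s))
        v1 = int(np.ceil(e / tr_s))
        bins[v0: min(v1, n_volumes)] = 1
    return SlowWaveVector(bins, tr_s)


def event_frequency(events: EventArray, bin_s: float = 100.0) -> tuple[np.ndarray, float]:
    """Per-bin event frequencies (Hz) and the session mean in events/min.

    The session is split into complete bins of ``bin_s`` (a trailing
    incomplete bin is ignored); the frequency in each bin is the event count
    divided by the bin duration.
    """
    if events.session_duration_s < bin_s:
        raise ValueError("session shorter than one frequency bin")
    n_bins = int(events.session_duration_s // bin_s)
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(events.onsets_s, bins=edges)
    freqs_hz = counts / bin_s
    return freqs_hz, float(freqs_hz.mean() * 60.0)


def _fit_rise_line(values: np.ndarray, i_peak: int, base: float,
                   amp: float) -> tuple[float, float] | None:
    """Least-squares line through the 20-80% portion of the rising flank.

    Returns (slope per sample, intercept at sample 0 of ``values``).
    """
    i80 = i_peak
    while i80 > 0 and values[i80] > base + 0.8 * amp:
        i80 -= 1
    i20 = i80
    while i20 > 0 and values[i20] > base + 0.2 * amp:
        i20 -= 1
    if i80 - i20 < 1:
        return None
    xs = np.arange(i20, i80 + 1)
    slope, intercept = np.polyfit(xs, values[i20: i80 + 1], 1)
    if slope <= 0:
        return None
    return float(slope), float(intercept)


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def quantify_wave_params(events: EventArray, trace: CalciumTrace,
                         baseline_ms: float = 200.0) -> pd.DataFrame:
    """Per-wave rise time, duration and amplitude.

    Rise time is the interval from the transient onset to the half-maximum
    crossing; duration the interval between the first and last value
    exceeding half maximum; amplitude the df/f difference between the
    pre-onset baseline (mean of the 200 ms preceding the estimated onset)
    and the peak. The transient onset is recovered by fitting a line to the
    20-80% portion of the rising flank and extrapolating it down to the
    baseline level (the detector's threshold crossing sits partway up the
    flank and is not the physiological onset).

    Returns a DataFrame with one row per event; waves on which the
    measurement is degenerate are flagged rather than dropped.
    """
    fs, t0 = trace.fs_hz, trace.t0_s
    v = trace.values
    n = v.size
    base_n = max(1, int(round(baseline_ms / 1000.0 * fs)))
    rows = []
    next_onsets = np.append(events.onsets_s[1:], trace.t0_s + trace.duration_s)
    for k, (o, e) in enumerate(zip(events.onsets_s, events.ends_s)):
        i_on = max(0, int(round((o - t0) * fs)))
        i_end = min(n, max(int(round((e - t0) * fs)), i_on + 1))
        row = {"event": k, "onset_s": np.nan, "rise_time_ms": np.nan,
               "duration_ms": np.nan, "amplitude_dff": np.nan,
               "peak_time_s": np.nan, "baseline_dff": np.nan, "flagged": True}
        if i_end - i_on < 2:
            warnings.warn(f"event {k} shorter than 2 samples; skipped")
            rows.append(row)
            continue
        i_pk = i_on + int(np.argmax(v[i_on:i_end]))
        v_pk = v[i_pk]

        # rough pre-event baseline well clear of the rising foot
        rb1 = max(0, i_on - int(round(0.70 * fs)))
        rb2 = max(rb1 + 1, i_on - int(round(0.45 * fs)))
        rough_base = float(np.median(v[rb1:rb2]))
        amp_rough = v_pk - rough_base
        if amp_rough <= 0:
            row["amplitude_dff"] = 0.0
            rows.append(row)
            continue

        fit = _fit_rise_line(v, i_pk, rough_base, amp_rough)
        if fit is None:
            rows.append(row)
            continue
        slope, intercept = fit

        # transient onset: rising line extrapolated to the local baseline,
        # iterated once so the baseline window precedes the estimated onset
        onset_idx = (rough_base - intercept) / slope
        b1 = max(0, int(round(onset_idx)) - base_n)
        b2 = max(b1 + 1, int(round(onset_idx)))
        baseline = float(np.mean(v[b1:b2]))
        onset_idx = (baseline - intercept) / slope
        amp = v_pk - baseline
        if amp <= 0:
            row["amplitude_dff"] = 0.0
            rows.append(row)
            continue
        half = baseline + 0.5 * amp

        # first half-max crossing on the rising flank
        i = i_pk
        while i > 0 and v[i - 1] >= half:
            i -= 1
        if v[i] >= half and i > 0:
            t_rise = _interp_crossing((i - 1) / fs, v[i - 1], i / fs, v[i], half)
        else:
            t_rise = i / fs

        # last half-max crossing on the falling flank (cap at next onset);
        # the signal must stay below half maximum for 25 ms so that single
        # noise dips on the slow decay do not truncate the measured width
        limit = min(n, int(round((next_onsets[k] - t0) * fs)))
        pers = max(1, int(round(0.025 * fs)))
        seg = v[i_pk:limit] < half
        run = 0
        j_run = None
        for jj, b in enumerate(seg):
            run = run + 1 if b else 0
            if run >= pers:
                j_run = jj - pers + 1
                break
        if j_run is None and run > 0:
            j_run = seg.size - run
        if j_run is not None and j_run > 0:
            j = i_pk + j_run
            t_fall = _interp_crossing((j - 1) / fs, v[j - 1], j / fs, v[j], half)
        else:
            t_fall = (limit - 1) / fs

        row.update(
            onset_s=t0 + onset_idx / fs,
            rise_time_ms=(t_rise - onset_idx / fs) * 1000.0,
            duration_ms=(t_fall - t_rise) * 1000.0,
            amplitude_dff=amp,
            peak_time_s=t0 + i_pk / fs,
            baseline_dff=baseline,
            flagged=False,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def match_events(detected: EventArray, truth: EventArray,
                 tol_s: float = 0.5) -> tuple[int, int, int]:
    """Greedy onset matching; returns (n_matched, n_detected, n_truth)."""
    used = np.zeros(truth.n_events, dtype=bool)
    matched = 0
    for o in detected.onsets_s:
        diffs = np.abs(truth.onsets_s - o)
        diffs[used] = np.inf
        if diffs.size and diffs.min() <= tol_s:
            used[int(np.argmin(diffs))] = True
            matched += 1
    return matched, detected.n_events, truth.n_events
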
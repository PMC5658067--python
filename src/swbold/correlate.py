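"""Specificity controls and correlation-based mapping.

Two controls probe whether BOLD activation is specifically tied to the
detected slow-wave timing: time-mirroring the event array (same number of
events, same duration and interval statistics, different timing) and
swapping event arrays between sessions. Seed-based maps correlate a
region's mean timecourse with every target voxel; the calcium-informed map
correlates each voxel's event-locked mean response with a reference
response from an ROI, thresholds at r > 0.8, removes clusters below 70
voxels and derives a time-to-peak parameter map. Cluster extent uses
26-connectivity in 3-D.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from swbold.types import BoldSession, CalciumTrace, CorrelationMap, EventArray

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def mirror_events(events: EventArray) -> EventArray:
    """Reflect the event array in time: (onset, d) -> (T - onset - d, d)."""
    if events.n_events == 0:
        return EventArray.empty(events.session_duration_s)
    T = events.session_duration_s
    onsets = T - events.onsets_s - events.durations_s
    order = np.argsort(onsets)
    return EventArray(onsets[order], events.durations_s[order], T)


def swap_events(events_from_other: EventArray,
                target_session_length_s: float) -> EventArray:
    """Re-validate another session's events against a target session length.

    Events starting beyond the target length are dropped; an event
    straddling the end is clipped (both with a warning).
    """
    T = target_session_length_s
    keep = events_from_other.onsets_s < T
    if not keep.any():
        raise ValueError("all events lie beyond the target session")
    if not keep.all():
        warnings.warn("events beyond the target session length were dropped")
    onsets = events_from_other.onsets_s[keep]
    ends = np.minimum(events_from_other.ends_s[keep], T)
    if np.any(events_from_other.ends_s[keep] > T):
        warnings.warn("an event straddling the session end was clipped")
    return EventArray(onsets, ends - onsets, T)


def _clusters_from_mask(mask: np.ndarray, min_cluster: int) -> tuple[list[dict], np.ndarray]:
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    clusters = []
    out = np.zeros_like(mask, dtype=bool)
    for lab in range(1, n + 1):
        idx = np.flatnonzero(labels.ravel() == lab)
        if idx.size >= min_cluster:
            clusters.append({"voxels": idx, "size": int(idx.size)})
            out.ravel()[idx] = True
    return clusters, out


def filter_clusters(mask: np.ndarray, min_cluster: int) -> np.ndarray:
    """Keep only 26-connected components with at least ``min_cluster`` voxels."""
    _, out = _clusters_from_mask(np.asarray(mask, dtype=bool), min_cluster)
    return out


def seed_correlation_map(bold: BoldSession, seed_mask: np.ndarray,
                         target_mask: np.ndarray | None = None,
                         r_thresh: float = 0.5,
                         min_cluster: int = 300) -> CorrelationMap:
    """Pearson correlation of the seed-mean timecourse with every target voxel.

    Suprathreshold voxels (r > ``r_thresh``) are grouped into 26-connected
    clusters and clusters below ``min_cluster`` voxels are discarded.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.sum() == 0:
        raise ValueError("empty seed mask")
    if target_mask is None:
        target_mask = bold.brain_mask
    target_mask = np.asarray(target_mask, dtype=bool)

    seed_tc = bold.data[seed_mask].mean(axis=0)
    if np.std(seed_tc) == 0:
        raise ValueError("seed timecourse has zero variance")

    Y = bold.data[target_mask]                            # (V, T)
    sc = (seed_tc - seed_tc.mean()) / seed_tc.std()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1)
    sd = np.where(sd == 0, np.inf, sd)
    r = (Yc @ sc) / (sd * sc.size)

    r_volume = np.full(bold.grid_shape, np.nan)
    r_volume[target_mask] = r
    supra = np.zeros(bold.grid_shape, dtype=bool)
    supra[target_mask] = r > r_thresh
    clusters, supra_filtered = _clusters_from_mask(supra, min_cluster)
    return CorrelationMap(r_volume, r_thresh, clusters, supra_filtered)


def event_locked_responses(bold: BoldSession, events: EventArray,
                           window_s: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mean response over post-onset windows.

    Returns (times, responses) where responses has shape
    (n_lags, x, y, z); events whose window runs past the session end are
    skipped. Responses are baseline-subtracted per event (value at onset).
    """
    tr = bold.tr_s
    n_lags = int(round(window_s / tr)) + 1
    onset_vols = np.floor(events.onsets_s / tr).astype(int)
    onset_vols = onset_vols[onset_vols + n_lags <= bold.n_volumes]
    if onset_vols.size == 0:
        raise ValueError("no events with a complete post-onset window")
    acc = np.zeros((n_lags,) + bold.grid_shape)
    for v0 in onset_vols:
        seg = bold.data[..., v0: v0 + n_lags]
        acc += np.moveaxis(seg - seg[..., :1], -1, 0)
    acc /= onset_vols.size
    return np.arange(n_lags) * tr, acc


def calcium_informed_map(bold: BoldSession, events: EventArray,
                         roi_mask: np.ndarray, r_thresh: float = 0.8,
                         min_cluster: int = 70, window_s: float = 20.0,
                         baseline_window_s: float = 100.0,
                         ) -> tuple[CorrelationMap, np.ndarray]:
    """Correlate each voxel's event-locked response with an ROI reference.

    The BOLD series is first baseline-corrected per voxel with a 100 s
    window. The reference is the mean event-locked response over
    ``roi_mask``; every voxel's event-locked response is correlated with
    it, the map is thresholded at r > ``r_thresh`` and clusters below
    ``min_cluster`` voxels are removed. For surviving voxels a time-to-peak
    volume (time of the maximum of the event-locked response) is returned.
    """
    if events.n_events < 5:
        raise ValueError("insufficient events (<5) for a calcium-informed map")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("empty ROI mask")

    corrected = baseline_correct_bold(bold, baseline_window_s)
    times, resp = event_locked_responses(corrected, events, window_s)
    ref = resp[:, roi_mask].mean(axis=1)
    if np.std(ref) == 0:
        raise ValueError("reference response has zero variance")

    R = resp.reshape(resp.shape[0], -1)
    refc = (ref - ref.mean()) / ref.std()
    Rc = R - R.mean(axis=0, keepdims=True)
    sd = R.std(axis=0)
    sd = np.where(sd == 0, np.inf, sd)
    r = (refc @ Rc) / (sd * ref.size)
    r_volume = r.reshape(bold.grid_shape)

    supra = r_volume > r_thresh
    clusters, supra_filtered = _clusters_from_mask(supra, min_cluster)
    cmap = CorrelationMap(r_volume, r_thresh, clusters, supra_filtered)

    ttp = np.full(bold.grid_shape, np.nan)
    idx = np.argmax(resp, axis=0)
    ttp[supra_filtered] = times[idx[supra_filtered]]
    return cmap, ttp


def baseline_correct_bold(bold: BoldSession, window_s: float = 100.0) -> BoldSession:
    """Per-voxel slow-baseline removal (windowed low quantile + spline)."""
    from swbold.preprocess import estimate_baseline

    window = max(4, int(round(window_s / bold.tr_s)))
    flat = bold.data.reshape(-1, bold.n_volumes)
    out = np.empty_like(flat)
    for i, ts in enumerate(flat):
        out[i] = ts - estimate_baseline(ts, window, refine=False)
    return BoldSession(out.reshape(bold.data.shape), bold.tr_s,
                       bold.voxel_size_mm, bold.brain_mask, bold.n_discarded)


def regress_out(bold: BoldSession, covariates: np.ndarray) -> BoldSession:
    """Remove covariate timecourses from every voxel by linear projection.

    Covariates are mean-centered; each voxel's residual after projection
    onto them (plus an implicit intercept) replaces its timecourse, so the
    voxel mean is preserved.
    """
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != bold.n_volumes:
        C = C.T
    if C.shape[0] != bold.n_volumes:
        raise ValueError("covariate length does not match the session")
    C = C - C.mean(axis=0)
    if bold.highpass_cutoff_s is not None:
        from swbold.glm import dct_highpass_basis

        K = dct_highpass_basis(bold.n_volumes, bold.tr_s, bold.highpass_cutoff_s)
        if K is not None:
            C = C - K @ (K.T @ C)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("collinear covariates")
    flat = bold.data.reshape(-1, bold.n_volumes).T        # (T, V)
    beta, *_ = np.linalg.lstsq(C, flat, rcond=None)
    resid = flat - C @ beta
    return BoldSession(resid.T.reshape(bold.data.shape), bold.tr_s,
                       bold.voxel_size_mm, bold.brain_mask, bold.n_discarded)


def cross_correlate(a: np.ndarray | CalciumTrace, b: np.ndarray | CalciumTrace,
                    max_lag_s: float, fs_hz: float | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalized cross-correlation at integer-sample lags within +-max_lag.

    Returns (lags_s, r, peak_lag_s, peak_r). Positive lag means ``b``
    trails ``a``. Pearson r is computed on the overlapping samples at each
    lag.
    """
    if isinstance(a, CalciumTrace):
        fs_hz = a.fs_hz
        a = a.values
    if isinstance(b, CalciumTrace):
        fs_hz = fs_hz or b.fs_hz
        b = b.values
    if fs_hz is None:
        raise ValueError("sampling rate required for array inputs")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input")
    max_lag = int(round(max_lag_s * fs_hz))
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: a.size - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: b.size + lag]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            r[i] = np.nan
            continue
        r[i] = np.corrcoef(x, y)[0, 1]
    k = int(np.nanargmax(np.abs(r)))
    return lags / fs_hz, r, float(lags[k] / fs_hz), float(r[k])
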
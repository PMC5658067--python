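"""Model-free hemodynamic-response extraction and quantification.

The response to a slow-wave onset is estimated with a finite impulse
response (FIR) basis: 40 time bins of one TR, spanning 20 s before to 20 s
after each onset, yield one beta map per bin without assuming a response
shape. The mean response of the 30 most active voxels (10 per slice in the
most active slice and its two neighbors, by F-value) is the session's
hemodynamic response (HR). HRs from the *other* sessions are averaged,
truncated to 0-15 s and peak-normalized to serve as the convolution kernel
for the event-related GLM -- the leave-n-out construction that avoids
circular analysis. HRs are summarized by time-to-peak (TTP), normalized
peak amplitude (dSA) and half-maximum duration (HMD), optionally through a
gamma-variate fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import gamma as gamma_dist

from swbold.types import (
    BoldSession,
    GammaVariateParams,
    GlmResult,
    HemodynamicResponse,
    HrQuant,
    SlowWaveVector,
)


@dataclass
class FIRConfig:
    """FIR basis layout: 40 bins x 1 s covering -20 s ... +20 s."""

    n_bins: int = 40
    bin_s: float = 1.0
    window_start_s: float = -20.0
    response_support_s: tuple[float, float] = (0.0, 15.0)

    def __post_init__(self) -> None:
        if self.n_bins <= 0 or self.bin_s <= 0:
            raise ValueError("n_bins and bin_s must be positive")

    @property
    def bin_times_s(self) -> np.ndarray:
        return self.window_start_s + np.arange(self.n_bins) * self.bin_s


@dataclass
class FIRDesign:
    matrix: np.ndarray           # (n_volumes, n_bins)
    bin_times_s: np.ndarray
    onset_volumes: np.ndarray
    config: FIRConfig = field(repr=False, default=None)


def build_fir_design(sw: SlowWaveVector, config: FIRConfig | None = None,
                     onset_volumes: np.ndarray | None = None) -> FIRDesign:
    """Indicator design matrix: column j is one at volume v iff an event
    onset occurred at volume ``v - offset_j`` (offsets span the FIR window).

    Onsets default to the starts of runs of ones in the slow-wave vector;
    pass ``onset_volumes`` explicitly when event durations are long enough
    that consecutive events' marked volumes touch (run starts would then
    undercount the onsets).
    """
    config = config or FIRConfig()
    if abs(config.bin_s - sw.tr_s) > 1e-9:
        raise ValueError("FIR bin width must equal the TR of the slow-wave vector")
    onsets = sw.onset_volumes if onset_volumes is None else np.asarray(onset_volumes, dtype=int)
    if onsets.size == 0:
        raise ValueError("slow-wave vector contains no events")
    T = sw.n_volumes
    X = np.zeros((T, config.n_bins))
    offsets = np.round(config.bin_times_s / config.bin_s).astype(int)
    for j, off in enumerate(offsets):
        rows = onsets + off
        rows = rows[(rows >= 0) & (rows < T)]
        X[rows, j] = 1.0
    return FIRDesign(X, config.bin_times_s.copy(), onsets, config)


def fit_fir(bold: BoldSession, design: FIRDesign, ar1: str | float = "auto") -> GlmResult:
    """Per-voxel least squares of the FIR design (betas in % signal change).

    Thin wrapper around the GLM fit; raises on a rank-deficient design,
    naming the collinear bins.
    """
    from swbold.glm import fit_glm

    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.T)
        bad = [
            (i, j)
            for i in range(X.shape[1])
            for j in range(i + 1, X.shape[1])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient FIR design; collinear bin pairs: {bad[:5]}")
    names = [f"fir[{t:+.0f}s]" for t in design.bin_times_s]
    return fit_glm(bold, X, ar1=ar1, regressor_names=names)


def select_top_voxels(f_map: np.ndarray, p_map: np.ndarray,
                      n_per_slice: int = 10, alpha: float = 0.05,
                      exclusion_mask: np.ndarray | None = None) -> np.ndarray:
    """The 30 most active voxels: 10 per slice around the most active slice.

    The slice (last axis) with the most suprathreshold voxels (p < alpha)
    anchors the selection; the ``n_per_slice`` highest-F suprathreshold
    voxels are taken from it and from each neighboring slice. Excluded
    voxels (e.g. a sinus-vein mask) are skipped; ties break by ascending
    linear index. Returns an (n, 3) array of voxel indices.
    """
    if exclusion_mask is None:
        exclusion_mask = np.zeros(f_map.shape, dtype=bool)
    eligible = (p_map < alpha) & ~exclusion_mask & np.isfinite(f_map)
    if not eligible.any():
        raise ValueError("no active voxels above threshold")
    per_slice = eligible.reshape(-1, f_map.shape[2]).sum(axis=0)
    z_anchor = int(np.argmax(per_slice))
    picks = []
    for z in (z_anchor - 1, z_anchor, z_anchor + 1):
        if not 0 <= z < f_map.shape[2]:
            continue
        xs, ys = np.nonzero(eligible[:, :, z])
        if xs.size == 0:
            continue
        fvals = f_map[xs, ys, z]
        lin = xs * f_map.shape[1] + ys
        order = np.lexsort((lin, -fvals))
        if xs.size < n_per_slice:
            warnings.warn(
                f"slice {z}: only {xs.size} eligible voxels (< {n_per_slice})"
            )
        take = order[:n_per_slice]
        picks.extend((int(xs[i]), int(ys[i]), z) for i in take)
    return np.asarray(picks, dtype=int)


def extract_mean_hr(glm: GlmResult, design: FIRDesign,
                    voxels: np.ndarray) -> HemodynamicResponse:
    """Average the per-voxel FIR beta series and subtract the pre-onset baseline.

    The baseline is the mean of the bins covering the 5 s preceding onset.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    if voxels.size == 0:
        raise ValueError("need at least one voxel")
    flat_mask = np.flatnonzero(glm.mask.ravel())
    lin = np.ravel_multi_index(tuple(voxels.T), glm.mask.shape)
    pos = np.searchsorted(flat_mask, lin)
    if np.any(flat_mask[np.minimum(pos, flat_mask.size - 1)] != lin):
        raise ValueError("selected voxels fall outside the GLM mask")
    # row 0 of the GLM betas is the intercept; FIR bins follow
    n_bins = design.bin_times_s.size
    series = glm.betas[1: n_bins + 1, :][:, pos].mean(axis=1)
    times = design.bin_times_s
    base_bins = (times >= -5.0) & (times < 0.0)
    baseline = series[base_bins].mean() if base_bins.any() else 0.0
    return HemodynamicResponse(times_s=times, values=series - baseline)


def assemble_leave_n_out_hrf(hrs: list[HemodynamicResponse], held_out: int,
                             support_s: tuple[float, float] = (0.0, 15.0),
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Average the HRs of all sessions except ``held_out``.

    The average is truncated to the response support (0-15 s, i.e. until
    the timecourses have returned to baseline) and normalized to unit peak
    for use as a convolution kernel. Requires at least two sessions --
    using a session's own HR on itself would be circular.
    """
    if len(hrs) < 2:
        raise ValueError("need >=2 sessions for a leave-n-out HRF (circularity)")
    if not 0 <= held_out < len(hrs):
        raise ValueError(f"held-out index {held_out} out of range")
    others = [hr for i, hr in enumerate(hrs) if i != held_out]
    times = others[0].times_s
    for hr in others[1:]:
        if not np.allclose(hr.times_s, times):
            raise ValueError("HRs are on different time grids")
    mean = np.mean([hr.values for hr in others], axis=0)
    keep = (times >= support_s[0] - 1e-9) & (times <= support_s[1] + 1e-9)
    t, v = times[keep], mean[keep]
    peak = v.max()
    if peak <= 0:
        raise ValueError("leave-n-out HR has a non-positive peak")
    return t, v / peak


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> tuple[np.ndarray, np.ndarray]:
    """The standard canonical HRF: difference of two gamma densities.

    Response peak at 6 s, undershoot at 16 s, undershoot ratio 1/6, unit
    dispersion; sampled at the TR and normalized to unit peak.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return t, h / h.max()


def _gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float,
                   amp: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > t0
    x = (t[pos] - t0) / (alpha * beta)
    out[pos] = amp * np.power(x, alpha) * np.exp(alpha - (t[pos] - t0) / beta)
    return out


def fit_gamma_variate(hr: HemodynamicResponse,
                      fit_window_s: tuple[float, float] = (0.0, 20.0),
                      smooth_points: int = 1,
                      ) -> tuple[GammaVariateParams, float]:
    """Nonlinear least squares of the unit-peak gamma-variate model.

    ``y(t) = amp * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)``
    for ``t > t0``, zero before; the model peak is ``amp`` at
    ``t0 + alpha*beta``. A small moving average (``smooth_points`` bins) can
    be applied before fitting, as is common for noisy per-event
    timecourses; the default leaves the FIR estimate untouched since FIR
    betas are already event averages. Multi-start over shape/onset grids;
    returns the parameters and r-squared over the fit window.
    """
    times, values = hr.times_s, hr.values.copy()
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        values = np.convolve(values, kernel, mode="same")
    sel = (times >= fit_window_s[0] - 1e-9) & (times <= fit_window_s[1] + 1e-9)
    t, y = times[sel], values[sel]
    if t.size < 5:
        raise ValueError("HR must cover the response window (>=5 bins)")
    peak = y.max()
    if peak <= 0:
        raise ValueError("cannot fit a gamma variate to a non-positive response")
    ttp0 = float(t[int(np.argmax(y))])

    def residuals(p):
        return _gamma_variate(t, *p) - y

    lo = [-5.0, 0.3, 0.01, peak * 1e-3]
    hi = [max(ttp0 - 0.05, -4.9 + 1e-6), 100.0, 50.0, peak * 10.0]
    best, best_cost = None, np.inf
    for alpha0 in (1.5, 3.0, 6.0, 12.0):
        for t0_0 in (0.0, min(1.0, max(ttp0 - 0.5, 0.0)), -1.0):
            t0_0 = min(max(t0_0, lo[0] + 1e-6), hi[0] - 1e-6)
            beta0 = max((ttp0 - t0_0) / alpha0, 0.02)
            p0 = [t0_0, alpha0, min(beta0, 49.0), peak]
            try:
                res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
            except ValueError:
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
    if best is None:
        raise RuntimeError("gamma-variate fit failed to converge from any start")
    t0_f, alpha_f, beta_f, amp_f = best.x
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return GammaVariateParams(t0_s=float(t0_f), alpha=float(alpha_f),
                              beta_s=float(beta_f), amp=float(amp_f)), float(r2)


def quantify_hr(hr: HemodynamicResponse | None = None,
                fit: GammaVariateParams | None = None,
                support_s: tuple[float, float] = (0.0, 20.0)) -> HrQuant:
    """TTP, dSA and HMD of a hemodynamic response.

    With a gamma-variate ``fit``, the descriptors come from the fitted
    curve evaluated densely (TTP = t0 + alpha*beta, dSA = fitted peak, HMD
    interpolated at half maximum). Otherwise they are read from the
    discrete response: the peak is refined with a three-point parabola and
    the half-maximum crossings are linearly interpolated. A non-positive
    peak leaves the descriptors undefined (flagged).
    """
    if fit is not None:
        dt = 0.005
        t = np.arange(support_s[0], support_s[1] + dt, dt)
        y = fit(t)
        peak = y.max()
        if peak <= 0:
            return HrQuant(np.nan, np.nan, np.nan, fit.t0_s, defined=False)
        ttp = fit.time_to_peak_s
        hmd = _width_at_level(t, y, peak / 2.0)
        return HrQuant(float(ttp), float(fit.amp), float(hmd), float(fit.t0_s))

    if hr is None:
        raise ValueError("provide a response or a fit")
    sel = (hr.times_s >= support_s[0] - 1e-9) & (hr.times_s <= support_s[1] + 1e-9)
    t, y = hr.times_s[sel], hr.values[sel]
    i_pk = int(np.argmax(y))
    if y[i_pk] <= 0:
        return HrQuant(np.nan, np.nan, np.nan, defined=False)
    if 0 < i_pk < y.size - 1:
        # parabola through the three samples around the discrete maximum
        y0, y1, y2 = y[i_pk - 1: i_pk + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
        dt = t[i_pk] - t[i_pk - 1]
        ttp = t[i_pk] + shift * dt
        dsa = y1 - 0.25 * (y0 - y2) * shift
    else:
        ttp, dsa = float(t[i_pk]), float(y[i_pk])
    hmd = _width_at_level(t, y, dsa / 2.0)
    return HrQuant(float(ttp), float(dsa), float(hmd))


def _width_at_level(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Interpolated width of the main lobe of ``y`` at ``level``."""
    i_pk = int(np.argmax(y))
    left = t[0]
    for i in range(i_pk, 0, -1):
        if y[i - 1] < level <= y[i]:
            left = t[i - 1] + (level - y[i - 1]) * (t[i] - t[i - 1]) / (y[i] - y[i - 1])
            break
    right = t[-1]
    for i in range(i_pk, y.size - 1):
        if y[i] >= level > y[i + 1]:
            right = t[i] + (y[i] - level) * (t[i + 1] - t[i]) / (y[i] - y[i + 1])
            break
    return float(right - left)
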
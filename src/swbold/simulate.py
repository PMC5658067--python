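"""Synthetic paired calcium + BOLD recordings with known ground truth.

The generator emulates fiber-photometry recordings of slow
oscillation-associated calcium waves under isoflurane anesthesia --
stereotyped transients (sharp linear rise, exponential decay) separated by
network quiescence, riding on slow baseline drift and white photon noise --
and simultaneously acquired whole-brain BOLD in which a contiguous
"cortical" compartment carries the event train convolved with a
gamma-variate hemodynamic response, plus scanner drift and temporally
autocorrelated (AR(1)) noise.

Default wave statistics follow in-vivo population recordings with OGB-1:
~10.9 events/min, onset-to-half-max rise 72 ms, half-max duration 1356 ms,
peak amplitude 2.6 df/f. A GCaMP6f preset differs only in its slower rise
kinetics (163 ms). Amplitudes, rise times and durations vary from wave to
wave (log-normal, with the coefficients of variation implied by the
published spread), since that variability is part of the measurement
problem the detector has to cope with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from swbold.types import BoldSession, CalciumTrace, EventArray, GammaVariateParams

LN2 = math.log(2.0)

#: Half-max wave duration shared by both indicators (ms).
WAVE_DURATION_MS = 1356.0
#: Mean peak amplitude shared by both indicators (df/f).
WAVE_AMPLITUDE_DFF = 2.6
#: In-scanner mean slow-wave rate (events/min).
EVENT_RATE_PER_MIN = 10.9


def decay_tau_for_duration(duration_ms: float, rise_time_ms: float) -> float:
    """Exponential decay constant giving a target half-max duration.

    The wave rises linearly to its peak over ``2 * rise_time_ms`` (so the
    onset-to-half-max interval is ``rise_time_ms`` by construction) and then
    decays as ``exp(-t/tau)``; the width at half maximum is therefore
    ``rise_time_ms + tau * ln 2``.
    """
    if duration_ms <= rise_time_ms:
        raise ValueError("duration must exceed the rise time")
    return (duration_ms - rise_time_ms) / LN2


@dataclass
class CalciumSimConfig:
    """Ground-truth parameters for a simulated photometry session."""

    duration_s: float = 1800.0
    fs_hz: float = 2000.0
    event_rate_per_min: float = EVENT_RATE_PER_MIN
    isi_model: str = "poisson_with_refractory"
    refractory_s: float = 3.0
    rise_time_ms: float = 72.0
    decay_tau_ms: float = decay_tau_for_duration(WAVE_DURATION_MS, 72.0)
    amplitude_dff: float = WAVE_AMPLITUDE_DFF
    amplitude_cv: float = 0.2
    rise_cv: float = 0.3
    duration_cv: float = 0.3
    drift_amplitude: float = 0.3
    drift_period_s: float = 240.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.event_rate_per_min < 0 or self.refractory_s < 0:
            raise ValueError("rate and refractory period must be non-negative")
        if self.amplitude_dff <= 0 or self.rise_time_ms <= 0 or self.decay_tau_ms <= 0:
            raise ValueError("waveform parameters must be positive")
        if self.isi_model != "poisson_with_refractory":
            raise ValueError(f"unknown ISI model {self.isi_model!r}")
        if self.event_rate_per_min > 0:
            mean_isi = 60.0 / self.event_rate_per_min
            if mean_isi <= self.refractory_s:
                raise ValueError(
                    f"event rate {self.event_rate_per_min}/min implies a mean "
                    f"inter-event interval of {mean_isi:.2f} s, not compatible "
                    f"with the {self.refractory_s:.2f} s refractory period"
                )

    @property
    def mean_duration_ms(self) -> float:
        """Planted mean half-max wave duration."""
        return self.rise_time_ms + self.decay_tau_ms * LN2


def preset(name: str, **overrides) -> CalciumSimConfig:
    """Indicator presets: ``"ogb1"`` (rise 72 ms) or ``"gcamp6f"`` (163 ms)."""
    name = name.lower()
    if name == "ogb1":
        rise = 72.0
    elif name == "gcamp6f":
        rise = 163.0
    else:
        raise ValueError(f"unknown preset {name!r}")
    cfg = CalciumSimConfig(
        rise_time_ms=rise,
        decay_tau_ms=decay_tau_for_duration(WAVE_DURATION_MS, rise),
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class CalciumSimResult:
    """Simulated trace plus the planted ground truth."""

    trace: CalciumTrace
    truth_events: EventArray          # onsets at ramp start, half-max durations
    amplitudes_dff: np.ndarray        # per-wave peak amplitude
    rise_times_ms: np.ndarray         # per-wave onset-to-half-max interval
    durations_ms: np.ndarray          # per-wave half-max duration
    config: CalciumSimConfig = field(repr=False, default=None)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal samples parameterized by their arithmetic mean and CV."""
    if cv <= 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _sample_onsets(rng: np.random.Generator, cfg: CalciumSimConfig) -> np.ndarray:
    if cfg.event_rate_per_min == 0:
        return np.empty(0)
    mean_isi = 60.0 / cfg.event_rate_per_min
    exp_mean = mean_isi - cfg.refractory_s
    onsets = []
    t = 0.0
    while True:
        t += cfg.refractory_s + rng.exponential(exp_mean)
        if t >= cfg.duration_s:
            break
        onsets.append(t)
    return np.asarray(onsets)


def simulate_calcium_trace(config: CalciumSimConfig,
                           onsets_s: np.ndarray | None = None) -> CalciumSimResult:
    """Render a photometry trace with planted slow-wave transients.

    Each wave is a linear ramp from 0 to its peak over ``2 * rise_time``
    followed by an exponential decay; waves superpose linearly on a
    sinusoidal drift and white Gaussian noise. Deterministic given
    ``config.seed``. If ``onsets_s`` is given, waves are planted at exactly
    those times instead of sampling the renewal process (for experiments
    that fix the per-session event count).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    n = int(round(config.duration_s * fs))
    values = np.zeros(n)

    if onsets_s is None:
        onsets = _sample_onsets(rng, config)
    else:
        onsets = np.sort(np.asarray(onsets_s, dtype=float))
        if onsets.size and (onsets[0] < 0 or onsets[-1] >= config.duration_s):
            raise ValueError("planted onsets outside the session")
    amps = _lognormal(rng, config.amplitude_dff, config.amplitude_cv, onsets.size)
    rises_ms = _lognormal(rng, config.rise_time_ms, config.rise_cv, onsets.size)
    mean_dur = config.mean_duration_ms
    durs_ms = _lognormal(rng, mean_dur, config.duration_cv, onsets.size)
    # keep the half-max duration under the refractory period so planted
    # events never overlap (resampling clips <1% of the log-normal tail)
    if config.refractory_s > 0:
        cap = config.refractory_s * 1000.0 * 0.98
        for _ in range(20):
            bad = durs_ms >= cap
            if not bad.any():
                break
            durs_ms[bad] = _lognormal(rng, mean_dur, config.duration_cv, int(bad.sum()))
        durs_ms = np.minimum(durs_ms, cap)
    durs_ms = np.maximum(durs_ms, rises_ms * 1.2)

    keep = onsets + durs_ms / 1000.0 <= config.duration_s
    onsets, amps, rises_ms, durs_ms = (a[keep] for a in (onsets, amps, rises_ms, durs_ms))

    taus_s = (durs_ms - rises_ms) / LN2 / 1000.0
    for onset, amp, rise_ms, tau in zip(onsets, amps, rises_ms, taus_s):
        i0 = int(round(onset * fs))
        ramp_n = max(2, int(round(2.0 * rise_ms / 1000.0 * fs)))
        i_peak = min(i0 + ramp_n, n)
        t_rel = (np.arange(i0, i_peak) - i0) / (ramp_n - 1)
        values[i0:i_peak] += amp * t_rel
        decay_n = int(round(9.5 * tau * fs))  # render until < 1e-4 of the peak
        i_end = min(i_peak + decay_n, n)
        if i_end > i_peak:
            t_dec = (np.arange(i_peak, i_end) - i_peak + 1) / fs
            values[i_peak:i_end] += amp * np.exp(-t_dec / tau)

    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        values += config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period_s + phase
        )
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=n)

    trace = CalciumTrace(values=values, fs_hz=fs, units="dff")
    events = (
        EventArray(onsets, durs_ms / 1000.0, config.duration_s)
        if onsets.size
        else EventArray.empty(config.duration_s)
    )
    return CalciumSimResult(trace, events, amps, rises_ms, durs_ms, config)


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

#: Published hemodynamic response to a slow-wave onset: time-to-peak 6.5 s,
#: peak amplitude 0.17 % signal change, half-maximum duration 6.8 s, with a
#: short (~0.7 s) onset latency.
HR_TTP_S = 6.5
HR_AMP_PCT = 0.17
HR_HMD_S = 6.8
HR_ONSET_S = 0.7


def gamma_variate_from_shape(
    ttp_s: float, hmd_s: float, t0_s: float = HR_ONSET_S, amp: float = HR_AMP_PCT
) -> GammaVariateParams:
    """Gamma-variate parameters matching a target peak time and half width.

    With the unit-peak parameterization the peak sits at ``t0 + alpha*beta``
    and the full width at half maximum scales as ``(ttp - t0) * du(alpha)``
    where ``du`` shrinks monotonically with the shape parameter; ``alpha`` is
    solved by bisection.
    """
    peak_lag = ttp_s - t0_s
    if peak_lag <= 0 or hmd_s <= 0:
        raise ValueError("need ttp > t0 and a positive half width")

    def du(alpha: float) -> float:
        target = -LN2 / alpha

        def g(u: float) -> float:
            return math.log(u) + 1.0 - u - target

        u_lo = brentq(g, 1e-9, 1.0 - 1e-12)
        u_hi = brentq(g, 1.0 + 1e-12, 60.0)
        return u_hi - u_lo

    def objective(alpha: float) -> float:
        return peak_lag * du(alpha) - hmd_s

    alpha = brentq(objective, 0.05, 500.0, xtol=1e-10)
    return GammaVariateParams(t0_s=t0_s, alpha=alpha, beta_s=peak_lag / alpha, amp=amp)


def default_hrf_params() -> GammaVariateParams:
    return gamma_variate_from_shape(HR_TTP_S, HR_HMD_S, HR_ONSET_S, HR_AMP_PCT)


@dataclass
class BoldSimConfig:
    """Ground-truth parameters for a simulated BOLD session."""

    grid_shape: tuple[int, int, int] = (12, 12, 5)
    n_volumes: int = 1200
    tr_s: float = 1.0
    voxel_size_mm: tuple[float, float, float] = (0.35, 0.325, 1.2)
    cortical_mask_fraction: float = 0.4
    hrf_params: GammaVariateParams = field(default_factory=default_hrf_params)
    response_amplitude_pct: float = HR_AMP_PCT
    noise_sd_pct: float = 0.5
    ar1_coeff: float = 0.3
    drift_amplitude_pct: float = 0.5
    drift_period_s: float = 300.0
    event_model: str = "impulse"   # {"impulse", "boxcar"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 45:
            raise ValueError("need more than 45 volumes (discarded scans + FIR window)")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if not 0.0 < self.cortical_mask_fraction <= 1.0:
            raise ValueError("cortical fraction must lie in (0, 1]")
        if self.event_model not in ("impulse", "boxcar"):
            raise ValueError(f"unknown event model {self.event_model!r}")


@dataclass
class BoldSimResult:
    session: BoldSession
    cortical_mask: np.ndarray
    kernel: np.ndarray           # HRF sampled at TR, peak = response_amplitude_pct
    config: BoldSimConfig = field(repr=False, default=None)


def sample_hrf_kernel(params: GammaVariateParams, tr_s: float,
                      peak_pct: float | None = None,
                      support_s: float = 32.0) -> np.ndarray:
    """Sample the gamma-variate response at TR resolution, unit-peak scaled."""
    t = np.arange(0.0, support_s + tr_s / 2, tr_s)
    h = params(t)
    if h.max() <= 0:
        raise ValueError("HRF kernel is non-positive on the requested support")
    h = h / h.max()
    return h * (params.amp if peak_pct is None else peak_pct)


def _ar1_noise(rng: np.random.Generator, rho: float, sd: float,
               shape: tuple[int, int]) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_volumes, n_voxels), marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, sd * math.sqrt(1.0 - rho * rho), size=shape)
    if rho == 0:
        return eps
    x0 = rng.normal(0.0, sd, size=(1, shape[1]))
    out, _ = sps.lfilter([1.0], [1.0, -rho], eps, axis=0, zi=rho * x0)
    return out


def cortical_slab_mask(grid_shape: tuple[int, int, int], fraction: float) -> np.ndarray:
    """Contiguous dorsal slab covering ``fraction`` of the voxel grid."""
    nx, ny, nz = grid_shape
    n_rows = max(1, int(round(fraction * ny)))
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, :n_rows, :] = True
    return mask


def simulate_bold_session(config: BoldSimConfig, events: EventArray) -> BoldSimResult:
    """Render a 4-D BOLD session driven by the planted slow-wave events.

    Cortical voxels carry the event train convolved with the gamma-variate
    response (an isolated event peaks at exactly
    ``response_amplitude_pct`` percent signal change); all voxels receive
    scanner drift and AR(1) noise around a written baseline of 100.
    """
    T = config.n_volumes
    duration = T * config.tr_s
    if events.n_events and events.ends_s.max() > duration + 1e-9:
        raise ValueError("events extend beyond the session duration")

    rng = np.random.default_rng(config.seed)
    mask = cortical_slab_mask(config.grid_shape, config.cortical_mask_fraction)
    n_vox = int(np.prod(config.grid_shape))

    neural = np.zeros(T)
    if events.n_events:
        onset_vols = np.floor(events.onsets_s / config.tr_s).astype(int)
        if config.event_model == "impulse":
            np.add.at(neural, onset_vols, 1.0)
        else:
            from swbold.detect import binarize_to_tr

            neural = binarize_to_tr(events, config.tr_s, T).bins.astype(float)

    kernel = sample_hrf_kernel(config.hrf_params, config.tr_s,
                               peak_pct=config.response_amplitude_pct)
    signal_pct = np.convolve(neural, kernel)[:T]

    t = np.arange(T) * config.tr_s
    drift = config.drift_amplitude_pct * np.sin(
        2 * np.pi * t / config.drift_period_s + rng.uniform(0, 2 * np.pi)
    )

    noise = _ar1_noise(rng, config.ar1_coeff, config.noise_sd_pct, (T, n_vox))
    data = 100.0 + noise + drift[:, None]
    data[:, mask.ravel()] += signal_pct[:, None]
    data = data.T.reshape(config.grid_shape + (T,))

    session = BoldSession(
        data=data,
        tr_s=config.tr_s,
        voxel_size_mm=config.voxel_size_mm,
    )
    return BoldSimResult(session, mask, kernel, config)
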
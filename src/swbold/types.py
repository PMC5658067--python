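"""Shared domain containers for calcium traces, events and BOLD sessions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalciumTrace:
    """Uniformly sampled photometry signal.

    Parameters
    ----------
    values : np.ndarray
        Signal samples, either raw fluorescence (arbitrary units) or
        relative fluorescence change df/f (unitless).
    fs_hz : float
        Sampling rate in samples per second.
    t0_s : float
        Time of the first sample, seconds.
    units : str
        ``"raw"`` or ``"dff"``.
    """

    values: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    units: str = "dff"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.units not in ("raw", "dff"):
            raise ValueError(f"unknown units flag {self.units!r}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, values: np.ndarray, fs_hz: float | None = None,
                  units: str | None = None) -> "CalciumTrace":
        return CalciumTrace(
            values=np.asarray(values, dtype=float),
            fs_hz=self.fs_hz if fs_hz is None else fs_hz,
            t0_s=self.t0_s,
            units=self.units if units is None else units,
        )


@dataclass
class EventArray:
    """Detected (or planted) slow-wave events as onsets + durations, seconds.

    Events are non-overlapping: ``onset[i] + duration[i] <= onset[i+1]``, all
    contained in ``[0, session_duration_s]``.
    """

    onsets_s: np.ndarray
    durations_s: np.ndarray
    session_duration_s: float

    def __post_init__(self) -> None:
        self.onsets_s = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        self.durations_s = np.atleast_1d(np.asarray(self.durations_s, dtype=float))
        if self.onsets_s.shape != self.durations_s.shape:
            raise ValueError("onsets and durations must have equal length")
        if self.session_duration_s <= 0:
            raise ValueError("session duration must be positive")
        if self.n_events:
            if np.any(self.durations_s < 0):
                raise ValueError("durations must be non-negative")
            if np.any(np.diff(self.onsets_s) <= 0):
                raise ValueError("onsets must be strictly increasing")
            ends = self.onsets_s + self.durations_s
            if np.any(ends[:-1] > self.onsets_s[1:] + 1e-9):
                raise ValueError("events overlap")
            if self.onsets_s[0] < -1e-9 or ends[-1] > self.session_duration_s + 1e-6:
                raise ValueError("events outside the session")

    @property
    def n_events(self) -> int:
        return self.onsets_s.size

    @property
    def ends_s(self) -> np.ndarray:
        return self.onsets_s + self.durations_s

    @classmethod
    def empty(cls, session_duration_s: float) -> "EventArray":
        return cls(np.empty(0), np.empty(0), session_duration_s)


@dataclass
class SlowWaveVector:
    """Binary per-volume event indicator at TR resolution."""

    bins: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int8)
        if self.bins.ndim != 1:
            raise ValueError("bins must be 1-D")
        if not np.all((self.bins == 0) | (self.bins == 1)):
            raise ValueError("bins must be binary")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.bins.size

    @property
    def onset_volumes(self) -> np.ndarray:
        """Volumes at which a run of ones begins (event onsets)."""
        padded = np.concatenate([[0], self.bins])
        return np.flatnonzero(np.diff(padded) == 1)


@dataclass
class BoldSession:
    """4-D BOLD time series with acquisition geometry.

    ``data`` is indexed ``(x, y, z, volume)`` in scanner units.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (0.35, 0.325, 1.2)
    brain_mask: np.ndarray | None = None
    n_discarded: int = 0
    #: cutoff of the high-pass filter already applied to the data, if any;
    #: model regressors are passed through the same filter
    highpass_cutoff_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, volume)")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match the voxel grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def masked_timeseries(self) -> np.ndarray:
        """Return (n_volumes, n_mask_voxels) view of the in-mask data."""
        return self.data[self.brain_mask].T


@dataclass
class HemodynamicResponse:
    """Event-locked BOLD response on FIR time bins.

    ``values`` are percent signal change relative to the pre-onset baseline
    (mean of the 5 s preceding the event onset).
    """

    times_s: np.ndarray
    values: np.ndarray
    baseline_window_s: tuple[float, float] = (-5.0, 0.0)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HR values must be finite")


@dataclass
class GammaVariateParams:
    """Parameters of the unit-peak gamma-variate response model.

    ``y(t) = amp * ((t - t0)/(alpha*beta))**alpha * exp(alpha - (t - t0)/beta)``
    for ``t > t0`` and zero before; the peak of ``y`` is ``amp`` at
    ``t0 + alpha*beta``.
    """

    t0_s: float
    alpha: float
    beta_s: float
    amp: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def time_to_peak_s(self) -> float:
        return self.t0_s + self.alpha * self.beta_s

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > self.t0_s
        x = (t[pos] - self.t0_s) / (self.alpha * self.beta_s)
        out[pos] = self.amp * np.power(x, self.alpha) * np.exp(
            self.alpha - (t[pos] - self.t0_s) / self.beta_s
        )
        return out


@dataclass
class HrQuant:
    """Scalar hemodynamic-response descriptors.

    ttp_s : time from event onset to the response peak.
    dsa_pct : peak amplitude (percent signal change over pre-onset baseline).
    hmd_s : full width of the response at half of ``dsa_pct``.
    onset_latency_s : fitted response onset (gamma-variate t0), if available.
    """

    ttp_s: float
    dsa_pct: float
    hmd_s: float
    onset_latency_s: float = float("nan")
    defined: bool = True


@dataclass
class GlmResult:
    """Per-voxel GLM fit over a masked 3-D grid."""

    betas: np.ndarray            # (n_regressors, n_mask_voxels), % signal change
    sigma2: np.ndarray           # residual variance per voxel (whitened scale)
    df_resid: int
    design: np.ndarray           # whitened design, (n_volumes, n_regressors)
    xtx_inv: np.ndarray
    mask: np.ndarray             # boolean volume
    rho: float                   # pooled AR(1) coefficient used for whitening
    regressor_names: list[str] = field(default_factory=list)
    _yw: np.ndarray | None = None  # whitened % data, for extra-SS F tests

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def map_from_vector(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3-D volume."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = vec
        return out


@dataclass
class CorrelationMap:
    """Voxelwise Pearson correlation with threshold + cluster bookkeeping."""

    r_volume: np.ndarray
    threshold: float
    clusters: list[dict]
    supra_mask: np.ndarray

    def __post_init__(self) -> None:
        finite = self.r_volume[np.isfinite(self.r_volume)]
        if finite.size and (finite.min() < -1.000001 or finite.max() > 1.000001):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)
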
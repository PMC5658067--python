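"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from swbold.detect import DetectionConfig
from swbold.hrf import FIRConfig
from swbold.simulate import BoldSimConfig, CalciumSimConfig, preset


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalciumSimSection(_Section):
    preset: str = "ogb1"
    duration_s: float = 1800.0
    event_rate_per_min: float = 10.9
    refractory_s: float = 3.0
    noise_sd: float = 0.05
    drift_amplitude: float = 0.3
    amplitude_cv: float = 0.2

    def to_config(self, seed: int) -> CalciumSimConfig:
        return preset(
            self.preset,
            duration_s=self.duration_s,
            event_rate_per_min=self.event_rate_per_min,
            refractory_s=self.refractory_s,
            noise_sd=self.noise_sd,
            drift_amplitude=self.drift_amplitude,
            amplitude_cv=self.amplitude_cv,
            seed=seed,
        )


class BoldSimSection(_Section):
    grid_shape: tuple[int, int, int] = (12, 12, 5)
    n_volumes: int = 1200
    tr_s: float = 1.0
    cortical_mask_fraction: float = 0.4
    response_amplitude_pct: float = 0.17
    noise_sd_pct: float = 0.5
    ar1_coeff: float = 0.3
    drift_amplitude_pct: float = 0.5

    def to_config(self, seed: int) -> BoldSimConfig:
        return BoldSimConfig(
            grid_shape=tuple(self.grid_shape),
            n_volumes=self.n_volumes,
            tr_s=self.tr_s,
            cortical_mask_fraction=self.cortical_mask_fraction,
            response_amplitude_pct=self.response_amplitude_pct,
            noise_sd_pct=self.noise_sd_pct,
            ar1_coeff=self.ar1_coeff,
            drift_amplitude_pct=self.drift_amplitude_pct,
            seed=seed,
        )


class DetectionSection(_Section):
    ema_window_ms: float = 25.0
    onset_threshold_frac: float = 0.70
    termination_frac_of_threshold: float = 0.50
    merge_gap_ms: float = 100.0
    min_duration_ms: float = 600.0
    intensity_percentile: float = 0.90
    reference_percentile: float = 0.95
    noise_refine: bool = True

    def to_config(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump())


class FIRSection(_Section):
    n_bins: int = 40
    bin_s: float = 1.0
    window_start_s: float = -20.0

    def to_config(self) -> FIRConfig:
        return FIRConfig(n_bins=self.n_bins, bin_s=self.bin_s,
                         window_start_s=self.window_start_s)


class GlmSection(_Section):
    fwhm_mm: float = 0.5
    highpass_cutoff_s: float = 128.0
    n_discard: int = 5
    regressor_model: str = "impulse"
    correction: str = "fwe"
    alpha: float = 0.05


class CorrelationSection(_Section):
    seed_r_thresh: float = 0.5
    seed_min_cluster: int = 300
    calcium_r_thresh: float = 0.8
    calcium_min_cluster: int = 70


class PipelineConfig(_Section):
    """All stage parameters plus the global seed and output directory."""

    seed: int = 0
    n_sessions: int = 3
    out_dir: str | None = None
    calcium_sim: CalciumSimSection = Field(default_factory=CalciumSimSection)
    bold_sim: BoldSimSection = Field(default_factory=BoldSimSection)
    detection: DetectionSection = Field(default_factory=DetectionSection)
    fir: FIRSection = Field(default_factory=FIRSection)
    glm: GlmSection = Field(default_factory=GlmSection)
    correlation: CorrelationSection = Field(default_factory=CorrelationSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def hash(self) -> str:
        """Stable digest of the full configuration, recorded in outputs."""
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def session_seeds(self) -> list[int]:
        """Per-session RNG seeds fanned out from the global seed (< 2^31)."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(self.n_sessions * 2)]
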
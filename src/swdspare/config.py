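"""YAML pipeline configuration with strict validation.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running with defaults. The parsed config is re-serialized into
every output directory for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .classification import CLASSIFIERS, FEATURE_SETS, WINDOW_STRATEGIES


class WindowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pre_ms: float = 1000.0
    ict_ms: float = 500.0


class SelectionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_threshold: float = 0.001
    scope: str = "per_fold"


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    feature_set: str = "csp"
    window_strategy: str = "fusion"
    classifier: str = "lda"

    @field_validator("feature_set")
    @classmethod
    def _fs(cls, v: str) -> str:
        if v not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        return v

    @field_validator("window_strategy")
    @classmethod
    def _ws(cls, v: str) -> str:
        if v not in WINDOW_STRATEGIES:
            raise ValueError(f"window_strategy must be one of {WINDOW_STRATEGIES}")
        return v

    @field_validator("classifier")
    @classmethod
    def _clf(cls, v: str) -> str:
        if v not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        return v


class SyntheticSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 34
    n_spared_swd: int = 81
    n_impaired_swd: int = 49
    rate_hz: float = 256.0
    n_channels: int = 16
    swd_freq_hz: float = 3.5
    amplitude_uv_spared: float = 40.0
    amplitude_uv_impaired: float = 80.0
    preictal_delta_gain_impaired: float = 2.0
    background_noise_uv: float = 15.0
    patient_purity: float | None = None


class DataSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    edf_dir: str | None = None
    annotations: str | None = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "swdspare_out"
    k_folds: int = 10
    n_csp_filters: int = 5
    grid: bool = False  # evaluate all 32 model configurations
    allow_extrapolation: bool = False
    window: WindowSection = WindowSection()
    selection: SelectionSection = SelectionSection()
    model: ModelSection = ModelSection()
    synthetic: SyntheticSection = SyntheticSection()
    data: DataSection = DataSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls.model_validate(raw)
        if not cfg.allow_extrapolation:
            if not (100 <= cfg.window.pre_ms <= 5000):
                raise ValueError(
                    "window.pre_ms outside the validated range [100, 5000] "
                    "(set allow_extrapolation to override)")
            if not (100 <= cfg.window.ict_ms <= 1000):
                raise ValueError(
                    "window.ict_ms outside the validated range [100, 1000] "
                    "(set allow_extrapolation to override)")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
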
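"""Schema-validated pipeline configuration.

All sections are strict (unknown keys rejected) and every stochastic
stage's seed derives from the single top-level seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .design import DEFAULT_CONDITIONS, DIFFERENT_FACE, NO_FACE, SAME_FACE

__all__ = [
    "DesignConfig",
    "RoiModelConfig",
    "NoiseConfig",
    "GlmConfig",
    "RsaConfig",
    "BehaviorConfig",
    "InferenceConfig",
    "PipelineConfig",
    "validate_config",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class DesignConfig(_Strict):
    n_pairs_total: int = 36
    n_pairs_per_condition: int = 12
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    subcategories: tuple[str, ...] = ("indoor", "outdoor")
    n_runs: int = 8
    trial_duration: float = 4.0
    stim_duration: float = 0.5
    tr: float = 2.0
    n_null_interleaved: int = 18
    n_lead_in: int = 3
    n_lead_out: int = 3
    target_rate: float = 1.0 / 12.0


class RoiModelConfig(_Strict):
    n_voxels: int = 120
    n_units: int = 60
    c_global: dict[str, float] | float = 0.1
    c_pair: dict[str, float] | float = 0.15
    selectivity: Literal["uniform", "linear"] = "uniform"
    pattern_noise_sd: float = 0.0

    @field_validator("n_voxels", "n_units")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 2:
            raise ValueError("must be >= 2")
        return v


def _default_rois() -> dict[str, RoiModelConfig]:
    """HIPP-like: positive baseline clustering, learning-driven
    repulsion (strongest in selective voxels).  PPA/EVC-like controls:
    clustering in every condition."""
    return {
        "HIPP": RoiModelConfig(
            c_global={NO_FACE: 0.08, DIFFERENT_FACE: 0.12, SAME_FACE: 0.12},
            c_pair={NO_FACE: 0.15, DIFFERENT_FACE: 0.0, SAME_FACE: -0.12},
            selectivity="linear",
        ),
        "PPA": RoiModelConfig(c_global=0.12, c_pair=0.12),
        "EVC": RoiModelConfig(c_global=0.10, c_pair=0.15),
    }


class NoiseConfig(_Strict):
    sigma: float = 1.0
    ar1_phi: float = 0.3
    drift_amplitude: float = 0.5
    run_jitter: float = 0.1

    @field_validator("sigma", "drift_amplitude")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @field_validator("ar1_phi")
    @classmethod
    def _phi(cls, v: float) -> float:
        if not 0 <= v < 1:
            raise ValueError("must be in [0, 1)")
        return v


class GlmConfig(_Strict):
    prewhiten: Literal["none", "ar1"] = "ar1"
    highpass_sigma: float = 64.0
    hrf: dict[str, float] = Field(default_factory=dict)

    @field_validator("highpass_sigma")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v


class RsaConfig(_Strict):
    use_betas: bool = False
    zscore_patterns: bool = False


class BehaviorConfig(_Strict):
    intercept: float = 1.0
    slope_score: float = -2.0
    condition_effects: dict[str, float] = Field(
        default_factory=lambda: {DIFFERENT_FACE: 0.9}
    )
    repetition_effect: float = 0.8
    interaction: float = 0.0
    subject_sd: float = 0.5
    other_rate: float = 0.04


class InferenceConfig(_Strict):
    fixed: tuple[str, ...] = ("difference_score", "condition", "test_repetition")
    random_slopes: tuple[str, ...] = ()
    score_term: str = "difference_score"


class PipelineConfig(_Strict):
    seed: int = 0
    n_subjects: int = 6
    out_dir: str | None = None
    design: DesignConfig = Field(default_factory=DesignConfig)
    rois: dict[str, RoiModelConfig] = Field(default_factory=_default_rois)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    glm: GlmConfig = Field(default_factory=GlmConfig)
    rsa: RsaConfig = Field(default_factory=RsaConfig)
    behavior: BehaviorConfig = Field(default_factory=BehaviorConfig)
    inference: InferenceConfig = Field(default_factory=InferenceConfig)

    @field_validator("n_subjects")
    @classmethod
    def _subjects(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_config(data: dict | None = None, **overrides) -> PipelineConfig:
    payload = dict(data or {})
    payload.update(overrides)
    return PipelineConfig.model_validate(payload)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and schema-check a YAML/JSON config file; defaults filled,
    unknown keys rejected with their field paths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)
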
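"""Schema-validated pipeline configuration (YAML/JSON) for the command-line surface.

Unknown keys are rejected so that a typo in a config file fails loudly
before any stage runs.  Model-parameter defaults match the analytic-model
defaults elsewhere in the package; the matched-mean tolerance of 0.03 is
the tolerance used when pairing constructs by 1/(normalized mean).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError
from .library import DEFAULT_REGULATION_STRENGTHS
from .telegraph import CrisprParams, PromoterKinetics

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WildTypeConfig(_Strict):
    k_on_wt: float = 1.0
    k_off_wt: float = 1.0
    tau: float = Field(1.0, gt=0)
    C: float = Field(200.0, gt=0)

    def to_kinetics(self) -> PromoterKinetics:
        return PromoterKinetics(
            k_on=self.k_on_wt,
            k_off=self.k_off_wt,
            k_on_wt=self.k_on_wt,
            k_off_wt=self.k_off_wt,
            tau=self.tau,
            C=self.C,
        )


class CrisprParamsConfig(_Strict):
    K_ro: float = 0.01
    K_ao: float = 0.02
    K_i: float = 10.0
    K_int1: float = 0.5
    K_int2: float = 2.0

    def to_params(self) -> CrisprParams:
        return CrisprParams(
            K_ro=self.K_ro, K_ao=self.K_ao, K_i=self.K_i,
            K_int1=self.K_int1, K_int2=self.K_int2,
        )


class SyntheticConfig(_Strict):
    n_replicates: int = Field(6, ge=1)
    n_events: int = Field(20_000, ge=100)
    measurement_cv: float = Field(0.05, ge=0)
    replicate_cv: float = Field(0.05, ge=0)
    blank_mean_fraction: float = Field(0.01, gt=0)
    regulation_strengths: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_REGULATION_STRENGTHS)
    )
    mode: str = "gamma_approx"


class AnalysisConfig(_Strict):
    gating_quantile: float = Field(0.99, gt=0, lt=1)
    match_tolerance: float = Field(0.03, gt=0)
    expression_threshold: float = Field(1.0, gt=0)
    noise_region_quantile: float = Field(0.5, gt=0, lt=1)
    mean_tolerance: float = Field(0.05, gt=0)
    noise_tolerance: float = Field(0.10, gt=0)
    equal_tolerance: float = Field(0.0, ge=0)
    normalization_mode: str = "pooled"


class GridConfig(_Strict):
    k_on_min: float = Field(0.01, gt=0)
    k_on_max: float = Field(1.0, gt=0)
    k_off_min: float = Field(0.01, gt=0)
    k_off_max: float = Field(1.0, gt=0)
    n_points: int = Field(50, ge=2)


class PipelineConfig(_Strict):
    events: str | None = None
    library: str | None = None
    outdir: str = "crisprar_out"
    seed: int = 0
    wild_type: WildTypeConfig = Field(default_factory=WildTypeConfig)
    crispr_params: CrisprParamsConfig = Field(default_factory=CrisprParamsConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    grid: GridConfig = Field(default_factory=GridConfig)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"invalid pipeline config: {exc}") from exc
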
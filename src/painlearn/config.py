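"""Pipeline configuration: a single structured file, schema-validated
before any stage runs (unknown keys rejected), with CLI overrides."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "SamplerSettings", "NetworkSettings", "load_config"]


class SamplerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_chains: int = Field(4, ge=1)
    n_warmup: int = Field(1000, ge=0)
    n_samples: int = Field(2000, ge=1)
    method: str = "mcmc"  # "mcmc" or "approx"


class NetworkSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    link_density: float = Field(0.10, gt=0.0, le=1.0)
    prior_width: float = Field(1.0, gt=0.0)
    log_base: float = Field(2.718281828459045, gt=1.0)
    fdr_threshold: float = Field(0.01, gt=0.0, lt=1.0)
    measure: str = "degree"


class PipelineConfig(BaseModel):
    """Paths, models to fit, sampler and network settings, master seed."""

    model_config = ConfigDict(extra="forbid")
    behaviour: str | None = None
    timeseries: list[str] = Field(default_factory=list)
    clinical: str | None = None
    output_dir: str = "painlearn_out"
    models: list[int] = Field(default_factory=lambda: [1, 2, 3, 4, 5])
    groups: list[str] = Field(default_factory=list)
    nodes_of_interest: list[str] = Field(default_factory=list)
    sampler: SamplerSettings = Field(default_factory=SamplerSettings)
    network: NetworkSettings = Field(default_factory=NetworkSettings)
    seed: int = 0


def load_config(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
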
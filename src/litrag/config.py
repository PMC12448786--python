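"""Structured run configuration with validation.

A single config object carries every tunable parameter of the pipeline at the
standard settings (chunks of 500 characters with 100 overlap, top 10 per
retrieval strategy, fusion weights 5/3/1, a selection target of 5 with an
examination budget of 30).  Configs load from YAML, reject unknown keys, and
validate each numeric parameter against the precondition of the operation it
feeds; command-line flags override file values, which override defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pipeline import PipelineParams
from .retrieval import AggregatorWeights

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # corpus
    records_path: str = "corpus.jsonl"
    texts_dir: str | None = "texts"
    # chunking
    chunk_size: int = Field(default=500, ge=1)
    overlap: int = Field(default=100, ge=0)
    # retrieval
    k_per_strategy: int = Field(default=10, ge=1)
    keyword_cap: int = Field(default=50, ge=1)
    # fusion weights
    w_s: float = Field(default=5.0, ge=0)
    w_m: float = Field(default=3.0, ge=0)
    w_r: float = Field(default=1.0, ge=0)
    # generation
    target: int = Field(default=5, ge=1)
    examination_cap: int = Field(default=30, ge=1)
    # backends
    backend: str = "mock"
    embedding_dimension: int = Field(default=256, ge=1)
    # reproducibility
    seed: int = 0

    @model_validator(mode="after")
    def _check_cross_field(self) -> "RunConfig":
        if self.overlap >= self.chunk_size:
            raise ValueError(
                f"overlap ({self.overlap}) must be smaller than chunk_size "
                f"({self.chunk_size})"
            )
        if self.w_s == self.w_m == self.w_r == 0:
            raise ValueError("fusion weights must not all be zero")
        if self.backend != "mock":
            raise ValueError(f"unknown backend {self.backend!r}; available: mock")
        return self

    def pipeline_params(self) -> PipelineParams:
        return PipelineParams(
            k_per_strategy=self.k_per_strategy,
            keyword_cap=self.keyword_cap,
            weights=AggregatorWeights(self.w_s, self.w_m, self.w_r),
            target=self.target,
            examination_cap=self.examination_cap,
        )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from defaults, an optional YAML file, and overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
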
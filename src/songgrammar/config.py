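"""Experiment configuration: one validated YAML file drives the pipeline.

All constants default to the study's values (band edges, 0.6 ratio
threshold, 500 ms region minimum, 300 ms search window, 10 ms hops, 1.0
prominence, 150 ms refractory, 100 ms MFCC window, 13 coefficients; all
concentrations 1, truncations 40/100/100, 500 restarts, tol 0.1, 300 max
iterations).  Desk-scale runs override the truncations and restart count.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class FrontendConfig(BaseModel):
    window_s: float = 0.020
    hop_s: float = 0.010
    song_band_hz: tuple[float, float] = (500.0, 1500.0)
    total_band_hz: tuple[float, float] = (0.0, 8000.0)
    region_threshold: float = 0.6
    min_region_duration_s: float = 0.5
    band_cutoffs_hz: list[float] = Field(
        default=[80.0, 260.0, 600.0, 1240.0, 2420.0, 4650.0, 7999.0])
    search_window_s: float = 0.300
    peak_hop_s: float = 0.010
    min_prominence: float = 1.0
    refractory_s: float = 0.150
    mfcc_window_s: float = 0.100
    n_mfcc: int = 13
    channel: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not (self.window_s > self.hop_s > 0):
            raise ValueError("need window_s > hop_s > 0")
        if not (0 < self.region_threshold < 1):
            raise ValueError("region_threshold must be in (0, 1)")
        return self


class ModelConfig(BaseModel):
    dim: int = 13
    alpha: float = 1.0
    k_beta: int = 40
    k_gamma: int = 100
    k_omega: int = 100
    hmm_model_termination: bool = True


class FitSection(BaseModel):
    n_restarts: int = 500
    tol: float = 0.1
    max_iter: int = 300


class SimulateConfig(BaseModel):
    kind: str = "center_embedding"
    n: int = 200
    dim: int = 13
    separation: float = 5.0
    continue_prob: float = 0.82
    max_len: int = 30


class ExperimentConfig(BaseModel):
    seed: int = 0
    stages: list[str] = Field(default=["simulate", "train-pcfg", "train-hmm", "evaluate"])
    frontend: FrontendConfig = Field(default_factory=FrontendConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    fit: FitSection = Field(default_factory=FitSection)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    wav_paths: list[str] = Field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
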
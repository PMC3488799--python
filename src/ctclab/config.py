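"""Run configuration: JSON-schema-validated settings for the CLI.

All defaults are the production values: 40 individuals x 15 generations with
SBX(10)/polynomial-mutation(20) operators, 0.1/0.01 ms Euler steps, a 300 ms
error window aligned at -40 mV, ten 1 Hz beats per pseudo-cell with 3%
conductance jitter and 0.5 mV voltage noise.
"""

from __future__ import annotations

import json

from pydantic import BaseModel, Field, field_validator

from .ga import GAConfig
from .metrics import ErrorWindow
from .models import SimSettings
from .pseudo import NoiseSettings

__all__ = ["RunConfig", "load_config", "config_schema"]


class GASection(BaseModel):
    population_size: int = Field(40, ge=2)
    generations: int = Field(15, ge=1)
    crossover_probability: float = Field(0.9, ge=0.0, le=1.0)
    sbx_eta: float = Field(10.0, gt=0.0)
    swap_probability: float = Field(0.5, ge=0.0, le=1.0)
    mutation_probability: float = Field(0.1, ge=0.0, le=1.0)
    mutation_eta: float = Field(20.0, gt=0.0)
    elitism: bool = True

    @field_validator("population_size")
    @classmethod
    def _even(cls, v: int) -> int:
        if v % 2:
            raise ValueError("population size must be even")
        return v

    def build(self, seed: int) -> GAConfig:
        return GAConfig(seed=seed, **self.model_dump())


class SimSection(BaseModel):
    dt: float = Field(0.1, gt=0.0)
    beats: int = Field(1, ge=1)
    use_fast_exp: bool = False

    def build(self) -> SimSettings:
        return SimSettings(**self.model_dump())


class WindowSection(BaseModel):
    threshold: float = Field(-40.0, ge=-80.0, le=0.0)
    t_max: float = Field(300.0, gt=0.0)

    def build(self) -> ErrorWindow:
        return ErrorWindow(**self.model_dump())


class CTCSection(BaseModel):
    r_seal_gohm: float | None = Field(None, gt=0.0, description="None = infinite seal")
    ljp_mv: float = 0.0
    loop_dt: float = Field(0.1, gt=0.0)
    substeps: int = Field(10, ge=1)
    beats: int = Field(1, ge=1)
    scenario: str = Field("ideal", pattern="^(ideal|mismatch|template|fit)$")
    mismatch_label: float = 70.0


class PseudoSection(BaseModel):
    conductance_cv: float = Field(0.03, ge=0.0)
    voltage_sd_mv: float = Field(0.5, ge=0.0)
    n_beats: int = Field(10, ge=1)
    n_cells: int = Field(1, ge=1)

    def build(self) -> NoiseSettings:
        return NoiseSettings(self.conductance_cv, self.voltage_sd_mv)


class RunConfig(BaseModel):
    """Top-level CLI configuration (every section optional, defaults apply)."""

    seed: int = 0
    ga: GASection = GASection()
    sim: SimSection = SimSection()
    window: WindowSection = WindowSection()
    ctc: CTCSection = CTCSection()
    pseudo: PseudoSection = PseudoSection()

    model_config = {"extra": "forbid"}


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def config_schema() -> dict:
    """Published JSON schema of the run configuration."""
    return RunConfig.model_json_schema()
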
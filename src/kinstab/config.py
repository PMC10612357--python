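"""Pipeline configuration: one flat YAML file with per-stage sections.

Unknown keys are rejected; every default is documented on the model and
reproducible from the emitted template (``kinstab run --emit-template``).
CLI flags override config values; config values override defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config", "emit_template"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SampleSpec(_Strict):
    """One simulated sample: truth overrides for each generator."""

    name: str
    protein: str = "MAPK1"
    substitution: str = "WT"
    unfolding_model: str = Field("two", pattern="^(two|three)$")
    two_state: dict = Field(default_factory=dict)
    three_state: dict = Field(default_factory=dict)
    melt: dict = Field(default_factory=dict)
    kinetics: dict = Field(default_factory=dict)


class SimulateConfig(_Strict):
    enabled: bool = True
    noise_sd: float | None = None  # None -> 2% of signal span per channel
    samples: list[SampleSpec] = Field(default_factory=lambda: [SampleSpec(name="WT")])


class UnfoldingConfig(_Strict):
    temperature_K: float = 283.15
    model: str = Field("auto", pattern="^(auto|two|three)$")
    share_m: bool = False
    svd_rank_hint: int | None = None
    input: str | None = None  # denaturation CSV; None -> simulate


class ThermalConfig(_Strict):
    window_C: float = 2.5
    prominence: float = 0.1
    input: str | None = None  # thermal CSV; None -> simulate


class KineticsConfig(_Strict):
    input_progress: str | None = None
    input_temperature_rates: str | None = None
    max_window_s: float = 60.0
    max_conversion: float = 0.10


class ReportConfig(_Strict):
    wildtype_id: str = "WT"
    format: str = Field("csv", pattern="^(csv|text)$")


class PipelineConfig(_Strict):
    """Top-level configuration for ``kinstab run``."""

    seed: int = 1
    out_dir: str = "results"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    unfolding: UnfoldingConfig = Field(default_factory=UnfoldingConfig)
    thermal: ThermalConfig = Field(default_factory=ThermalConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    def referenced_files(self) -> list[str]:
        refs = [self.unfolding.input, self.thermal.input,
                self.kinetics.input_progress, self.kinetics.input_temperature_rates]
        return [r for r in refs if r]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def emit_template() -> str:
    """The full default configuration as YAML."""
    return yaml.safe_dump(PipelineConfig().model_dump(), sort_keys=False)
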
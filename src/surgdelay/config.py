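"""Run configuration: validated JSON/YAML input for every module.

A :class:`RunConfig` gathers the population, delay distribution, growth,
mortality and MET-timing parameters plus run options. Every field
defaults to the calibrated base case (TD0 19.8 mm, a=58.4/b=4.46/c=0.071,
VDT 170/72 days, 6.2% M1, 85% HR+), so an empty config file is a valid,
fully specified run. Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cohorts, gompertz, growth, met_timing
from .datasets import read_delay_csv

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GrowthConfig(_Strict):
    td0: float = Field(19.8, gt=0)
    diameter_factor: float = Field(1.26, gt=1)
    vdt_hr_pos: float = Field(170.0, gt=0)
    vdt_hr_neg: float = Field(72.0, gt=0)

    def build(self) -> growth.GrowthParams:
        return growth.GrowthParams(**self.model_dump())


class MortalityConfig(_Strict):
    a: float = Field(58.4, gt=0)
    b: float = Field(4.46, gt=0)
    c: float = Field(0.071, gt=0)

    def build(self) -> gompertz.GompertzParams:
        return gompertz.GompertzParams(**self.model_dump())


class PopulationConfig(_Strict):
    incidence: float = Field(287_850, ge=0)
    m1_fraction: float = Field(0.062, ge=0, le=1)
    hr_pos_fraction: float = Field(0.85, ge=0, le=1)
    td0: float = Field(19.8, gt=0)

    def build(self) -> cohorts.PopulationSpec:
        return cohorts.PopulationSpec(**self.model_dump())


class MetTimingConfig(_Strict):
    pi80_hr_pos: tuple[float, float, float] = (16.9, 60.4, 141.3)
    pi80_hr_neg: tuple[float, float, float] = (9.4, 25.2, 80.8)
    post_met_survival: float = Field(28.0, gt=0)

    def build(self) -> met_timing.MetTimingParams:
        return met_timing.MetTimingParams(**self.model_dump())


class DelayBinConfig(_Strict):
    label: str
    mass: float = Field(ge=0)
    representative_day: float = Field(gt=0)


class DelayDistributionConfig(_Strict):
    """Inline bins or a CSV path (exactly one of the two)."""

    bins: Optional[list[DelayBinConfig]] = None
    mass_type: Literal["fraction", "count"] = "fraction"
    csv_path: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.bins is None) == (self.csv_path is None):
            raise ValueError("specify exactly one of 'bins' or 'csv_path'")
        return self

    def build(self, base_dir: Path | None = None) -> cohorts.DelayDistribution:
        if self.csv_path is not None:
            path = Path(self.csv_path)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return read_delay_csv(path)
        bins = tuple(
            cohorts.DelayBin(b.label, b.mass, b.representative_day) for b in self.bins
        )
        return cohorts.DelayDistribution(bins, self.mass_type)


class OptionsConfig(_Strict):
    rounding_mode: Literal["full", "printed"] = "full"
    open_bin_day_overrides: dict[str, float] = Field(default_factory=dict)
    seed: int = 0


class RunConfig(_Strict):
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    delay_distribution: Optional[DelayDistributionConfig] = None
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    mortality: MortalityConfig = Field(default_factory=MortalityConfig)
    met_timing: MetTimingConfig = Field(default_factory=MetTimingConfig)
    options: OptionsConfig = Field(default_factory=OptionsConfig)

    def build_distribution(self, base_dir: Path | None = None):
        if self.delay_distribution is None:
            return None
        dist = self.delay_distribution.build(base_dir)
        for label, day in self.options.open_bin_day_overrides.items():
            dist = dist.with_representative_day(label, day)
        return dist

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    An empty file yields the all-defaults configuration. Validation
    errors carry field-level messages (pydantic).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    return RunConfig.model_validate(raw)
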
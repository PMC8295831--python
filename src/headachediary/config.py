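"""Validated pipeline configuration (YAML-loadable; unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classifier import (
    DEFAULT_MIGRAINE_SPECIFIC_DRUGS,
    ClassifierConfig,
    IntensityBands,
)


class ClassifierSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mild_max: int = 3
    moderate_max: int = 7
    migraine_min_duration_h: float = 4.0
    tth_min_duration_h: float = 0.5
    tth_max_duration_h: float = 168.0
    migraine_specific_drugs: list[str] = Field(
        default_factory=lambda: list(DEFAULT_MIGRAINE_SPECIFIC_DRUGS))
    attribution_window_h: float = 1.0

    def to_classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            bands=IntensityBands(self.mild_max, self.moderate_max),
            migraine_min_duration_h=self.migraine_min_duration_h,
            tth_min_duration_h=self.tth_min_duration_h,
            tth_max_duration_h=self.tth_max_duration_h,
            migraine_specific_drugs=tuple(self.migraine_specific_drugs),
            attribution_window_h=self.attribution_window_h,
        )


class AggregationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chronic_headache_days: int = 45
    chronic_migraine_days: int = 24
    episodic_min_attacks: int = 5
    diagnosis_window_days: int = 90


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    baseline_month: int = 1
    followup_month: int = 7
    alpha: float = Field(default=0.05, gt=0, lt=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    classifier: ClassifierSettings = Field(default_factory=ClassifierSettings)
    aggregation: AggregationSettings = Field(
        default_factory=AggregationSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()
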
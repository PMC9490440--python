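"""Run configuration: a single validated YAML schema for the pipeline.

Unknown keys are rejected everywhere so that a typo in a threshold name
fails loudly before any stage runs.  Every default that stands in for an
under-documented instrument value (detection limits, band centers, the
OH-Cl position) lives here, not in code, and is echoed into run logs.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError
from .spectra import FeatureQuery, RatioDefinition


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FeatureQueryConfig(_Strict):
    center: float
    tolerance: float = 5.0
    mode: Literal["peak", "valley", "shoulder"] = "peak"

    def build(self) -> FeatureQuery:
        return FeatureQuery(self.center, self.tolerance, self.mode)


class RatioConfig(_Strict):
    name: str
    numerator: list[FeatureQueryConfig]
    denominator: list[FeatureQueryConfig]
    applicability: Literal["both", "unburnt-only", "burnt-only"] = "both"

    def build(self) -> RatioDefinition:
        return RatioDefinition(
            self.name,
            tuple(q.build() for q in self.numerator),
            tuple(q.build() for q in self.denominator),
            self.applicability,
        )


class MarkersConfig(_Strict):
    btcp_center: float = 1123.0
    btcp_tol: float = 5.0
    shoulder_center: float = 547.0
    shoulder_tol: float = 5.0
    extra_band: tuple[float, float] = (1080.0, 1100.0)
    oh_cl_center: float = 3494.0  # literature default; never stated on-instrument
    oh_cl_tol: float = 10.0
    prominence_floor: float = 0.005


class StatsConfig(_Strict):
    sidedness: Literal["two-sided", "greater", "less"] = "two-sided"
    mct_method: Literal["holm", "bonferroni"] = "holm"
    regression_unit: Literal["sample", "group_mean"] = "sample"
    alpha: float = 0.05


class DecisionConfig(_Strict):
    k_threshold: float = 0.07
    k_band: float = 0.01
    fresh_floor: float = 0.20
    k_scale: Literal["elemental", "oxide"] = "elemental"
    cn_p_floor: float = 0.02
    irsf_cut: float = 3.8


class SimulateConfig(_Strict):
    points_per_zone: int = 5
    absorbance_noise_sd: float = 0.005
    low_total_fraction: float = 0.02
    oc_uptake: float = 0.02
    extra_peak_absent_34d: bool = False
    include_btcp: bool = False


class PathsConfig(_Strict):
    input_dir: str = "results/study"
    output_dir: str = "results"


class RunConfig(_Strict):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    anchors: list[float] = [450.0, 800.0, 900.0, 1200.0, 1300.0, 1800.0, 2200.0]
    ratios: list[RatioConfig] = Field(default_factory=list)
    markers: MarkersConfig = Field(default_factory=MarkersConfig)
    detection_limits: dict[str, float] = Field(default_factory=dict)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    decisions: DecisionConfig = Field(default_factory=DecisionConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    seed: int = 0

    def battery(self):
        from .spectra import default_battery

        return [r.build() for r in self.ratios] if self.ratios else default_battery()

    def limits(self):
        from .empa import DEFAULT_DETECTION_LIMITS, DetectionLimits

        merged = dict(DEFAULT_DETECTION_LIMITS)
        merged.update(self.detection_limits)
        return DetectionLimits(merged)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> RunConfig:
    """The shipped defaults (data/defaults.yaml), validated."""
    text = resources.files("bioapatite").joinpath("data/defaults.yaml").read_text()
    return load_config_text(text)


def load_config_text(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from None


def load_config(path) -> RunConfig:
    return load_config_text(Path(path).read_text())
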
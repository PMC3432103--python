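"""Pipeline configuration: structured, validated, YAML round-trippable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import DetectabilityModel, EffortModel, PoolConfig


@dataclass
class LandscapeConfig:
    n_rows: int = 24
    n_cols: int = 24
    cell_km: float = 20.0
    smooth_sigma: float = 3.0


@dataclass
class SurveyConfig:
    n_sites: int = 80
    years: list[int] = field(default_factory=lambda: list(range(2000, 2005)))
    effort: EffortModel = field(default_factory=EffortModel)
    detectability: DetectabilityModel = field(default_factory=DetectabilityModel)


@dataclass
class SplitConfig:
    n_eval: int = 16
    stratify_by_quadrant: bool = True


@dataclass
class MethodsConfig:
    methods: list[str] = field(default_factory=lambda: ["a", "b", "c", "d"])
    min_records: int = 30
    gam_df: int = 5
    gam_family: str = "poisson"  # poisson | gaussian-log | gaussian


@dataclass
class MetricsSectionConfig:
    hull_mass_frac: float = 0.95
    hull_max_axes: int = 3
    neighbourhood_mean: bool = False  # 3x3 cell averaging around each site


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int = 1
    n_species: int = 40
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    pool: PoolConfig = field(default_factory=PoolConfig)
    survey: SurveyConfig = field(default_factory=SurveyConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    methods: MethodsConfig = field(default_factory=MethodsConfig)
    metrics: MetricsSectionConfig = field(default_factory=MetricsSectionConfig)
    slope_test_sided: str = "two"
    run_sar: bool = True

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("landscape", LandscapeConfig),
            ("pool", PoolConfig),
            ("split", SplitConfig),
            ("methods", MethodsConfig),
            ("metrics", MetricsSectionConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "survey" in d and isinstance(d["survey"], dict):
            s = dict(d["survey"])
            if isinstance(s.get("effort"), dict):
                s["effort"] = EffortModel(**s["effort"])
            if isinstance(s.get("detectability"), dict):
                s["detectability"] = DetectabilityModel(**s["detectability"])
            d["survey"] = SurveyConfig(**s)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """All violations, each naming the offending field; empty list = ok."""
    errors: list[str] = []
    if config.landscape.n_rows < 4 or config.landscape.n_cols < 4:
        errors.append("landscape.n_rows/n_cols: grid must be at least 4x4")
    if config.n_species < 2:
        errors.append("n_species: need at least 2 species")
    if not config.methods.methods:
        errors.append("methods.methods: method list must be non-empty")
    for m in config.methods.methods:
        if m not in ("a", "b", "c", "d"):
            errors.append(f"methods.methods: unknown method {m!r}")
    if config.survey.n_sites < 2:
        errors.append("survey.n_sites: need at least 2 sites")
    if not config.survey.years:
        errors.append("survey.years: need at least one survey year")
    if config.split.n_eval >= config.survey.n_sites:
        errors.append("split.n_eval: must be smaller than survey.n_sites")
    if config.split.n_eval < 3:
        errors.append("split.n_eval: need at least 3 evaluation sites for regression")
    if config.methods.gam_df < 4:
        errors.append("methods.gam_df: spline df must be at least 4")
    if config.slope_test_sided not in ("two", "one"):
        errors.append("slope_test_sided: must be 'two' or 'one'")
    try:
        config.pool.validate()
    except ValueError as e:
        errors.append(f"pool: {e}")
    return errors
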
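"""Pipeline configuration: typed blocks with strict YAML (de)serialization.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently falling back to a default; ``load(save(c)) == c`` for any valid
config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_PROFILES, ObserverProfile, PhantomParams, StudyDesign

__all__ = ["AnalysisConfig", "ExtractionConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ExtractionConfig:
    bin_width: float = 25.0
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass(frozen=True)
class AnalysisConfig:
    icc_threshold: float = 0.75
    qcd_threshold: float = 10.0
    inclusive_small_qcd: bool = False
    robust_semantics: str = "all"  # "all" arms/pairs must pass, or "any"
    robust_modality: str = "MR"
    comparison_arm: str = "MR1"
    pca_arm: str = "MR1"
    pca_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.robust_semantics not in ("all", "any"):
            raise ValueError("robust_semantics must be 'all' or 'any'")
        if not 0 < self.pca_fraction <= 1:
            raise ValueError("pca_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    profiles: dict[str, ObserverProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "radrepro_run"
    write_volumes: bool = True


def _as_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _from_dict(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        default = fields[name].default
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def to_dict(config: PipelineConfig) -> dict:
    return {
        "design": _as_dict(config.design),
        "phantom": _as_dict(config.phantom),
        "profiles": {m: _as_dict(p) for m, p in config.profiles.items()},
        "extraction": _as_dict(config.extraction),
        "analysis": _as_dict(config.analysis),
        "output_dir": config.output_dir,
        "write_volumes": config.write_volumes,
    }


def from_dict(data: dict) -> PipelineConfig:
    known = {"design", "phantom", "profiles", "extraction", "analysis", "output_dir", "write_volumes"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    profiles = {
        m: _from_dict(ObserverProfile, p, f"profiles.{m}")
        for m, p in data.get("profiles", {m: _as_dict(p) for m, p in DEFAULT_PROFILES.items()}).items()
    }
    return PipelineConfig(
        design=_from_dict(StudyDesign, data.get("design", {}), "design"),
        phantom=_from_dict(PhantomParams, data.get("phantom", {}), "phantom"),
        profiles=profiles,
        extraction=_from_dict(ExtractionConfig, data.get("extraction", {}), "extraction"),
        analysis=_from_dict(AnalysisConfig, data.get("analysis", {}), "analysis"),
        output_dir=data.get("output_dir", "radrepro_run"),
        write_volumes=data.get("write_volumes", True),
    )


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(to_dict(config), sort_keys=False))
    return path


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return from_dict(data or {})
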
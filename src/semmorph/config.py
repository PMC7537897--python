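"""Pipeline configuration: nested dataclasses loaded from YAML/JSON.

Unknown keys are rejected at load time so a typo never silently falls
back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DenoiseConfig",
    "RoiConfig",
    "FuzzyConfig",
    "RefineConfig",
    "MorphometryConfig",
    "PeriodicityConfig",
    "ReportConfig",
    "PipelineConfig",
    "load_config",
]


@dataclass
class DenoiseConfig:
    enabled: bool = True
    family: str = "db4"
    levels: int = 3
    threshold_rule: str = "universal"
    threshold_value: float = 0.0
    shrinkage: str = "soft"


@dataclass
class RoiConfig:
    max_iter: int = 200
    smoothing: int = 1


@dataclass
class FuzzyConfig:
    n_classes: int = 2
    fuzziness: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    features: str = "intensity"


@dataclass
class RefineConfig:
    enabled: bool = True
    ambiguity_threshold: float = 0.8
    max_rounds: int = 1


@dataclass
class MorphometryConfig:
    min_area_px: int = 16
    n_groups: int = 3
    foreground: str = "bright"  # or "dark": which intensity class is object


@dataclass
class PeriodicityConfig:
    enabled: bool = False
    period_min_nm: float = 5.0
    period_max_nm: float = 20.0
    n_angles: int = 360


@dataclass
class ReportConfig:
    diameter_decimals: int = 2
    area_decimals: int = 1


@dataclass
class PipelineConfig:
    """Everything a run needs; ``pixel_size_nm`` has no default."""

    images: list = field(default_factory=list)
    pixel_size_nm: float = 0.0
    output_dir: str = "semmorph_out"
    seed: int = 0
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    periodicity: PeriodicityConfig = field(default_factory=PeriodicityConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    _SECTIONS = {
        "denoise": DenoiseConfig,
        "roi": RoiConfig,
        "fuzzy": FuzzyConfig,
        "refine": RefineConfig,
        "morphometry": MorphometryConfig,
        "periodicity": PeriodicityConfig,
        "report": ReportConfig,
    }

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be set explicitly (> 0)")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        for key, section_cls in cls._SECTIONS.items():
            if key in data and isinstance(data[key], dict):
                sub = data[key]
                sub_known = {f.name for f in dataclasses.fields(section_cls)}
                sub_unknown = set(sub) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown {key} keys: {sorted(sub_unknown)}"
                    )
                data[key] = section_cls(**sub)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return PipelineConfig.from_dict(data)
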
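"""Pipeline configuration: one YAML file, strict keys, stable content hash.

Unknown keys are rejected (fail-fast) rather than ignored, and every output
record produced by the pipeline is stamped with the config's content hash so
results can always be traced back to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .cfsa import SeverityThresholds
from .errors import ValidationError
from .landmarks import DetectorConfig
from .preprocess import CameraModel, GateConfig

__all__ = ["GeneratorDefaults", "PipelineConfig"]


@dataclass(frozen=True)
class GeneratorDefaults:
    """Defaults fed to the synthetic generator by the CLI."""

    finger_width_mm: float = 16.0
    nail_length_mm: float = 12.0
    noise_sigma: float = 0.01
    distance_min_cm: float = 4.0
    distance_max_cm: float = 7.0


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(path, f"unknown config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    gate: GateConfig = field(default_factory=GateConfig)
    thresholds: SeverityThresholds = field(default_factory=SeverityThresholds)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    generator: GeneratorDefaults = field(default_factory=GeneratorDefaults)
    clubbing_cutoff_deg: float = 160.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "camera": CameraModel,
            "gate": GateConfig,
            "thresholds": SeverityThresholds,
            "detector": DetectorConfig,
            "generator": GeneratorDefaults,
        }
        kwargs = {}
        for key, cls in sections.items():
            if key in data:
                sub = data.pop(key)
                if not isinstance(sub, dict):
                    raise ValidationError(key, "must be a mapping")
                kwargs[key] = _build(cls, sub, key)
        allowed = {"clubbing_cutoff_deg", "seed"}
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError("config", f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
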
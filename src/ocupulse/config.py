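"""Pipeline configuration: one strict, human-readable YAML file.

Defaults pin the analysis constants the method is defined by — the 3-MAD
outlier rule, the 0.5-3x heart-rate pass band, the thin-shell volume
model with R = AL/2 — so a run with no config reproduces the reference
processing exactly.  Parsing is strict: unknown keys are rejected rather
than silently ignored, so a typo cannot quietly drift a pinned constant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .rigidity import SchematicEyeConstants
from .segmentation import SegmentationConfig
from .waveform import WaveformConfig

__all__ = ["StatsConfig", "ModelConfig", "PipelineConfig", "load_config", "config_hash"]


@dataclass
class StatsConfig:
    alpha: float = 0.05
    exact_threshold: int = 8
    holm_adjust: bool = False


@dataclass
class ModelConfig:
    volume_model: str = "thin_shell"  # or "exact"
    schematic_eye: SchematicEyeConstants = field(default_factory=SchematicEyeConstants)

    def __post_init__(self) -> None:
        if self.volume_model not in ("thin_shell", "exact"):
            raise ValueError("volume_model must be 'thin_shell' or 'exact'")


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under {path!r}")
    return cls(**data)


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "waveform": WaveformConfig,
    "model": ModelConfig,
    "stats": StatsConfig,
}


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a YAML config; missing file or None gives pure defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = dict(data[name] or {})
            if name == "model" and "schematic_eye" in section:
                section["schematic_eye"] = _build(
                    SchematicEyeConstants, section["schematic_eye"], "model.schematic_eye"
                )
            if name == "waveform" and "hr_search_band_hz" in section:
                section["hr_search_band_hz"] = tuple(section["hr_search_band_hz"])
            kwargs[name] = _build(cls, section, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return PipelineConfig(**kwargs)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for run manifests."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
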
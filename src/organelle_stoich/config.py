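"""Pipeline configuration: YAML schema, validation, defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError, SchemaError

__all__ = ["PipelineConfig", "load_config"]

_REQUIRED = ("pixel_size_nm",)


@dataclass
class PipelineConfig:
    """Acquisition metadata and analysis parameters for one pipeline run."""

    pixel_size_nm: float
    exposure_ms: float = 5.0
    frame_interval_s: float = 60.0
    attenuation_factor: float = 1.0
    roi_radius: float = 5.0
    bg_halfwidth: int = 8
    snr_threshold: float = 0.4
    ck_window: int = 10
    ck_exponent: float = 4.0
    kernel_width: float = 0.5
    oligomer_sizes: dict = field(default_factory=dict)
    resolution_radius_nm: float = 250.0
    group_size: int = 85
    overtrack_frames: int = 20
    seed: int | None = None
    simulate: dict | None = None

    def __post_init__(self):
        positives = (
            "pixel_size_nm", "exposure_ms", "frame_interval_s", "attenuation_factor",
            "roi_radius", "snr_threshold", "ck_exponent", "kernel_width",
            "resolution_radius_nm",
        )
        bad = [n for n in positives if getattr(self, n) <= 0]
        bad += [n for n in ("bg_halfwidth", "ck_window", "group_size") if getattr(self, n) < 2]
        if bad:
            raise ConfigurationError(f"non-positive or out-of-range parameters: {', '.join(bad)}")
        bad_olig = [k for k, v in self.oligomer_sizes.items() if v < 1]
        if bad_olig:
            raise ConfigurationError(f"oligomer sizes must be >= 1: {', '.join(bad_olig)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        missing = [k for k in _REQUIRED if k not in data]
        if missing:
            raise SchemaError(missing)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(_REQUIRED)
    return PipelineConfig.from_dict(data)
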
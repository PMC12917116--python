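"""Pipeline configuration: a single validated source of truth for every
tunable constant.

Printed method constants live here with their role:
heat peak 256 and focusing parameter gamma=2 (training losses), the
6 mm per-axis identification tolerance, the 10 mm canal / 3 mm recess
height / 30 degree recess angle stenosis thresholds, sigma=6 mm heatmap
width, candidate threshold 128 (half peak), 15 mm fusion gate, and the
10 mm / 30 mm saturation-band offset and thickness.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HeatmapConfig(_Strict):
    sigma_mm: float = Field(6.0, gt=0)
    threshold: float = Field(128.0, gt=0, lt=256)


class LabelingConfig(_Strict):
    template_path: Optional[str] = None
    gate_mm: float = Field(15.0, gt=0)
    tolerance_mm: float = Field(6.0, gt=0)
    reference_threshold: float = Field(0.0, ge=0)


class PlanningConfig(_Strict):
    sat_band_offset_mm: float = Field(10.0, gt=0)
    sat_band_thickness_mm: float = Field(30.0, gt=0)


class ThresholdConfig(_Strict):
    canal_mm: float = Field(10.0, gt=0)
    recess_height_mm: float = Field(3.0, gt=0)
    recess_angle_deg: float = Field(30.0, gt=0)
    angle_direction: str = Field("less", pattern="^(less|greater)$")


class PipelineConfig(_Strict):
    heatmap: HeatmapConfig = HeatmapConfig()
    labeling: LabelingConfig = LabelingConfig()
    planning: PlanningConfig = PlanningConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        try:
            return cls(**data)
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"])
            raise ConfigError(
                f"invalid config field {loc!r}: {first['msg']}") from exc

    def thresholds_obj(self):
        from .morphometry import Thresholds
        return Thresholds(canal_mm=self.thresholds.canal_mm,
                          recess_height_mm=self.thresholds.recess_height_mm,
                          recess_angle_deg=self.thresholds.recess_angle_deg,
                          angle_direction=self.thresholds.angle_direction)
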
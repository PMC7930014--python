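"""Pipeline configuration.

Every constant of the processing framework is surfaced here rather than
hard-coded, because the interesting analyses sweep them (agreement
thresholds, detector confidence thresholds, link IoU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Union

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    clip_len_s: float = 10.0
    max_frames_per_clip: int = 3
    clip_agreement_threshold: float = 0.8
    frame_agreement_threshold: float = 0.8
    link_iou: float = 0.5
    conf_thresholds: tuple[float, ...] = (0.5, 0.7, 0.9)
    tracker_max_steps: int = 10
    tracker_stop_score: float = 0.5
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in (
            "clip_agreement_threshold",
            "frame_agreement_threshold",
            "link_iou",
            "tracker_stop_score",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for t in self.conf_thresholds:
            if not (0 < t <= 1):
                raise ValidationError(f"conf_thresholds must be in (0, 1], got {t}")
        if self.clip_len_s <= 0 or self.max_frames_per_clip < 1:
            raise ValidationError("clip_len_s must be > 0 and max_frames_per_clip >= 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValidationError(f"split_ratios must sum to 1: {self.split_ratios}")
        return self


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML key-value config; keys not present keep their defaults."""
    if path is None:
        return PipelineConfig().validate()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("conf_thresholds", "split_ratios"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw).validate()
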
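"""Pipeline configuration: every tunable constant in one serialisable object.

Collects the attention thresholds (yaw 0.4, pitch 5, EAR 0.10, gaze window
1–25 cm), the smoothing window, the attention banding thresholds (0.2/0.8),
the trend-fit parameters and the processing frame rate.  Round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import AttentionConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    smoothing_window: int = 28       # frames; ~2 s at 14 fps
    band_low: float = 0.2
    band_high: float = 0.8
    min_frames: int = 5              # per sub-segment, for a trend fit
    slope_tie_epsilon: float = 0.0   # valence units per second
    trend_encoding: str = "sign"     # 'sign' | 'difference'
    frame_rate: float = 14.0
    segment_duration: float = 10.0
    gap: float = 1.0
    period_boundaries: tuple[float, float] | None = None  # None = equal thirds
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.band_low < self.band_high <= 1.0:
            raise ValueError("banding thresholds must satisfy 0 <= low < high <= 1")
        if self.smoothing_window < 1 or self.min_frames < 1:
            raise ValueError("window and frame counts must be >= 1")
        if self.trend_encoding not in ("sign", "difference"):
            raise ValueError(f"unknown trend_encoding {self.trend_encoding!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.period_boundaries is not None:
            d["period_boundaries"] = list(self.period_boundaries)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = AttentionConfig(**d["attention"])
        if d.get("period_boundaries") is not None:
            d["period_boundaries"] = tuple(d["period_boundaries"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
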
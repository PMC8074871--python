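"""Pipeline configuration: every tunable threshold in one serializable place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .features import FeatureConfig


@dataclass
class PipelineConfig:
    tz_offset_hours: float = 8.0
    enrollment_path: str | None = None
    event_date: str | None = None        # ISO date of the regime change
    home_radius_m: float = 200.0
    eps_m: float = 100.0
    min_dwell_min: float = 30.0
    gap_max_min: float = 30.0
    walk_threshold: int = 10
    allowance_min: float = 120.0
    night_window: tuple[float, float] = (22.0, 8.0)
    min_history: int = 21
    model_kind: str = "ar_weekly"
    alert_orange: float = 0.80
    alert_red: float = 0.95
    green_max_h: float = 24.0
    red_min_h: float = 48.0
    before_window: tuple[int, int] = (-45, -3)
    after_window: tuple[int, int] = (3, 45)
    min_days_per_window: int = 7
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alert_orange <= self.alert_red <= 1:
            raise ValueError("alert thresholds must satisfy 0 <= orange <= red <= 1")
        if self.green_max_h >= self.red_min_h:
            raise ValueError("green_max_h must be < red_min_h")
        if self.min_history < 1:
            raise ValueError("min_history must be >= 1")
        if self.walk_threshold < 0 or self.home_radius_m <= 0 or self.eps_m <= 0:
            raise ValueError("thresholds out of range")

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            tz_offset_hours=self.tz_offset_hours,
            walk_threshold=self.walk_threshold,
            night_window=tuple(self.night_window),
            allowance_min=self.allowance_min,
            home_radius_m=self.home_radius_m,
            gap_max_min=self.gap_max_min,
            eps_m=self.eps_m,
            min_dwell_min=self.min_dwell_min,
        )

    def to_yaml(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        d["night_window"] = list(d["night_window"])
        d["before_window"] = list(d["before_window"])
        d["after_window"] = list(d["after_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for k in ("night_window", "before_window", "after_window"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
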
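"""Study-level configuration shared by every analysis stage.

The defaults encode the Cayman Islands study conditions: receiver clocks
log UTC and the islands sit at UTC-5 with no daylight saving, summer is
April-September, the diel day window is 06:30-18:29 local time, a
"Month" for the residency classifier is a 30-day block, and stations
enter the analysis only when they carried a functioning receiver for at
least six months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date, time
from pathlib import Path

import yaml

from .errors import ConfigurationError

SUMMER_MONTHS_DEFAULT = frozenset({4, 5, 6, 7, 8, 9})


@dataclass(frozen=True)
class StudyConfig:
    """Parameters governing pre-processing, metrics and subsetting.

    Parameters
    ----------
    study_start, study_end
        Inclusive bounds of the monitoring window (local dates).
    utc_offset_hours
        Added to UTC timestamps to obtain local time (Cayman: -5).
    summer_months
        Calendar months forming the "summer" season; the rest is winter.
    day_start, day_end
        Inclusive local-clock bounds of the diel "day" window.
    month_block_days
        Length of the 30-day "Month" block used by the residency
        classifier (passer-by / transient rules).
    min_station_months
        Stations with fewer than ``min_station_months * 30`` working
        days are excluded from analysis.
    presence_threshold_pct
        Detection-day percentage separating pseudo-residents from
        residents among sharks with >= 3 detection months.
    station_day_min_detections
        Detections required at a single station on one day before that
        day counts as a station-level detection day.
    bad_row_tolerance
        Maximum tolerated fraction of malformed rows in a detection
        export before the load aborts.
    rng_seed
        Seed for every stochastic procedure in a pipeline run.
    """

    study_start: date
    study_end: date
    utc_offset_hours: int = -5
    summer_months: frozenset = SUMMER_MONTHS_DEFAULT
    day_start: time = time(6, 30)
    day_end: time = time(18, 29)
    month_block_days: int = 30
    min_station_months: int = 6
    presence_threshold_pct: float = 30.0
    station_day_min_detections: int = 2
    bad_row_tolerance: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ConfigurationError(
                f"study_start {self.study_start} must precede study_end {self.study_end}"
            )
        if not self.summer_months or not set(self.summer_months) <= set(range(1, 13)):
            raise ConfigurationError("summer_months must be a non-empty subset of 1..12")
        if self.month_block_days <= 0:
            raise ConfigurationError("month_block_days must be positive")
        if not 0 <= self.bad_row_tolerance <= 1:
            raise ConfigurationError("bad_row_tolerance must be in [0, 1]")

    @property
    def winter_months(self) -> frozenset:
        return frozenset(range(1, 13)) - frozenset(self.summer_months)

    @property
    def min_station_days(self) -> int:
        return self.min_station_months * 30

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Read a flat key/value (YAML) config file mirroring the fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in ("study_start", "study_end") and isinstance(value, str):
                value = date.fromisoformat(value)
            elif key in ("day_start", "day_end") and isinstance(value, str):
                value = time.fromisoformat(value)
            elif key == "summer_months":
                value = frozenset(int(m) for m in value)
            kwargs[key] = value
        if "study_start" not in kwargs or "study_end" not in kwargs:
            raise ConfigurationError("config must define study_start and study_end")
        return cls(**kwargs)
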
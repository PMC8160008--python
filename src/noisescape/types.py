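"""Domain types for the monitoring pipeline.

All timestamps are timezone-naive local wall-clock time: the study setting
(Accra, UTC+0 year-round) has no daylight-saving shifts, so no timezone
logic exists anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

#: The four land-use strata of the monitoring design.
LAND_USE_CLASSES = (
    "peri-urban background",
    "medium/low-density residential",
    "high-density residential",
    "commercial-business-industrial",
)

ROAD_CLASSES = ("major", "secondary/tertiary", "minor")

SITE_TYPES = ("fixed", "rotating")

#: Higher-order sound-source categories (ISO-adapted taxonomy).
#: "other" is the default sink for unmapped fine-grained labels.
SOURCE_CATEGORIES = (
    "road-transport",
    "animals-and-insects",
    "outdoor-music",
    "human-speech",
    "aircraft",
    "nature",
    "other",
)

#: Instrument noise floor in dBA. Levels below it are flagged on input,
#: never clipped by the metrics engine.
NOISE_FLOOR_DBA = 30.0


@dataclass
class MinuteLevelSeries:
    """One site's time-ordered LAeq_1min measurements.

    Parameters
    ----------
    site_id : str
        Opaque site identifier.
    timestamps : pandas.DatetimeIndex
        Minute-aligned, strictly increasing, timezone-naive local times.
        Gaps (missing minutes) are simply absent entries; they are never
        filled.
    levels : numpy.ndarray
        A-weighted 1-minute equivalent continuous levels (dBA), one per
        timestamp. Must be finite.
    """

    site_id: str
    timestamps: pd.DatetimeIndex
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.levels = np.asarray(self.levels, dtype=float)
        if len(self.timestamps) != len(self.levels):
            raise ValueError(
                f"site {self.site_id}: {len(self.timestamps)} timestamps "
                f"but {len(self.levels)} levels"
            )
        if self.timestamps.tz is not None:
            raise ValueError("timestamps must be timezone-naive local time")
        if len(self.timestamps) > 0:
            if ((self.timestamps.second != 0) | (self.timestamps.microsecond != 0)).any():
                raise ValueError(f"site {self.site_id}: timestamps not minute-aligned")
            diffs = np.diff(self.timestamps.asi8)
            if (diffs <= 0).any():
                bad = self.timestamps[1:][diffs <= 0][0]
                raise ValueError(
                    f"site {self.site_id}: timestamps not strictly increasing "
                    f"(at {bad})"
                )
        if not np.isfinite(self.levels).all():
            raise ValueError(f"site {self.site_id}: non-finite level values")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def below_floor_mask(self) -> np.ndarray:
        """Boolean mask of minutes below the 30 dBA instrument noise floor."""
        return self.levels < NOISE_FLOOR_DBA

    @property
    def n_below_floor(self) -> int:
        return int(self.below_floor_mask.sum())

    def dates(self) -> list[_date]:
        """Calendar dates with at least one observation."""
        return sorted(set(self.timestamps.date))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_id, "timestamp": self.timestamps, "laeq_1min": self.levels}
        )


@dataclass(frozen=True)
class SiteRecord:
    """Identity, location and design role of a monitoring site."""

    site_id: str
    latitude: float
    longitude: float
    land_use: str
    road_class: str
    site_type: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.site_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"site {self.site_id}: longitude {self.longitude} out of range")
        if self.land_use not in LAND_USE_CLASSES:
            raise ValueError(
                f"site {self.site_id}: land_use {self.land_use!r} not one of "
                f"{LAND_USE_CLASSES}"
            )
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(
                f"site {self.site_id}: road_class {self.road_class!r} not one of "
                f"{ROAD_CLASSES}"
            )
        if self.site_type not in SITE_TYPES:
            raise ValueError(
                f"site {self.site_id}: site_type {self.site_type!r} not one of {SITE_TYPES}"
            )


@dataclass(frozen=True)
class ClipPrediction:
    """Top-3 detected sound classes for one 10-s audio clip.

    The classifier's three highest-probability classes are retained per clip;
    scores are probabilities in [0, 1], non-increasing.
    """

    site_id: str
    timestamp: pd.Timestamp
    labels: tuple[str, str, str]
    scores: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if len(self.labels) != 3:
            raise ValueError(f"clip needs exactly 3 labels, got {len(self.labels)}")
        if len(set(self.labels)) != 3:
            raise ValueError(f"clip labels not distinct: {self.labels}")
        if len(self.scores) != 3:
            raise ValueError(f"clip needs exactly 3 scores, got {len(self.scores)}")
        for s in self.scores:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0, 1]")
        if not (self.scores[0] >= self.scores[1] >= self.scores[2]):
            raise ValueError(f"scores not descending: {self.scores}")


@dataclass
class PeriodMetrics:
    """Per-site, per-date derived metrics.

    Level metrics are dBA; IR values are percent, keyed by the event cutoff
    K (dBA above the window LAeq). ``None`` marks a metric that could not be
    computed (window coverage below the configured minimum). ``coverage``
    maps window name -> observed/expected minute fraction.
    """

    site_id: str
    date: _date
    laeq_24hr: float | None
    l_day: float | None
    l_night: float | None
    ir_24hr: dict[int, float | None] = field(default_factory=dict)
    ir_day: dict[int, float | None] = field(default_factory=dict)
    ir_night: dict[int, float | None] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
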
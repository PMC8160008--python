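"""Analysis configuration shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis.

    Attributes
    ----------
    day_start_hour, day_end_hour : int
        Daytime window 06:00-21:59 by default: hours ``day_start_hour``
        through ``day_end_hour`` inclusive. Night is the complement
        (22:00-05:59), so the two windows partition the 24-h day.
    cutoffs : tuple of int
        Event cutoffs K (dBA above the window LAeq) for the Intermittency
        Ratio; the primary cutoff is +3 dBA with +4 and +5 as alternatives.
    min_coverage : float
        Minimum observed/expected minute fraction per window before a
        metric is emitted; windows below it are reported missing.
    night_convention : str
        ``"calendar"`` (default): the night of date D comprises minutes
        00:00-05:59 and 22:00-23:59 of D, making every metric a pure
        function of one calendar date. ``"spanning"``: 22:00 of D through
        05:59 of D+1.
    level_bin_edges : numpy.ndarray
        Half-open 5-dB bin edges for prevalence-by-level tables; a minute
        at level L falls in bin (e_i, e_{i+1}] — e.g. edges 50, 55 give the
        printed "51-55 dBA" style interval, with a minute at exactly 55.0
        in the lower bin. Extremes are open-ended.
    flight_path : list of (lat, lon)
        Polyline approximating the airport landing/take-off trajectory.
    flight_buffer_m : float
        Buffer distance around the flight path (metres, default 1 km).
    seed : int
        Random seed for every stochastic operation.
    """

    day_start_hour: int = 6
    day_end_hour: int = 21
    cutoffs: tuple[int, ...] = (3, 4, 5)
    min_coverage: float = 0.8
    night_convention: str = "calendar"
    level_bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(30.0, 100.0, 5.0)
    )
    flight_path: list[tuple[float, float]] = field(
        default_factory=lambda: [(5.595, -0.180), (5.615, -0.155)]
    )
    flight_buffer_m: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.level_bin_edges = np.asarray(self.level_bin_edges, dtype=float)
        if not 0 <= self.day_start_hour < self.day_end_hour <= 23:
            raise ValueError("day window hours must satisfy 0 <= start < end <= 23")
        if any(k <= 0 for k in self.cutoffs):
            raise ValueError("IR cutoffs must be strictly positive")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.night_convention not in ("calendar", "spanning"):
            raise ValueError("night_convention must be 'calendar' or 'spanning'")
        if (np.diff(self.level_bin_edges) <= 0).any():
            raise ValueError("level_bin_edges must be strictly increasing")

    @property
    def day_hours(self) -> tuple[int, ...]:
        return tuple(range(self.day_start_hour, self.day_end_hour + 1))

    @property
    def night_hours(self) -> tuple[int, ...]:
        return tuple(h for h in range(24) if h not in self.day_hours)

    # expected minutes per window, fixed by the clock
    @property
    def expected_minutes(self) -> dict[str, int]:
        n_day = 60 * len(self.day_hours)
        return {"full": 1440, "day": n_day, "night": 1440 - n_day}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load configuration from a YAML file; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        if "flight_path" in raw:
            raw["flight_path"] = [tuple(p) for p in raw["flight_path"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "day_start_hour": self.day_start_hour,
            "day_end_hour": self.day_end_hour,
            "cutoffs": list(self.cutoffs),
            "min_coverage": self.min_coverage,
            "night_convention": self.night_convention,
            "level_bin_edges": [float(e) for e in self.level_bin_edges],
            "flight_path": [list(p) for p in self.flight_path],
            "flight_buffer_m": self.flight_buffer_m,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
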
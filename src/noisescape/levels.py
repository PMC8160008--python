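"""Equivalent continuous sound levels and the Intermittency Ratio.

The equivalent continuous level LAeq_T is the steady level carrying the
same total acoustic energy as the fluctuating signal over period T:

    LAeq = 10 * log10( mean_i 10^(L_i / 10) )

The Intermittency Ratio (IR) is the percentage of a window's total sound
energy contributed by "event" minutes — minutes whose LAeq_1min surpasses
the window LAeq plus a fixed cutoff K dBA:

    IR = 100 * sum_{i: L_i > LAeq + K} 10^(L_i/10) / sum_i 10^(L_i/10)

IR is 0 for a steady environment and approaches (but never reaches) 100
for one dominated by emergent events; it discriminates peaky from steady
sound environments at the same average level.

Events are resolved at the minute, the integration period of the logger;
the event inequality is strict (a minute exactly at LAeq + K is not an
event).
"""

from __future__ import annotations

from datetime import date as _date, datetime, timedelta

import numpy as np
import pandas as pd

from noisescape.config import AnalysisConfig
from noisescape.types import MinuteLevelSeries, PeriodMetrics

WINDOWS = ("full", "day", "night")


def energetic_average(levels) -> float:
    """Energetic (power) average of sound levels, in dBA.

    Averages on the linear energy scale 10^(L/10) and converts back to
    decibels. Always lies in [min, max] of the inputs and is >= their
    arithmetic mean (Jensen's inequality on the convex exponential).

    Raises
    ------
    ValueError
        If ``levels`` is empty or contains non-finite values.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("no observations in window")
    if not np.isfinite(levels).all():
        raise ValueError("non-finite levels in window")
    # factor out the max for numerical stability at extreme levels
    ref = levels.max()
    return float(ref + 10.0 * np.log10(np.mean(10.0 ** ((levels - ref) / 10.0))))


def detect_events(levels, window_laeq: float, cutoff: float) -> np.ndarray:
    """Flag event minutes: LAeq_1min strictly above ``window_laeq + cutoff``.

    Returns a boolean mask of the same length as ``levels``. For any
    cutoff > 0 at least one minute is always unflagged, since the
    energetic mean lies within the range of the minute levels.
    """
    levels = np.asarray(levels, dtype=float)
    return levels > window_laeq + cutoff


def intermittency_ratio(levels, cutoff: float, window_laeq: float | None = None) -> float:
    """Intermittency Ratio (percent) of a window of minute levels.

    Parameters
    ----------
    levels : array-like
        LAeq_1min values (dBA) observed in the window.
    cutoff : float
        Fixed event cutoff K in dBA above the window LAeq (study default
        +3, with +4 and +5 as alternatives).
    window_laeq : float, optional
        Precomputed window LAeq; computed from ``levels`` if omitted.

    Returns
    -------
    float
        IR in [0, 100); 0 when no minute exceeds the threshold, and
        strictly below 100 for cutoff > 0 because the energy of the
        sub-threshold minutes is always positive.
    """
    levels = np.asarray(levels, dtype=float)
    if window_laeq is None:
        window_laeq = energetic_average(levels)
    mask = detect_events(levels, window_laeq, cutoff)
    if not mask.any():
        return 0.0
    ref = levels.max()
    energy = 10.0 ** ((levels - ref) / 10.0)
    return float(100.0 * energy[mask].sum() / energy.sum())


def _date_slice(series: MinuteLevelSeries, start: datetime, end: datetime):
    """Levels observed in [start, end) via binary search on the sorted index."""
    lo = series.timestamps.searchsorted(start, side="left")
    hi = series.timestamps.searchsorted(end, side="left")
    return series.timestamps[lo:hi], series.levels[lo:hi]


def window_levels(
    series: MinuteLevelSeries,
    date: _date,
    window: str,
    config: AnalysisConfig,
) -> np.ndarray:
    """Minute levels of ``series`` falling in a clock window on ``date``.

    ``window`` is one of ``"full"`` (the whole calendar day), ``"day"``
    (06:00-21:59 by default) or ``"night"``. Under the default
    ``calendar`` night convention the night of date D is 00:00-05:59 plus
    22:00-23:59 of D; under ``spanning`` it is 22:00 of D to 05:59 of D+1.
    """
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}, got {window!r}")
    d0 = datetime(date.year, date.month, date.day)
    if window == "night" and config.night_convention == "spanning":
        ts, lv = _date_slice(series, d0 + timedelta(hours=22), d0 + timedelta(hours=30))
        return lv
    ts, lv = _date_slice(series, d0, d0 + timedelta(days=1))
    if window == "full":
        return lv
    hours = ts.hour
    in_day = (hours >= config.day_start_hour) & (hours <= config.day_end_hour)
    return lv[in_day] if window == "day" else lv[~in_day]


def period_level(
    series: MinuteLevelSeries,
    date: _date,
    window: str,
    config: AnalysisConfig | None = None,
) -> tuple[float | None, float]:
    """Window LAeq (dBA) and coverage for one site-date.

    Returns ``(laeq, coverage)`` where coverage is the observed fraction
    of the window's clock minutes. When coverage falls below
    ``config.min_coverage`` the level is ``None`` (missing), never an
    exception — incomplete windows are an expected feature of field data.
    """
    config = config or AnalysisConfig()
    lv = window_levels(series, date, window, config)
    coverage = len(lv) / config.expected_minutes[window]
    if len(lv) == 0 or coverage < config.min_coverage:
        return None, coverage
    return energetic_average(lv), coverage


def aggregate_hourly(
    series: MinuteLevelSeries,
    date: _date,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """LAeq_1hr for each of the 24 clock hours of ``date``.

    Returns a length-24 float array; hours with coverage below the
    configured minimum (of 60 expected minutes) are NaN.
    """
    config = config or AnalysisConfig()
    d0 = datetime(date.year, date.month, date.day)
    ts, lv = _date_slice(series, d0, d0 + timedelta(days=1))
    out = np.full(24, np.nan)
    if len(lv) == 0:
        return out
    hours = np.asarray(ts.hour)
    for h in range(24):
        hl = lv[hours == h]
        if len(hl) / 60.0 >= config.min_coverage and len(hl) > 0:
            out[h] = energetic_average(hl)
    return out


def daily_metrics(
    series: MinuteLevelSeries,
    date: _date,
    config: AnalysisConfig | None = None,
) -> PeriodMetrics:
    """All level and intermittency metrics for one site-date.

    Assembles LAeq_24hr, L_day, L_night and the Intermittency Ratio for
    each window at every configured cutoff, together with per-window
    coverage. Sub-metrics whose window falls below minimum coverage are
    None; their IRs are None too.
    """
    config = config or AnalysisConfig()
    laeq: dict[str, float | None] = {}
    cov: dict[str, float] = {}
    irs: dict[str, dict[int, float | None]] = {}
    for window in WINDOWS:
        lv = window_levels(series, date, window, config)
        cov[window] = len(lv) / config.expected_minutes[window]
        if len(lv) == 0 or cov[window] < config.min_coverage:
            laeq[window] = None
            irs[window] = {k: None for k in config.cutoffs}
            continue
        laeq[window] = energetic_average(lv)
        irs[window] = {
            k: intermittency_ratio(lv, k, window_laeq=laeq[window])
            for k in config.cutoffs
        }
    return PeriodMetrics(
        site_id=series.site_id,
        date=date,
        laeq_24hr=laeq["full"],
        l_day=laeq["day"],
        l_night=laeq["night"],
        ir_24hr=irs["full"],
        ir_day=irs["day"],
        ir_night=irs["night"],
        coverage=cov,
    )


def metrics_table(
    series_collection,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-site, per-date metrics for a collection of minute series.

    Returns a DataFrame sorted by (site_id, date) with one row per
    site-date, columns ``laeq_24hr``, ``l_day``, ``l_night``,
    ``ir_<window>_k<K>`` for every configured cutoff K, and per-window
    coverage. Missing metrics are NaN.
    """
    config = config or AnalysisConfig()
    rows = []
    for series in series_collection:
        for date in series.dates():
            m = daily_metrics(series, date, config)
            row: dict = {"site_id": m.site_id, "date": m.date}
            row["laeq_24hr"] = np.nan if m.laeq_24hr is None else m.laeq_24hr
            row["l_day"] = np.nan if m.l_day is None else m.l_day
            row["l_night"] = np.nan if m.l_night is None else m.l_night
            for name, d in (("24hr", m.ir_24hr), ("day", m.ir_day), ("night", m.ir_night)):
                for k in config.cutoffs:
                    v = d.get(k)
                    row[f"ir_{name}_k{k}"] = np.nan if v is None else v
            for window in WINDOWS:
                row[f"coverage_{window}"] = m.coverage[window]
            rows.append(row)
    if not rows:
        cols = ["site_id", "date", "laeq_24hr", "l_day", "l_night"]
        cols += [f"ir_{w}_k{k}" for w in ("24hr", "day", "night") for k in config.cutoffs]
        cols += [f"coverage_{w}" for w in WINDOWS]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows).sort_values(["site_id", "date"]).reset_index(drop=True)
    return df
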
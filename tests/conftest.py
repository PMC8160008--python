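"""Shared fixtures and independent oracles.

The oracles here deliberately share no code with the package: brute-force
loops over minutes for the level metrics, and full enumeration for the
rank-sum test. They exist so the vectorized implementations can be checked
against an independent route.
"""

from __future__ import annotations

import math
from datetime import date, datetime
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from noisescape.config import AnalysisConfig
from noisescape.types import MinuteLevelSeries, SiteRecord


# ---------------------------------------------------------------- oracles


def laeq_bruteforce(levels) -> float:
    """Energetic average by a direct python loop."""
    total = 0.0
    for lv in levels:
        total += 10.0 ** (lv / 10.0)
    return 10.0 * math.log10(total / len(levels))


def ir_bruteforce(levels, cutoff: float) -> float:
    """Intermittency Ratio by direct summation, no shared code."""
    laeq = laeq_bruteforce(levels)
    total = 0.0
    event = 0.0
    for lv in levels:
        e = 10.0 ** (lv / 10.0)
        total += e
        if lv > laeq + cutoff:
            event += e
    return 100.0 * event / total


def ranksum_exact_enumeration(a, b) -> float:
    """Two-sided exact rank-sum p-value by enumerating every assignment
    of the pooled ranks to group A (ties assumed absent)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(pooled)
    all_ws = [sum(c) for c in combinations(range(1, n + 1), len(a))]
    mean_w = len(a) * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in all_ws if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(all_ws)


# --------------------------------------------------------------- builders


def make_series(levels, site_id="S1", start="2021-03-01 00:00") -> MinuteLevelSeries:
    """Minute series with consecutive timestamps from ``start``."""
    ts = pd.date_range(start, periods=len(levels), freq="min")
    return MinuteLevelSeries(site_id=site_id, timestamps=ts, levels=np.asarray(levels, float))


def full_day_series(levels_by_minute, site_id="S1", day=date(2021, 3, 1)) -> MinuteLevelSeries:
    assert len(levels_by_minute) == 1440
    ts = pd.date_range(datetime(day.year, day.month, day.day), periods=1440, freq="min")
    return MinuteLevelSeries(site_id=site_id, timestamps=ts, levels=np.asarray(levels_by_minute, float))


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def site() -> SiteRecord:
    return SiteRecord("S1", 5.6, -0.2, "high-density residential", "minor", "rotating")
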
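"""Synthetic minute-level sound series and coupled clip-prediction streams.

The generator emulates the statistical structure an urban monitoring
campaign produces, so every pipeline stage is testable without field
data. The minute-level model is

    L(t) = baseline + diurnal(hour) + AR(1) noise   [background, dB]

with sound events arriving as a Poisson process (hour-dependent rate),
lasting a random whole number of minutes and adding a lognormal dB excess
*energetically* on top of the background:

    L_minute = 10*log10( 10^(L_bg/10) + 10^((L_bg + excess)/10) )

Levels are clipped below at the 30 dBA instrument noise floor (the only
place in the package that clips). Clip streams draw multi-label source
presence per 10-min grid point with hour- and land-use-dependent
probabilities, plus a coupling term that raises road-transport presence
probability during event minutes.

Default parameters are synthetic calibrations, not estimates: they are
chosen so the four land-use archetypes reproduce the qualitative
phenomena of a heterogeneous city — the archetype level ordering
(commercial > high-density > medium/low-density > peri-urban), day above
night levels, intermittency highest where the background is quiet, and
the negative cross-site association between road-sound prevalence and
intermittency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date, datetime, timedelta

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from noisescape.sources import DEFAULT_CATEGORY_MAP, ValidationCounts
from noisescape.types import (
    ClipPrediction,
    MinuteLevelSeries,
    SiteRecord,
    LAND_USE_CLASSES,
    SOURCE_CATEGORIES,
)

PERI, MEDLOW, HIGH, CBI = LAND_USE_CLASSES

# fine-label pools per category, inverted from the default map
_LABEL_POOLS: dict[str, list[str]] = {}
for _lbl, _cat in sorted(DEFAULT_CATEGORY_MAP.items()):
    _LABEL_POOLS.setdefault(_cat, []).append(_lbl)


def default_diurnal_weights() -> np.ndarray:
    """Hourly weights in [0, 1] shaping the day-night contrast: quiet
    pre-dawn, morning ramp, busy daytime, evening taper."""
    w = np.zeros(24)
    w[5] = 0.3
    w[6] = 0.7
    w[7:20] = 1.0
    w[20] = 0.8
    w[21] = 0.6
    w[22] = 0.3
    w[23] = 0.1
    return w


@dataclass
class ArchetypeParams:
    """Level-generation parameters for one land-use archetype.

    ``event_rate_per_hour`` is a 24-vector of Poisson arrival rates by
    hour of day; event durations are 1 + Poisson(mean - 1) whole minutes;
    event excesses over the concurrent background are lognormal with the
    given median (dB) and log-scale sigma.
    """

    baseline_night_dba: float
    day_contrast_dba: float
    diurnal_weights: np.ndarray = field(default_factory=default_diurnal_weights)
    ar1_coef: float = 0.6
    ar1_sd: float = 2.0
    event_rate_per_hour: np.ndarray = field(default_factory=lambda: np.full(24, 4.0))
    event_duration_mean_min: float = 2.0
    event_excess_median_db: float = 10.0
    event_excess_sigma: float = 0.5

    def __post_init__(self) -> None:
        self.diurnal_weights = np.asarray(self.diurnal_weights, dtype=float)
        self.event_rate_per_hour = np.asarray(self.event_rate_per_hour, dtype=float)
        if self.diurnal_weights.shape != (24,):
            raise ValueError("diurnal_weights must have 24 entries")
        if self.event_rate_per_hour.shape != (24,):
            raise ValueError("event_rate_per_hour must have 24 entries")
        if (self.event_rate_per_hour < 0).any():
            raise ValueError("event_rate_per_hour must be >= 0")
        if self.event_duration_mean_min < 1:
            raise ValueError("event_duration_mean_min must be >= 1 minute")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")


def _day_night_rates(day: float, night: float) -> np.ndarray:
    r = np.full(24, night)
    r[6:22] = day
    return r


@dataclass
class SimulationProfile:
    """Full generative configuration for a synthetic campaign.

    ``presence_base`` gives each category's daytime presence probability
    per land use; ``presence_hour_logit`` adds a per-hour logit offset;
    ``coupling`` adds a logit bonus during event minutes (road-transport
    by default, making road sounds more likely while an event is
    running). ``gap_probability`` drops each minute independently to
    emulate logger outages.
    """

    archetypes: dict[str, ArchetypeParams]
    presence_base: dict[str, dict[str, float]]
    presence_hour_logit: dict[str, np.ndarray]
    coupling: dict[str, float] = field(default_factory=lambda: {"road-transport": 1.0})
    noise_floor_dba: float = 30.0
    gap_probability: float = 0.0

    def __post_init__(self) -> None:
        for lu in self.archetypes:
            if lu not in LAND_USE_CLASSES:
                raise ValueError(f"unknown land use {lu!r}")
        for cat, per_lu in self.presence_base.items():
            for lu, p in per_lu.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"presence_base[{cat}][{lu}] = {p} outside [0, 1]")
        if not 0.0 <= self.gap_probability < 1.0:
            raise ValueError("gap_probability must be in [0, 1)")

    @classmethod
    def default(cls) -> "SimulationProfile":
        """Synthetic default archetypes, ordered CBI > high > med/low > peri.

        Quiet archetypes get salient events (high excess over a low
        background, hence high intermittency); the commercial archetype
        gets a loud steady background with modest excesses, hence low
        intermittency.
        """
        archetypes = {
            PERI: ArchetypeParams(
                baseline_night_dba=46.0, day_contrast_dba=8.0,
                ar1_sd=1.5,
                event_rate_per_hour=_day_night_rates(0.8, 0.3),
                event_duration_mean_min=1.5,
                event_excess_median_db=13.0,
            ),
            MEDLOW: ArchetypeParams(
                baseline_night_dba=51.0, day_contrast_dba=8.0,
                ar1_sd=1.8,
                event_rate_per_hour=_day_night_rates(1.0, 0.5),
                event_duration_mean_min=1.5,
                event_excess_median_db=11.0,
            ),
            HIGH: ArchetypeParams(
                baseline_night_dba=58.0, day_contrast_dba=8.0,
                ar1_sd=2.0,
                event_rate_per_hour=_day_night_rates(1.1, 0.55),
                event_duration_mean_min=1.5,
                event_excess_median_db=10.0,
            ),
            CBI: ArchetypeParams(
                baseline_night_dba=61.0, day_contrast_dba=8.0,
                ar1_sd=2.0,
                event_rate_per_hour=_day_night_rates(1.2, 0.6),
                event_duration_mean_min=1.5,
                event_excess_median_db=8.0,
            ),
        }
        presence_base = {
            "road-transport": {PERI: 0.30, MEDLOW: 0.55, HIGH: 0.75, CBI: 0.90},
            "animals-and-insects": {PERI: 0.50, MEDLOW: 0.30, HIGH: 0.25, CBI: 0.15},
            "outdoor-music": {PERI: 0.05, MEDLOW: 0.10, HIGH: 0.15, CBI: 0.12},
            "human-speech": {PERI: 0.15, MEDLOW: 0.35, HIGH: 0.50, CBI: 0.50},
            "aircraft": {PERI: 0.02, MEDLOW: 0.02, HIGH: 0.02, CBI: 0.02},
            "nature": {PERI: 0.35, MEDLOW: 0.15, HIGH: 0.10, CBI: 0.08},
            "other": {PERI: 0.25, MEDLOW: 0.25, HIGH: 0.25, CBI: 0.25},
        }
        hour_logit = {cat: np.zeros(24) for cat in SOURCE_CATEGORIES}
        night = np.r_[np.ones(6), np.zeros(16), np.ones(2)].astype(bool)
        hour_logit["road-transport"][night] = -0.9
        hour_logit["animals-and-insects"][night] = +1.0
        hour_logit["human-speech"][night] = -1.5
        hour_logit["outdoor-music"][17:22] = +0.8
        hour_logit["outdoor-music"][night] = -1.0
        return cls(
            archetypes=archetypes,
            presence_base=presence_base,
            presence_hour_logit=hour_logit,
        )

    def with_overrides(self, **kwargs) -> "SimulationProfile":
        return replace(self, **kwargs)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def simulate_site_levels(
    profile: SimulationProfile,
    site: SiteRecord,
    start_date: _date,
    n_days: int,
    seed: int,
) -> MinuteLevelSeries:
    """Simulate a site's minute-level series over ``n_days``.

    Background is baseline + diurnal + stationary AR(1) noise; events are
    superimposed energetically, then the result is clipped at the noise
    floor and minutes are dropped independently with ``gap_probability``.
    Deterministic for fixed (profile, site, dates, seed).
    """
    try:
        params = profile.archetypes[site.land_use]
    except KeyError:
        raise ValueError(f"profile has no archetype for land use {site.land_use!r}")
    rng = np.random.default_rng(seed)
    n = n_days * 1440
    t0 = datetime(start_date.year, start_date.month, start_date.day)
    timestamps = pd.date_range(t0, periods=n, freq="min")
    hours = np.asarray(timestamps.hour)

    diurnal = params.day_contrast_dba * params.diurnal_weights[hours]
    # stationary AR(1): innovations scaled so the marginal sd is ar1_sd
    innov_sd = params.ar1_sd * np.sqrt(1.0 - params.ar1_coef**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, params.ar1_sd)
    ar1 = lfilter([1.0], [1.0, -params.ar1_coef], eps)
    background = params.baseline_night_dba + diurnal + ar1

    # Poisson events: count per clock hour, uniform start minute, whole-
    # minute durations, lognormal dB excess over the concurrent background
    event_energy = np.zeros(n)
    counts = rng.poisson(params.event_rate_per_hour[hours[::60]])
    total = int(counts.sum())
    if total > 0:
        hour_starts = np.repeat(np.arange(len(counts)) * 60, counts)
        offsets = rng.integers(0, 60, size=total)
        starts = hour_starts + offsets
        durations = 1 + rng.poisson(params.event_duration_mean_min - 1.0, size=total)
        excesses = rng.lognormal(
            np.log(params.event_excess_median_db), params.event_excess_sigma, size=total
        )
        for s, d, ex in zip(starts, durations, excesses):
            e = min(s + d, n)
            event_energy[s:e] += 10.0 ** ((background[s:e] + ex) / 10.0)

    levels = 10.0 * np.log10(10.0 ** (background / 10.0) + event_energy)
    levels = np.maximum(levels, profile.noise_floor_dba)

    if profile.gap_probability > 0.0:
        keep = rng.random(n) >= profile.gap_probability
        timestamps, levels = timestamps[keep], levels[keep]
    return MinuteLevelSeries(site_id=site.site_id, timestamps=timestamps, levels=levels)


def _event_minutes(series: MinuteLevelSeries, cutoff: float = 3.0) -> np.ndarray:
    """Boolean event flag per observed minute, using the daily LAeq + cutoff
    threshold — the same observable event definition the analysis uses."""
    df = pd.DataFrame({"d": series.timestamps.date, "lv": series.levels})
    energy = 10.0 ** (df["lv"] / 10.0)
    daily_laeq = 10.0 * np.log10(energy.groupby(df["d"]).transform("mean"))
    return (df["lv"] > daily_laeq + cutoff).to_numpy()


def simulate_clip_stream(
    profile: SimulationProfile,
    site: SiteRecord,
    series: MinuteLevelSeries,
    seed: int,
) -> tuple[list[ClipPrediction], int]:
    """Simulate the 10-s-every-10-min audio-classifier output at a site.

    One clip per 10-min grid point of the series' span; grid points whose
    minute has no level observation are skipped and counted (second
    return value). Category presence is Bernoulli with logit
    base(category, land use) + hour offset + coupling * 1[event minute];
    the three clip labels are drawn from the pools of the present
    categories (at most three categories can be realized per clip), with
    descending scores.
    """
    if len(series) == 0:
        return [], 0
    rng = np.random.default_rng(seed)
    t0 = series.timestamps[0].floor("D")
    t1 = series.timestamps[-1]
    grid = pd.date_range(t0, t1, freq="10min")
    # map grid points to observed minutes
    pos = series.timestamps.searchsorted(grid, side="left")
    has_minute = (pos < len(series)) & (
        series.timestamps[np.minimum(pos, len(series) - 1)] == grid
    )
    n_skipped = int((~has_minute).sum())
    grid = grid[has_minute]
    pos = pos[has_minute]
    if len(grid) == 0:
        return [], n_skipped

    events = _event_minutes(series)[pos]
    hours = np.asarray(grid.hour)
    cats = list(SOURCE_CATEGORIES)
    logits = np.empty((len(grid), len(cats)))
    for j, cat in enumerate(cats):
        base = profile.presence_base.get(cat, {}).get(site.land_use, 0.0)
        logits[:, j] = _logit(np.full(len(grid), base))
        logits[:, j] += profile.presence_hour_logit.get(cat, np.zeros(24))[hours]
        logits[:, j] += profile.coupling.get(cat, 0.0) * events
    probs = 1.0 / (1.0 + np.exp(-logits))
    draws = rng.random(probs.shape) < probs

    clips: list[ClipPrediction] = []
    other_idx = cats.index("other")
    for i in range(len(grid)):
        present = np.flatnonzero(draws[i])
        if present.size == 0:
            present = np.array([other_idx])
        if present.size > 3:  # a clip can realize at most 3 categories:
            # keep those with the highest presence probability
            present = present[np.argsort(-probs[i, present], kind="stable")[:3]]
        labels: list[str] = []
        for j in present:
            pool = _LABEL_POOLS[cats[j]]
            labels.append(pool[rng.integers(len(pool))])
        # fill remaining slots with distinct labels from the present pools
        k = 0
        pools = [lbl for j in present for lbl in _LABEL_POOLS[cats[j]]]
        while len(labels) < 3:
            cand = pools[rng.integers(len(pools))]
            if cand not in labels:
                labels.append(cand)
            k += 1
            if k > 50:  # tiny pools: fall back to deterministic fill
                for cand in pools:
                    if cand not in labels and len(labels) < 3:
                        labels.append(cand)
                break
        scores = np.sort(rng.random(3))[::-1]
        clips.append(
            ClipPrediction(
                site_id=site.site_id,
                timestamp=grid[i],
                labels=tuple(labels),
                scores=tuple(scores),
            )
        )
    return clips, n_skipped


def simulate_validation_set(
    n_clips: int,
    target_ppv: dict[str, float],
    seed: int,
) -> tuple[pd.DataFrame, ValidationCounts]:
    """Emulate a blinded manual validation of classifier predictions.

    Each clip gets one predicted category (cycled over ``target_ppv``
    keys); the prediction is manually confirmed with probability
    target/100, so the realized PPV converges to the target as n grows.
    Returns the per-clip table (predicted category, manually-true flag)
    and the exact per-category confusion counts.
    """
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    for cat, t in target_ppv.items():
        if not 0.0 < t <= 100.0:
            raise ValueError(f"target PPV for {cat} must be in (0, 100], got {t}")
    rng = np.random.default_rng(seed)
    cats = sorted(target_ppv)
    predicted = [cats[i % len(cats)] for i in range(n_clips)]
    confirmed = [rng.random() < target_ppv[c] / 100.0 for c in predicted]
    df = pd.DataFrame({"clip": range(n_clips), "predicted": predicted, "true": confirmed})
    tp = {c: int(((df["predicted"] == c) & df["true"]).sum()) for c in cats}
    fp = {c: int(((df["predicted"] == c) & ~df["true"]).sum()) for c in cats}
    return df, ValidationCounts(tp=tp, fp=fp)


#: Fixed-site archetype allocation mirroring a small permanent network:
#: 3 commercial, 2 high-density, 4 medium/low-density, 1 peri-urban.
FIXED_SITE_MIX = (CBI, CBI, CBI, HIGH, HIGH, MEDLOW, MEDLOW, MEDLOW, MEDLOW, PERI)


def simulate_campaign(
    profile: SimulationProfile | None = None,
    n_rotating: int = 136,
    n_fixed: int = 10,
    rotating_days: int = 7,
    fixed_days: int = 365,
    start: _date = _date(2019, 4, 1),
    seed: int = 0,
    with_clips: bool = True,
) -> dict:
    """Simulate a full mixed monitoring campaign.

    ``n_rotating`` week-long sites spread evenly over the four land-use
    archetypes plus ``n_fixed`` year-long sites allocated per
    :data:`FIXED_SITE_MIX`. Rotating deployments start on consecutive
    weeks cycling through the year. Returns a dict with ``sites``
    (site_id -> SiteRecord), ``series`` (list of MinuteLevelSeries) and,
    when ``with_clips``, ``clips`` (list of ClipPrediction).
    """
    profile = profile or SimulationProfile.default()
    root = np.random.SeedSequence(seed)
    site_seeds = root.generate_state(2 * (n_rotating + n_fixed) + 1) % (2**31)
    coord_rng = np.random.default_rng(site_seeds[-1])

    sites: dict[str, SiteRecord] = {}
    series: list[MinuteLevelSeries] = []
    clips: list[ClipPrediction] = []

    def _make_site(site_id: str, land_use: str, site_type: str) -> SiteRecord:
        # scatter around central Accra
        lat = 5.60 + coord_rng.uniform(-0.15, 0.15)
        lon = -0.20 + coord_rng.uniform(-0.20, 0.20)
        road = ("major", "secondary/tertiary", "minor")[coord_rng.integers(3)]
        return SiteRecord(site_id, lat, lon, land_use, road, site_type)

    for i in range(n_rotating):
        land_use = LAND_USE_CLASSES[i % 4]
        site = _make_site(f"R{i:03d}", land_use, "rotating")
        sites[site.site_id] = site
        week = (i * 7) % 350
        s = simulate_site_levels(
            profile, site, start + timedelta(days=week), rotating_days, int(site_seeds[2 * i])
        )
        series.append(s)
        if with_clips:
            clips.extend(simulate_clip_stream(profile, site, s, int(site_seeds[2 * i + 1]))[0])

    for i in range(n_fixed):
        land_use = FIXED_SITE_MIX[i % len(FIXED_SITE_MIX)]
        site = _make_site(f"F{i:02d}", land_use, "fixed")
        sites[site.site_id] = site
        j = 2 * (n_rotating + i)
        s = simulate_site_levels(profile, site, start, fixed_days, int(site_seeds[j]))
        series.append(s)
        if with_clips:
            clips.extend(simulate_clip_stream(profile, site, s, int(site_seeds[j + 1]))[0])

    out = {"sites": sites, "series": series}
    if with_clips:
        out["clips"] = clips
    return out
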
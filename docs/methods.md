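# Methods

## Level metrics

All level aggregation is energetic: a window's equivalent continuous level
is `LAeq = 10·log10(mean 10^(L_i/10))` over its observed minutes. The
implementation factors out the window maximum before exponentiating, so it
is stable at arbitrary levels. `L_day` covers 06:00–21:59 and `L_night`
22:00–05:59; the two windows partition the clock and both bounds are
configurable (`AnalysisConfig.day_start_hour` / `day_end_hour`).

Two night conventions are supported. The default, *calendar*, assigns the
night of date D the minutes 00:00–05:59 and 22:00–23:59 of D, which makes
every metric a pure function of one calendar date. The *spanning*
alternative (22:00 of D through 05:59 of D+1) matches the lived night and
is selectable per run; the two differ only in how the small hours are
attributed across dates.

Timestamps are timezone-naive local wall-clock throughout. The target
setting sits on UTC+0 with no daylight-saving shifts, so no timezone logic
exists anywhere; applying the package in a DST region would need external
pre-processing.

## The Intermittency Ratio

A minute is an *event* iff its `LAeq_1min` strictly exceeds the window
LAeq plus a fixed cutoff `K` (default 3 dBA; 4 and 5 available). "Strictly"
is a deliberate boundary choice — a minute exactly at threshold is not an
event — and is covered by a boundary test. The IR is the event minutes'
share of the window's total energy, in percent. Events are resolved at the
minute because that is the logger's integration period; no sub-minute
onset/offset reconstruction is attempted, and contiguous event minutes are
not merged into episodes (episode counting is a different statistic).

Useful identities the test suite exploits: IR is invariant to adding a
constant to every minute (both the threshold and all energies shift
together); IR is non-increasing in K; and a two-level series with fraction
`p` of minutes at `L+Δ` has `IR = 100·p·r/(p·r+1−p)` with `r = 10^(Δ/10)`
whenever `L+Δ` clears the threshold and `L` does not.

## Coverage and missingness

Expected minutes per window are fixed by the clock (1440 / 960 / 480).
Coverage = observed/expected, and a window below the minimum coverage
(default 0.8; no completeness rule is standard, so this is a package
choice) yields a missing metric rather than an exception. Gaps are never
filled, duplicate (site, minute) rows are a hard read error — silently
averaging duplicates would corrupt event detection — and levels below the
30 dBA instrument noise floor are flagged on input but never clipped by
the metrics engine. The only clipping in the package happens inside the
simulator, which emulates the instrument.

## Source presence and prevalence

Each 10-s clip retains its three highest-scoring classifier labels (ties
broken lexicographically for determinism). The fine-label → category map
ships as an editable table covering common urban labels of an
AudioSet-style ontology; any unmapped label resolves to "other", so the
map is total. A category is present iff ≥1 retained label maps to it;
presence is therefore multi-label and order-invariant, and a clip realizes
between one and three categories.

Prevalence is clip-weighted ("% site-time"): the prevalence of a pooled
stratum equals the clip-count-weighted mean of its parts, exactly. For
prevalence-by-level, each clip joins the `LAeq_1min` of its enclosing
minute (the 10-s sample stands for its minute); bins are half-open `(lo,
hi]` 5-dB intervals with open-ended extremes, so a minute at exactly
55.0 dBA falls in the 51–55 bin. Unjoined clips are dropped and counted.

Flight-path proximity uses great-circle point-to-segment distance on the
sphere (cross-track distance when the projection falls within the arc,
nearest endpoint otherwise), with a 1-km default buffer. The default path
is a single straight segment through the airport runway bearing, supplied
in configuration.

## Summaries and tests

Quartiles use linear interpolation between closest order statistics (the
numpy default), stated so ports can match bit-for-bit. Group comparisons
use the two-sided Wilcoxon rank-sum: exact enumeration when both groups
have ≤20 observations without ties, otherwise the normal approximation
with mid-ranks and tie correction and *no* continuity correction, so
identical groups return p = 1 exactly. The exact branch is verified
against full enumeration of rank assignments.

## Representativeness

For each fixed site, `n_days` (default 5) dates are sampled *without
replacement* from the valid daily `LAeq_24hr` values; each sample is
compared with the yearly average as a signed dBA difference and a percent
difference on the dB scale. The yearly average defaults to the energetic
mean of the daily values — physically consistent with how the daily values
themselves average minute energies — with an arithmetic-mean flag for
sensitivity analysis. Pooled medians are medians over the concatenated
per-site samples. Sampling is reproducible given (seed, site list).

## The synthetic generator

Minute levels follow `L(t) = baseline + contrast·w(hour) + AR(1)`, with
`w` a 24-point diurnal weight curve (quiet pre-dawn, morning ramp, busy
day, evening taper) and the AR(1) parameterized by its marginal sd (default
coefficient 0.6). Events arrive as an inhomogeneous Poisson process (per
hour-of-day rates), last `1 + Poisson(mean−1)` whole minutes, and add a
lognormal dB excess (sigma 0.5 log-units) over the concurrent background
*energetically* — total energy is conserved additively, which a test
verifies against the closed form.

The four archetype defaults were calibrated once, qualitatively, to the
phenomenology of a heterogeneous tropical city and then frozen: night
baselines 46/51/58/61 dBA and day event rates 0.8/1.0/1.1/1.2 h⁻¹ with
excess medians 13/11/10/8 dB for peri-urban, medium/low-density
residential, high-density residential and commercial-business-industrial
respectively. These produce median `LAeq_24hr` ≈ 57/61/67/69 dBA
(commercial loudest) and median `IR_24hr(3)` ≈ 63/56/51/37% (peri-urban
most intermittent): loud steady backgrounds swallow their events; quiet
backgrounds make them salient.

Clip streams draw category presence per 10-min grid point with logit =
base(category, land use) + hour offset + coupling·1[event minute], the
coupling (default +1 logit for road-transport) operating on the observable
event definition (minute above daily LAeq + 3 dBA). Base probabilities
rise with urbanization for road transport and speech and fall for animals
and nature, which by construction produces the negative cross-site
correlation between road-sound prevalence and intermittency. When more
than three categories are drawn, the three with the highest presence
probability are realized — the analogue of top-3 score retention.
Validation sets confirm each predicted category with probability
target-PPV/100, returning the exact confusion counts.

## What the generator does and does not emulate

It reproduces: the archetype level ordering, day > night levels, the IR
ordering across land uses and its monotone decline in K, diurnal source
patterns, multi-label presence, and the prevalence–intermittency
anticorrelation. It does not emulate: weather, weekly/seasonal cycles,
spatial autocorrelation between nearby sites, classifier confusion
structure beyond a scalar PPV, or realistic heavy-tail *damping* — the
unbounded lognormal dB excess occasionally produces extreme minutes whose
energy dominates a whole synthetic year. Two visible consequences,
reported as-is: the yearly energetic average at fixed sites sits several
dB above the median day (so the synthetic pooled representativeness median
difference is strongly negative, unlike the near-zero value expected of
stationary field data — the stationary-null test, which generates daily
levels directly, shows the estimator itself is unbiased), and the IR
medians at K = 3/4/5 are monotone but closely spaced, because most
synthetic event energy clears even the +5 dBA cutoff. Passing tests on
synthetic data therefore validate the *operators*, not field realism.

## Problem sizes

The test suite and acceptance script run the full campaign design (136
rotating × 7 days + 10 fixed × 365 days ≈ 6.6 M minutes, ≈ 660 k clips),
1,000-series oracle comparisons, 10,000 rank-sum null replicates, 100-seed
prevalence recovery and 200-seed representativeness resampling; the whole
acceptance script completes in about a minute on one CPU.
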
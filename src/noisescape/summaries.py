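"""Stratified descriptive statistics and representativeness analysis.

Metrics are summarized as medians and interquartile ranges within spatial
strata (land use, road class, region) and temporal strata (hour, weekday,
month); group differences use the two-sided Wilcoxon rank-sum test. The
representativeness analysis asks whether a handful of randomly sampled
measurement days can stand in for a site's long-term average level — the
question that decides whether short-term monitoring designs are adequate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from noisescape.levels import energetic_average

logger = logging.getLogger(__name__)


def quartiles(values) -> tuple[float, float, float]:
    """(q25, median, q75) by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q25), float(med), float(q75)


def stratified_summary(
    df: pd.DataFrame,
    by: list[str],
    metrics: list[str],
) -> pd.DataFrame:
    """Median, quartiles and n of each metric within each stratum.

    NaN metric values are excluded per metric; strata with no valid
    observations for a metric are omitted with a warning. Result is a
    long table with columns ``by + [metric, median, q25, q75, n]``.
    """
    rows = []
    for keys, grp in df.groupby(list(by), observed=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for metric in metrics:
            vals = grp[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                logger.warning("stratum %s: no valid %s values, omitted", keys, metric)
                continue
            q25, med, q75 = quartiles(vals)
            rows.append(
                dict(zip(by, keys))
                | {"metric": metric, "median": med, "q25": q25, "q75": q75, "n": vals.size}
            )
    return pd.DataFrame(rows, columns=[*by, "metric", "median", "q25", "q75", "n"])


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration of the rank-sum distribution when both groups
    have at most 20 observations and there are no ties; otherwise the
    normal approximation with mid-ranks and tie correction (no continuity
    correction, so identical groups give p = 1 exactly).

    Returns
    -------
    (statistic, p_value)
        The Mann-Whitney U statistic of the first sample and the
        two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= 20 and b.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x, y) -> float | None:
    """Pearson product-moment correlation; None if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance input; correlation undefined")
        return None
    return float(stats.pearsonr(x, y).statistic)


def cdf_curves(
    levels: pd.DataFrame,
    grid,
    by: list[str],
) -> pd.DataFrame:
    """Empirical CDFs of LAeq_1min per stratum, evaluated on a dBA grid.

    ``levels`` has a ``laeq_1min`` column plus the stratum columns in
    ``by`` (e.g. an hour grouping and land use). Each output column is a
    monotone non-decreasing step function from 0 to 1; the index is the
    grid.
    """
    grid = np.asarray(grid, dtype=float)
    out = {}
    for keys, grp in levels.groupby(list(by), observed=True):
        vals = np.sort(grp["laeq_1min"].to_numpy(dtype=float))
        if vals.size == 0:
            continue
        key = keys if isinstance(keys, tuple) else (keys,)
        out[key] = np.searchsorted(vals, grid, side="right") / vals.size
    result = pd.DataFrame(out, index=pd.Index(grid, name="dBA"))
    result.columns = pd.MultiIndex.from_tuples(result.columns, names=by)
    return result


@dataclass
class RepresentativenessResult:
    """Short-term-vs-yearlong comparison for fixed sites.

    ``samples`` has one row per sampled site-day with the signed dBA
    difference and percent difference from the site's yearly average;
    ``per_site`` and ``pooled`` carry medians of the signed and absolute
    quantities. Pooled medians are taken over the concatenated per-site
    sample differences. ``|median difference| <= median absolute
    difference`` holds by construction.
    """

    samples: pd.DataFrame
    per_site: pd.DataFrame
    pooled: dict[str, float]
    yearly_average: dict[str, float]


def representativeness(
    daily: pd.DataFrame,
    n_days: int = 5,
    seed: int = 0,
    yearly: str = "energetic",
) -> RepresentativenessResult:
    """How well do a few random days represent a site's yearly level?

    For each site, samples ``n_days`` dates without replacement from its
    valid daily LAeq_24hr values and compares each sampled day with the
    site's yearly average: difference = sampled - yearly (dBA), percent
    difference = 100 * difference / yearly.

    Parameters
    ----------
    daily : DataFrame
        Columns ``site_id, date, laeq_24hr`` — the year of daily levels
        at each fixed site. NaN days are dropped before sampling.
    n_days : int
        Days sampled per site (default 5).
    seed : int
        Seed for the sampling; identical (seed, site list) give identical
        sampled dates and outputs.
    yearly : str
        ``"energetic"`` (default): the yearly average is the energetic
        mean of the daily LAeq_24hr values, consistent with how the daily
        values themselves average minute energies. ``"arithmetic"``:
        plain mean of the dB values.
    """
    if yearly not in ("energetic", "arithmetic"):
        raise ValueError("yearly must be 'energetic' or 'arithmetic'")
    rng = np.random.default_rng(seed)
    rows = []
    yearly_avg: dict[str, float] = {}
    for site_id in sorted(daily["site_id"].unique()):
        grp = daily.loc[daily["site_id"] == site_id].dropna(subset=["laeq_24hr"])
        if len(grp) < n_days:
            raise ValueError(
                f"site {site_id}: only {len(grp)} valid days, need {n_days}"
            )
        grp = grp.sort_values("date")
        avg = (
            energetic_average(grp["laeq_24hr"])
            if yearly == "energetic"
            else float(grp["laeq_24hr"].mean())
        )
        yearly_avg[site_id] = avg
        idx = rng.choice(len(grp), size=n_days, replace=False)
        for i in sorted(idx):
            sampled = float(grp["laeq_24hr"].iloc[i])
            diff = sampled - avg
            rows.append(
                {
                    "site_id": site_id,
                    "date": grp["date"].iloc[i],
                    "sampled_laeq_24hr": sampled,
                    "yearly_laeq_24hr": avg,
                    "difference_dba": diff,
                    "pct_difference": 100.0 * diff / avg,
                }
            )
    samples = pd.DataFrame(rows)

    def _medians(g: pd.DataFrame) -> dict[str, float]:
        return {
            "median_difference_dba": float(g["difference_dba"].median()),
            "median_abs_difference_dba": float(g["difference_dba"].abs().median()),
            "median_pct_difference": float(g["pct_difference"].median()),
            "median_abs_pct_difference": float(g["pct_difference"].abs().median()),
            "n_samples": int(len(g)),
        }

    per_site = pd.DataFrame(
        [{"site_id": sid} | _medians(g) for sid, g in samples.groupby("site_id")]
    )
    pooled = _medians(samples)
    return RepresentativenessResult(
        samples=samples, per_site=per_site, pooled=pooled, yearly_average=yearly_avg
    )


def exceedance_count(levels, threshold_dba: float) -> int:
    """Number of minutes at or above a guideline threshold."""
    return int((np.asarray(levels, dtype=float) >= threshold_dba).sum())
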
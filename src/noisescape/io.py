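"""Tabular readers and writers for level logs, clip predictions and metrics.

All files are comma-separated text with a mandatory header row and
ISO-8601 local timestamps (YYYY-MM-DD HH:MM). Readers never mutate level
values: there is no implicit noise-floor clipping or timezone conversion
anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from noisescape.types import ClipPrediction, MinuteLevelSeries, SiteRecord

logger = logging.getLogger(__name__)

LEVEL_COLUMNS = ("site_id", "timestamp", "laeq_1min")


class DuplicateMinuteError(ValueError):
    """Two rows claim the same (site, minute): a hard error, since silent
    merging would corrupt event detection."""


@dataclass
class ReadReport:
    """Row-level bookkeeping from a reader."""

    n_rows: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    errors: list[str] = field(default_factory=list)

    def add_error(self, msg: str) -> None:
        self.n_rejected += 1
        self.errors.append(msg)
        logger.warning(msg)


def read_level_log(path: str | Path) -> tuple[dict[str, MinuteLevelSeries], ReadReport]:
    """Read a minute-level log into one :class:`MinuteLevelSeries` per site.

    Expects columns ``site_id, timestamp, laeq_1min``. Rows with an
    unparseable timestamp or a non-finite level are rejected and counted
    (with their line number); a duplicated (site, minute) pair raises
    :class:`DuplicateMinuteError` naming the collision. Gaps in the minute
    grid are preserved, never filled.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = set(LEVEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    report = ReadReport(n_rows=len(df))

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    lv = pd.to_numeric(df["laeq_1min"], errors="coerce")
    bad = ts.isna() | ~np.isfinite(lv)
    for i in df.index[bad]:
        # +2: header line plus 1-based numbering
        report.add_error(
            f"{path}: line {i + 2}: unparseable row "
            f"(timestamp={df['timestamp'][i]!r}, laeq_1min={df['laeq_1min'][i]!r})"
        )
    ok = df.loc[~bad].assign(timestamp=ts[~bad], laeq_1min=lv[~bad])

    dup = ok.duplicated(subset=["site_id", "timestamp"], keep=False)
    if dup.any():
        first = ok.loc[dup].iloc[0]
        raise DuplicateMinuteError(
            f"{path}: duplicate minute {first['timestamp']} at site {first['site_id']}"
        )

    series: dict[str, MinuteLevelSeries] = {}
    for site_id, grp in ok.groupby("site_id", sort=True):
        grp = grp.sort_values("timestamp")
        series[str(site_id)] = MinuteLevelSeries(
            site_id=str(site_id),
            timestamps=pd.DatetimeIndex(grp["timestamp"]),
            levels=grp["laeq_1min"].to_numpy(dtype=float),
        )
        n_floor = series[str(site_id)].n_below_floor
        if n_floor:
            logger.info("site %s: %d minutes below the 30 dBA noise floor", site_id, n_floor)
    report.n_valid = int((~bad).sum())
    return series, report


def write_level_log(series_collection, path: str | Path) -> None:
    """Write minute series to CSV in the schema :func:`read_level_log` reads."""
    frames = [s.to_frame() for s in series_collection]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(LEVEL_COLUMNS)
    )
    df = df.sort_values(["site_id", "timestamp"])
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%d %H:%M")
    df.to_csv(path, index=False, float_format="%.6f")


def read_clip_predictions(path: str | Path) -> tuple[list[ClipPrediction], ReadReport]:
    """Read per-clip classifier outputs (top-3 labels with scores).

    Accepts either the wide schema ``site_id, timestamp, label_1..3,
    score_1..3`` or the long schema ``site_id, timestamp, label, rank,
    score`` (rank 1-3). Clips with fewer than 3 distinct labels, or with
    scores not in descending order, are rejected with a reason.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    report = ReadReport(n_rows=len(df))
    if {"label_1", "label_2", "label_3"} <= set(df.columns):
        wide = df
    elif {"label", "rank", "score"} <= set(df.columns):
        wide = (
            df.pivot_table(
                index=["site_id", "timestamp"],
                columns="rank",
                values=["label", "score"],
                aggfunc="first",
            )
        )
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        wide = wide.reset_index()
        report.n_rows = len(wide)
    else:
        raise ValueError(f"{path}: unrecognized clip-prediction schema")

    clips: list[ClipPrediction] = []
    for i, row in wide.iterrows():
        labels = [row.get(f"label_{j}") for j in (1, 2, 3)]
        scores = [row.get(f"score_{j}") for j in (1, 2, 3)]
        where = f"{path}: clip row {i}"
        if any(pd.isna(x) for x in labels):
            report.add_error(f"{where}: fewer than 3 labels")
            continue
        if any(pd.isna(s) for s in scores):
            report.add_error(f"{where}: fewer than 3 scores")
            continue
        try:
            clip = ClipPrediction(
                site_id=str(row["site_id"]),
                timestamp=pd.Timestamp(row["timestamp"]),
                labels=tuple(str(x) for x in labels),
                scores=tuple(float(s) for s in scores),
            )
        except ValueError as exc:
            report.add_error(f"{where}: {exc}")
            continue
        clips.append(clip)
    report.n_valid = len(clips)
    return clips, report


def write_clip_predictions(clips, path: str | Path) -> None:
    """Write clips in the wide schema read by :func:`read_clip_predictions`."""
    rows = [
        {
            "site_id": c.site_id,
            "timestamp": c.timestamp.strftime("%Y-%m-%d %H:%M"),
            "label_1": c.labels[0],
            "label_2": c.labels[1],
            "label_3": c.labels[2],
            "score_1": c.scores[0],
            "score_2": c.scores[1],
            "score_3": c.scores[2],
        }
        for c in clips
    ]
    cols = ["site_id", "timestamp", "label_1", "label_2", "label_3",
            "score_1", "score_2", "score_3"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.4f")


def read_sites(path: str | Path) -> dict[str, SiteRecord]:
    """Read site metadata (id, coordinates, land use, road class, design role)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "latitude", "longitude", "land_use", "road_class", "site_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites = {}
    for _, row in df.iterrows():
        rec = SiteRecord(
            site_id=str(row["site_id"]),
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            land_use=str(row["land_use"]),
            road_class=str(row["road_class"]),
            site_type=str(row["site_type"]),
        )
        sites[rec.site_id] = rec
    return sites


def write_sites(sites, path: str | Path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "land_use": s.land_use,
            "road_class": s.road_class,
            "site_type": s.site_type,
        }
        for s in (sites.values() if isinstance(sites, dict) else sites)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metrics_table(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write a per-site-per-date metrics table to CSV.

    Rows are sorted by (site_id, date) and the column order is stable, so
    repeated writes of the same table are byte-identical. An empty table
    still gets its header, with a warning.
    """
    if len(metrics) == 0:
        warnings.warn("metrics table is empty; writing header only", stacklevel=2)
        metrics.to_csv(path, index=False)
        return
    out = metrics.sort_values(["site_id", "date"]).reset_index(drop=True)
    out.to_csv(path, index=False, float_format="%.9f")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics table written by :func:`write_metrics_table`."""
    df = pd.read_csv(path, dtype={"site_id": str})
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
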
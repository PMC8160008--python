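"""Sound-source post-processing: presence, prevalence, and validation.

A pre-trained audio classifier emits a score per fine-grained sound class
for each 10-s clip; the three highest-scoring classes are retained
("detected"). Fine classes are grouped into seven higher-order categories
adapted from ISO soundscape taxonomy, and a category is *present* in a
clip iff at least one of the three detected classes maps to it — presence
is multi-label, categories are not mutually exclusive.

Prevalence is the percentage of clips, pooled over the sites and times of
a stratum, in which a category is present: a measure of *site-time*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from noisescape.types import ClipPrediction, SOURCE_CATEGORIES

logger = logging.getLogger(__name__)

#: Default fine-label -> category map for common urban sound classes
#: (AudioSet-style ontology). Editable; any label absent from the map
#: resolves to "other".
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    # road transport
    "car": "road-transport", "car-horn": "road-transport", "truck": "road-transport",
    "bus": "road-transport", "motorcycle": "road-transport", "engine": "road-transport",
    "traffic": "road-transport", "vehicle": "road-transport", "tire-squeal": "road-transport",
    "air-brake": "road-transport", "siren": "road-transport", "horn": "road-transport",
    "engine-idling": "road-transport", "accelerating-engine": "road-transport",
    # animals and insects
    "dog": "animals-and-insects", "dog-bark": "animals-and-insects",
    "rooster": "animals-and-insects", "goat": "animals-and-insects",
    "sheep": "animals-and-insects", "bird": "animals-and-insects",
    "bird-song": "animals-and-insects", "crow": "animals-and-insects",
    "cricket": "animals-and-insects", "insect": "animals-and-insects",
    "frog": "animals-and-insects", "cat": "animals-and-insects",
    "chicken": "animals-and-insects", "livestock": "animals-and-insects",
    # outdoor music
    "music": "outdoor-music", "drum": "outdoor-music", "singing": "outdoor-music",
    "loudspeaker-music": "outdoor-music", "church-music": "outdoor-music",
    "percussion": "outdoor-music", "bass-music": "outdoor-music",
    "radio": "outdoor-music",
    # human speech
    "speech": "human-speech", "conversation": "human-speech",
    "shout": "human-speech", "crowd": "human-speech", "laughter": "human-speech",
    "child-speech": "human-speech", "preaching": "human-speech",
    "announcement": "human-speech",
    # aircraft
    "airplane": "aircraft", "aircraft": "aircraft", "jet-engine": "aircraft",
    "helicopter": "aircraft", "aircraft-flyover": "aircraft",
    # nature
    "wind": "nature", "rain": "nature", "thunder": "nature",
    "thunderstorm": "nature", "water": "nature", "waves": "nature",
    "leaves-rustling": "nature",
    # other
    "construction": "other", "hammering": "other", "drilling": "other",
    "generator": "other", "air-conditioner": "other", "footsteps": "other",
    "door": "other", "bell": "other", "static": "other", "silence": "other",
}


class CategoryMap:
    """Total mapping from fine-grained class labels to the seven categories.

    Unknown labels map to ``"other"``; mapped categories must be drawn from
    :data:`noisescape.types.SOURCE_CATEGORIES`.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self.mapping = dict(DEFAULT_CATEGORY_MAP if mapping is None else mapping)
        bad = {c for c in self.mapping.values() if c not in SOURCE_CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories in map: {sorted(bad)}")

    def __getitem__(self, label: str) -> str:
        return self.mapping.get(label, "other")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryMap":
        df = pd.read_csv(path)
        if not {"label", "category"} <= set(df.columns):
            raise ValueError(f"{path}: category map needs 'label' and 'category' columns")
        return cls(dict(zip(df["label"].astype(str), df["category"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["label", "category"]
        ).to_csv(path, index=False)


def top_k_retain(scores: dict[str, float], site_id: str, timestamp, k: int = 3):
    """Retain the k highest-scoring distinct labels, scores descending.

    Score ties are broken by lexicographic label order for determinism.
    For k=3 returns a :class:`ClipPrediction`; other k return the ranked
    (label, score) list.
    """
    if len(scores) < k:
        raise ValueError(f"need at least {k} scored labels, got {len(scores)}")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    if k == 3:
        return ClipPrediction(
            site_id=site_id,
            timestamp=pd.Timestamp(timestamp),
            labels=tuple(lbl for lbl, _ in ranked),
            scores=tuple(s for _, s in ranked),
        )
    return ranked


def to_presence(clip: ClipPrediction, category_map: CategoryMap | None = None) -> dict:
    """Binary per-category presence flags for one clip.

    A category is present iff at least one of the clip's three detected
    labels maps to it; the result is independent of label order. At least
    one category is always present (unmapped labels land in "other").
    """
    category_map = category_map or CategoryMap()
    present = {cat: 0 for cat in SOURCE_CATEGORIES}
    for label in clip.labels:
        present[category_map[label]] = 1
    return {"site_id": clip.site_id, "timestamp": clip.timestamp, **present}


def presence_table(clips, category_map: CategoryMap | None = None) -> pd.DataFrame:
    """Presence flags for a clip collection, one row per clip."""
    category_map = category_map or CategoryMap()
    rows = [to_presence(c, category_map) for c in clips]
    cols = ["site_id", "timestamp", *SOURCE_CATEGORIES]
    df = pd.DataFrame(rows, columns=cols)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def prevalence(
    presence: pd.DataFrame,
    by: list[str] | None = None,
    categories=SOURCE_CATEGORIES,
) -> pd.DataFrame:
    """Percent of clips in which each category is present, per stratum.

    ``by`` names stratum columns of ``presence`` (e.g. ``["land_use"]``,
    ``["hour"]``); with ``by=None`` all clips pool into one row. Each row
    carries ``n_clips``, the stratum denominator — pooling is
    clip-weighted, so the prevalence of a union of strata is the
    clip-count-weighted mean of the stratum prevalences. Category columns
    need not sum to 100: presence is multi-label.
    """
    if len(presence) == 0:
        raise ValueError("no presence records")
    categories = [c for c in categories if c in presence.columns]
    if by:
        grouped = presence.groupby(list(by), observed=True)
        out = grouped[categories].mean().mul(100.0)
        out["n_clips"] = grouped.size()
        out = out.reset_index()
    else:
        out = presence[categories].mean().mul(100.0).to_frame().T
        out["n_clips"] = len(presence)
    out["n_clips"] = out["n_clips"].astype(int)
    return out


def diurnal_prevalence(
    presence: pd.DataFrame,
    by_land_use: bool = True,
) -> pd.DataFrame:
    """Prevalence per hour of day (0-23), optionally by land use.

    ``presence`` needs a ``land_use`` column when ``by_land_use`` is set
    (join site metadata first). Hours with no clips are absent from the
    output.
    """
    df = presence.copy()
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.hour
    by = ["hour", "land_use"] if by_land_use else ["hour"]
    return prevalence(df, by=by)


def prevalence_by_level(
    presence: pd.DataFrame,
    levels: pd.DataFrame,
    bin_edges,
    by_land_use: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Prevalence per 5-dB sound-level bin (and land use).

    Each clip is joined to the LAeq_1min of its enclosing minute — the
    10-s clip is taken as representative of the acoustic environment over
    that minute. Bins are half-open ``(lo, hi]`` with open-ended extremes,
    labelled like ``"51-55"``. Clips with no matching minute level are
    dropped; the drop count is returned alongside the table.

    ``levels`` has columns ``site_id, timestamp, laeq_1min``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    lv = levels[["site_id", "timestamp", "laeq_1min"]].copy()
    lv["timestamp"] = pd.to_datetime(lv["timestamp"])
    df = presence.merge(lv, on=["site_id", "timestamp"], how="left")
    n_dropped = int(df["laeq_1min"].isna().sum())
    df = df.dropna(subset=["laeq_1min"])
    if len(df) == 0:
        raise ValueError("no overlap between clip timestamps and level minutes")
    full_edges = np.concatenate(([-np.inf], edges, [np.inf]))
    labels = (
        [f"<={edges[0]:.0f}"]
        + [f"{edges[i] + 1:.0f}-{edges[i + 1]:.0f}" for i in range(len(edges) - 1)]
        + [f">{edges[-1]:.0f}"]
    )
    df["level_bin"] = pd.cut(df["laeq_1min"], bins=full_edges, labels=labels, right=True)
    by = ["level_bin", "land_use"] if by_land_use and "land_use" in df.columns else ["level_bin"]
    return prevalence(df, by=by), n_dropped


_EARTH_RADIUS_M = 6371008.8


def _to_unit_vectors(lat, lon):
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in metres between two (lat, lon) points."""
    p1, p2 = _to_unit_vectors(lat1, lon1), _to_unit_vectors(lat2, lon2)
    d = np.clip((p1 * p2).sum(axis=-1), -1.0, 1.0)
    return float(_EARTH_RADIUS_M * np.arccos(d))


def _point_segment_distance_m(p_lat, p_lon, a_lat, a_lon, b_lat, b_lon) -> float:
    """Great-circle distance from a point to a great-circle arc segment.

    Uses the cross-track construction on the unit sphere: if the point's
    projection onto the great circle through A and B falls within the arc,
    the distance is the cross-track distance; otherwise the nearer
    endpoint distance.
    """
    p = _to_unit_vectors(p_lat, p_lon)
    a = _to_unit_vectors(a_lat, a_lon)
    b = _to_unit_vectors(b_lat, b_lon)
    n = np.cross(a, b)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:  # degenerate: coincident or antipodal endpoints
        return haversine_m(p_lat, p_lon, a_lat, a_lon)
    n = n / n_norm
    # projection of p onto the great-circle plane
    proj = p - np.dot(p, n) * n
    proj = proj / np.linalg.norm(proj)
    # within-arc test: projection lies between a and b along the arc
    ab = np.arccos(np.clip(np.dot(a, b), -1, 1))
    if (
        np.arccos(np.clip(np.dot(a, proj), -1, 1)) <= ab
        and np.arccos(np.clip(np.dot(b, proj), -1, 1)) <= ab
    ):
        return float(_EARTH_RADIUS_M * np.arcsin(np.clip(abs(np.dot(p, n)), 0, 1)))
    return min(
        haversine_m(p_lat, p_lon, a_lat, a_lon), haversine_m(p_lat, p_lon, b_lat, b_lon)
    )


def flight_path_strata(
    sites,
    path: list[tuple[float, float]],
    buffer_m: float = 1000.0,
) -> dict[str, bool]:
    """Flag each site as within ``buffer_m`` of the flight-path polyline.

    ``path`` is a list of >=2 (lat, lon) vertices approximating the
    landing/take-off trajectory; a site is *within* iff its great-circle
    distance to the nearest point on any segment is at most the buffer
    (default 1 km). Aircraft prevalence is then reported separately for
    the two strata.
    """
    if len(path) < 2:
        raise ValueError("flight path polyline needs at least 2 vertices")
    records = sites.values() if isinstance(sites, dict) else sites
    out = {}
    for s in records:
        d = min(
            _point_segment_distance_m(
                s.latitude, s.longitude, path[i][0], path[i][1], path[i + 1][0], path[i + 1][1]
            )
            for i in range(len(path) - 1)
        )
        out[s.site_id] = d <= buffer_m
    return out


@dataclass
class ValidationCounts:
    """Per-category confusion counts against blinded manual labels.

    ``tp[c]`` and ``fp[c]`` are the true- and false-positive clip counts
    for category c; false/true negatives are optional (the manual
    validation protocol may or may not label absences).
    """

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int] = field(default_factory=dict)
    tn: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.tp, self.fp, self.fn, self.tn):
            for cat, v in d.items():
                if not (isinstance(v, (int, np.integer)) and v >= 0):
                    raise ValueError(f"count for {cat} must be a non-negative integer, got {v}")


def ppv(counts: ValidationCounts) -> dict[str, float | None]:
    """Positive predictive value per category, in percent.

    PPV = 100 * TP / (TP + FP): the fraction of predicted presences
    confirmed by the manual labels. Categories never predicted
    (TP + FP = 0) are undefined and reported as None.
    """
    out: dict[str, float | None] = {}
    for cat in sorted(set(counts.tp) | set(counts.fp)):
        tp = counts.tp.get(cat, 0)
        fp = counts.fp.get(cat, 0)
        if tp + fp == 0:
            logger.warning("PPV undefined for %s (no predicted presences)", cat)
            out[cat] = None
        else:
            out[cat] = 100.0 * tp / (tp + fp)
    return out
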
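"""Figure generators for the standard report views.

Thin matplotlib wrappers over the summary tables: per-stratum level CDFs,
diurnal prevalence curves, and prevalence against concurrent sound-level
bins. Each returns the Figure for further styling or saving.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

from noisescape.types import SOURCE_CATEGORIES


def plot_cdf_curves(cdfs: pd.DataFrame, title: str = "1-min level CDFs"):
    """Plot the output of :func:`noisescape.summaries.cdf_curves`."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in cdfs.columns:
        label = " / ".join(str(c) for c in (col if isinstance(col, tuple) else (col,)))
        ax.plot(cdfs.index, cdfs[col], label=label, lw=1.2)
    ax.set_xlabel("LAeq$_{1min}$ (dBA)")
    ax.set_ylabel("Cumulative proportion")
    ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return fig


def plot_diurnal_prevalence(
    table: pd.DataFrame,
    categories=("road-transport", "animals-and-insects", "human-speech", "outdoor-music"),
):
    """Hour-of-day prevalence curves per category; input from
    :func:`noisescape.sources.diurnal_prevalence` (without land-use split,
    or pre-filtered to one land use)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cat in categories:
        if cat in table.columns:
            ax.plot(table["hour"], table[cat], marker="o", ms=3, label=cat)
    ax.set_xlabel("Hour of day")
    ax.set_ylabel("% site-time present")
    ax.set_xticks(range(0, 24, 3))
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_prevalence_by_level(table: pd.DataFrame, categories=SOURCE_CATEGORIES):
    """Prevalence per 5-dB bin; input from
    :func:`noisescape.sources.prevalence_by_level` (without land-use split)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = range(len(table))
    for cat in categories:
        if cat in table.columns:
            ax.plot(x, table[cat], marker="s", ms=3, label=cat)
    ax.set_xticks(list(x))
    ax.set_xticklabels(table["level_bin"], rotation=45, ha="right", fontsize=7)
    ax.set_xlabel("LAeq$_{1min}$ bin (dBA)")
    ax.set_ylabel("% site-time present")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
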
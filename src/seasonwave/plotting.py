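"""Basic figures for the seasonality study.

Three study-shaped plots: the overlay of reconstructed seasonal components
(change in relative search volume over time), the raw series of terms with
no significant seasonality, and per-year winter peak timing. All functions
return the matplotlib Figure so callers can restyle or save as needed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default; no-op if set
import matplotlib.pyplot as plt
import pandas as pd


def plot_components(
    components: Mapping[str, tuple[Sequence, Sequence[float]]],
) -> plt.Figure:
    """Overlay of band-reconstructed seasonal components.

    ``components`` maps term -> (week dates, component values).
    """
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for term, (weeks, values) in components.items():
        ax.plot(pd.to_datetime(list(weeks)), values, label=term, lw=1.2)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("week")
    ax.set_ylabel("change in relative search volume")
    ax.set_title("Seasonal (52-week band) components")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    return fig


def plot_raw_series(
    series: Mapping[str, tuple[Sequence, Sequence[float]]],
) -> plt.Figure:
    """Raw relative search volume for terms without seasonal structure."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for term, (weeks, values) in series.items():
        ax.plot(pd.to_datetime(list(weeks)), values, label=term, lw=1.0)
    ax.set_xlabel("week")
    ax.set_ylabel("relative search volume")
    ax.set_title("Non-seasonal search terms (raw data)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_peak_timing(
    peak_weeks: Mapping[str, Mapping[str, int]],
) -> plt.Figure:
    """Winter-peak week (offset within the analysis year) per year and term.

    ``peak_weeks`` maps term -> {year label -> peak week-in-window}.
    """
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for term, by_year in peak_weeks.items():
        years = list(by_year)
        ax.plot(years, [by_year[y] for y in years], marker="o", label=term)
    ax.set_xlabel("analysis year")
    ax.set_ylabel("peak week within year window")
    ax.set_title("Peak search volume timing by year")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    return fig
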
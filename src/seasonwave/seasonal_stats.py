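"""Winter-summer amplitude statistics and between-term comparisons.

The magnitude of seasonality is summarized per analysis year as the percent
change from the summer trough to the winter peak of the raw normalized
series: ``(winter peak - summer trough) / summer trough * 100``. Per-term
summaries report the mean over years, the sample SD, and a
normal-approximation 95% CI (``mean +/- 1.96 * SD / sqrt(n)``).

Between-term differences in mean percent change are tested with a classical
fixed-effects one-way ANOVA (computable from raw values or from per-group
(mean, SD, n) sufficient statistics) followed by Tukey HSD post-hoc
comparisons based on the studentized range distribution; effect size is
partial eta squared, SS_between / (SS_between + SS_within).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSeriesError
from .series import WeeklySeries

__all__ = [
    "SeasonalChangeSummary",
    "AnovaResult",
    "PairwiseComparison",
    "season_windows_for",
    "percent_change_year",
    "summarize_changes",
    "one_way_anova",
    "anova_from_summary",
    "tukey_hsd",
]

#: Normal-approximation multiplier for the 95% CI.
Z_95 = 1.96


@dataclass(frozen=True)
class SeasonalChangeSummary:
    """Per-term winter-summer percent-change summary over analysis years."""

    term: str
    per_year_pct: tuple[float, ...]
    mean_pct: float
    sd_pct: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "per_year_pct": list(self.per_year_pct),
            "mean_pct": self.mean_pct,
            "sd_pct": self.sd_pct,
            "ci95_lower": self.ci95[0],
            "ci95_upper": self.ci95[1],
        }


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects one-way ANOVA with partial eta squared."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    partial_eta_sq: float
    ss_between: float
    ss_within: float

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "partial_eta_sq": self.partial_eta_sq,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
        }


@dataclass(frozen=True)
class PairwiseComparison:
    """One Tukey HSD comparison; ``mean_difference`` is A minus B."""

    pair: tuple[str, str]
    mean_difference: float
    p_adjusted: float

    def to_dict(self) -> dict:
        return {
            "first": self.pair[0],
            "second": self.pair[1],
            "mean_difference": self.mean_difference,
            "p_adjusted": self.p_adjusted,
        }


def season_windows_for(
    year_window: tuple[pd.Timestamp, pd.Timestamp],
    winter_start_month: int = 10,
    summer_start_month: int = 4,
) -> tuple[tuple[pd.Timestamp, pd.Timestamp], tuple[pd.Timestamp, pd.Timestamp]]:
    """Default winter and summer intervals inside one analysis-year window.

    For a window starting in the second half of a calendar year (the study
    design anchors years in August), winter is October 1 of the start year
    through March 31, and summer is April 1 through the window end. Both
    intervals are half-open ``[start, end)`` and disjoint by construction.
    """
    w_start, w_end = pd.Timestamp(year_window[0]), pd.Timestamp(year_window[1])
    if w_start.month >= summer_start_month:
        # window starts Apr..Dec: its winter straddles the new year
        winter_start = pd.Timestamp(w_start.year, winter_start_month, 1)
        summer_start = pd.Timestamp(w_start.year + 1, summer_start_month, 1)
    else:
        # window starts Jan..Mar: it opens mid-winter
        winter_start = w_start
        summer_start = pd.Timestamp(w_start.year, summer_start_month, 1)
    winter_start = max(winter_start, w_start)
    return (winter_start, summer_start), (summer_start, w_end)


def _window_values(
    series: WeeklySeries, window: tuple[pd.Timestamp, pd.Timestamp]
) -> np.ndarray:
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    mask = (series.weeks >= start) & (series.weeks < end)
    if not mask.any():
        raise ValueError(
            f"{series.term!r}: window {start.date()}..{end.date()} contains no weeks"
        )
    return series.values[mask]


def percent_change_year(
    series: WeeklySeries,
    year_window: tuple[pd.Timestamp, pd.Timestamp],
    winter_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    summer_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> float:
    """Winter-summer percent change for one analysis year.

    ``(winter peak - summer trough) / summer trough * 100`` where the
    winter peak is the maximum raw series value inside ``winter_window``
    and the summer trough the minimum inside ``summer_window``; i.e. the
    percentage by which the winter peak exceeds the lowest summer point.
    When the seasonal windows are omitted they default to
    :func:`season_windows_for` of ``year_window``.

    Raises
    ------
    DegenerateSeriesError
        If the summer trough is zero.
    ValueError
        If the seasonal windows overlap or fall outside the series.
    """
    if winter_window is None or summer_window is None:
        default_winter, default_summer = season_windows_for(year_window)
        winter_window = winter_window or default_winter
        summer_window = summer_window or default_summer
    w0, w1 = pd.Timestamp(winter_window[0]), pd.Timestamp(winter_window[1])
    s0, s1 = pd.Timestamp(summer_window[0]), pd.Timestamp(summer_window[1])
    if max(w0, s0) < min(w1, s1):
        raise ValueError("winter and summer windows must be disjoint")
    winter_peak = float(_window_values(series, (w0, w1)).max())
    summer_trough = float(_window_values(series, (s0, s1)).min())
    if summer_trough == 0:
        raise DegenerateSeriesError(
            f"{series.term!r}: summer trough is zero; percent change undefined"
        )
    return (winter_peak - summer_trough) / summer_trough * 100.0


def summarize_changes(
    per_year: Sequence[float], term: str = ""
) -> SeasonalChangeSummary:
    """Mean, sample SD and normal-approximation 95% CI of yearly changes.

    The CI is ``mean +/- 1.96 * SD / sqrt(n)`` with ``n`` the number of
    years and SD the sample standard deviation (n-1 denominator).

    Raises ``ValueError`` for fewer than two years.
    """
    vals = np.asarray(per_year, dtype=float)
    if len(vals) < 2:
        raise ValueError(f"need at least 2 yearly values, got {len(vals)}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = Z_95 * sd / np.sqrt(len(vals))
    return SeasonalChangeSummary(
        term=term,
        per_year_pct=tuple(float(v) for v in vals),
        mean_pct=mean,
        sd_pct=sd,
        ci95=(mean - half, mean + half),
    )


def _check_groups(groups: Mapping[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")


def _anova_from_ss(
    ss_between: float, ss_within: float, df_between: int, df_within: int
) -> AnovaResult:
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ms_between == 0 else np.inf
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    total = ss_between + ss_within
    eta = ss_between / total if total > 0 else 0.0
    return AnovaResult(
        f_stat=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        partial_eta_sq=float(eta),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
    )


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA from raw observations.

    Reports F, degrees of freedom (k-1, N-k), the p-value from the F
    distribution, and partial eta squared. Agrees with
    :func:`anova_from_summary` on the groups' sufficient statistics to
    floating-point accuracy.
    """
    _check_groups(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    return _anova_from_ss(
        ss_between, ss_within, len(arrays) - 1, len(all_vals) - len(arrays)
    )


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int] | int
) -> AnovaResult:
    """One-way ANOVA from per-group (mean, sample SD, n) summaries.

    Lets published summary tables be re-analyzed without the raw data:
    ``SS_between = sum n_i (m_i - grand)^2`` (grand = weighted mean) and
    ``SS_within = sum (n_i - 1) s_i^2``.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.isscalar(ns):
        ns = np.full(len(means), int(ns))
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds and ns must have equal length")
    if len(means) < 2 or (ns < 2).any():
        raise ValueError("need >= 2 groups with n >= 2 each")
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    return _anova_from_ss(
        ss_between, ss_within, len(means) - 1, int(ns.sum() - len(means))
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD comparisons after a one-way ANOVA.

    For each of the k(k-1)/2 pairs the studentized-range statistic is
    ``|m_A - m_B| / sqrt(MS_within/2 * (1/n_A + 1/n_B))`` (Tukey-Kramer
    form, exact for balanced groups) and the adjusted p-value its upper
    tail under the studentized range distribution with (k, df_within).
    ``mean_difference`` is oriented A minus B in the pair's label order,
    which follows the mapping's iteration order.
    """
    _check_groups(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    k = len(arrays)
    df_within = sum(len(v) - 1 for v in arrays.values())
    ms_within = (
        sum(((v - v.mean()) ** 2).sum() for v in arrays.values()) / df_within
    )
    out: list[PairwiseComparison] = []
    for name_a, name_b in combinations(arrays, 2):
        va, vb = arrays[name_a], arrays[name_b]
        diff = float(va.mean() - vb.mean())
        if ms_within == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(ms_within / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within))
        out.append(
            PairwiseComparison(
                pair=(name_a, name_b),
                mean_difference=diff,
                p_adjusted=min(1.0, p_adj),
            )
        )
    return out
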
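"""Model/Results interface over the seasonality pipeline.

Two levels mirror the layout of mature statistical packages:

* :class:`TermSeasonality` — one term's weekly series. ``fit()`` runs the
  wavelet transform, the 52-week surrogate significance test and, when the
  component is significant, band reconstruction, annual peak detection,
  year-over-year phase shifts and winter-summer percent changes, returning
  a :class:`TermSeasonalityResults`.
* :class:`SeasonalityStudy` — a panel of terms. ``fit()`` fits every term,
  applies the significance gate (non-significant terms are excluded from
  all downstream stages), then computes the between-term phase table, the
  percent-change ANOVA and Tukey HSD comparisons, returning a
  :class:`SeasonalityStudyResults` whose ``summary()`` prints the study
  tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .errors import ConfigError
from .phase import (
    PeakCalendar,
    PhaseComparison,
    annual_peaks,
    phase_angle_between,
    study_year_windows,
    yearly_phase_shift,
)
from .seasonal_stats import (
    AnovaResult,
    PairwiseComparison,
    SeasonalChangeSummary,
    anova_from_summary,  # noqa: F401  (re-exported convenience)
    one_way_anova,
    percent_change_year,
    summarize_changes,
    tukey_hsd,
)
from .series import WeeklySeries
from .wavelet import (
    SeasonalComponent,
    SignificanceResult,
    WaveletConfig,
    WaveletSpectrum,
    cwt_morlet,
    reconstruct_band,
    test_periodicity,
)

__all__ = [
    "TermSeasonality",
    "TermSeasonalityResults",
    "SeasonalityStudy",
    "SeasonalityStudyResults",
]

#: Default reconstruction band around the annual cycle, in weeks.
DEFAULT_BAND = (40.0, 68.0)


class TermSeasonality:
    """Seasonality model for a single term's weekly series.

    Parameters
    ----------
    series
        The (normalized) weekly series.
    config
        Wavelet and surrogate-test configuration; ``config.seed`` must be
        set before calling :meth:`fit`.
    target_period
        Period of interest in weeks (default 52, the annual cycle).
    band
        Period band (weeks) for reconstructing the seasonal component.
    """

    def __init__(
        self,
        series: WeeklySeries,
        config: WaveletConfig = WaveletConfig(),
        target_period: float = 52.0,
        band: tuple[float, float] = DEFAULT_BAND,
    ) -> None:
        self.series = series
        self.config = config
        self.target_period = float(target_period)
        self.band = (float(band[0]), float(band[1]))

    @classmethod
    def from_csv(cls, path, config: WaveletConfig = WaveletConfig(), **kwargs):
        """Build the model straight from a search-interest CSV export."""
        read_kw = {
            k: kwargs.pop(k)
            for k in ("dialect", "term", "min_length")
            if k in kwargs
        }
        return cls(_io.read_trends_csv(path, **read_kw), config=config, **kwargs)

    def fit(
        self,
        year_windows: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
        year_labels: list[str] | None = None,
    ) -> "TermSeasonalityResults":
        """Run the per-term pipeline and return its results.

        ``year_windows`` default to consecutive 52-week windows anchored at
        the series start. If the periodicity test is not significant at
        alpha = .05, no component, peaks or percent changes are computed
        (the corresponding result fields are ``None``).
        """
        if self.config.seed is None:
            raise ConfigError(
                f"{self.series.term!r}: config.seed must be set before fit()"
            )
        series = self.series
        if year_windows is None:
            year_windows = study_year_windows(series.weeks[0], series.n_years)
        if year_labels is None:
            year_labels = [f"year {i + 1}" for i in range(len(year_windows))]

        spectrum = cwt_morlet(series, self.config)
        significance = test_periodicity(series, self.target_period, self.config)

        component = peaks = shifts = change_summary = None
        if significance.significant:
            component = reconstruct_band(spectrum, self.band)
            peaks = annual_peaks(component, year_windows, year_labels)
            shifts = yearly_phase_shift(peaks, year_labels[0], self.target_period)
            per_year = [
                percent_change_year(series, window) for window in year_windows
            ]
            change_summary = summarize_changes(per_year, term=series.term)

        return TermSeasonalityResults(
            model=self,
            spectrum=spectrum,
            significance=significance,
            component=component,
            peak_calendar=peaks,
            yearly_shifts=shifts,
            change_summary=change_summary,
            year_windows=list(year_windows),
            year_labels=list(year_labels),
        )


@dataclass
class TermSeasonalityResults:
    """Fitted per-term results; downstream fields are None when the
    52-week component is not significant."""

    model: TermSeasonality
    spectrum: WaveletSpectrum
    significance: SignificanceResult
    component: SeasonalComponent | None
    peak_calendar: PeakCalendar | None
    yearly_shifts: list[PhaseComparison] | None
    change_summary: SeasonalChangeSummary | None
    year_windows: list[tuple[pd.Timestamp, pd.Timestamp]] = field(repr=False, default_factory=list)
    year_labels: list[str] = field(default_factory=list)

    @property
    def term(self) -> str:
        return self.model.series.term

    @property
    def significant(self) -> bool:
        return self.significance.significant

    def summary(self) -> str:
        s = self.significance
        lines = [
            f"Seasonality analysis: {self.term}",
            "=" * 40,
            f"target period        {s.target_period:g} weeks "
            f"(grid period {s.period_used:.2f})",
            f"time-avg power       {s.observed_stat:.4f}",
            f"surrogate p-value    {s.p_value:.4g}  "
            f"({s.n_surrogates} surrogates, seed {s.seed})",
            f"significant (.05)    {s.significant}",
        ]
        if not self.significant:
            lines.append("no significant seasonal component; analysis stops here")
            return "\n".join(lines)
        cs = self.change_summary
        lines += [
            f"winter-summer change {cs.mean_pct:.1f}% "
            f"(SD {cs.sd_pct:.1f}%; 95% CI {cs.ci95[0]:.1f}%-{cs.ci95[1]:.1f}%)",
            "annual peaks:",
        ]
        for peak in self.peak_calendar.peaks:
            lines.append(
                f"  {peak.year_label}: {peak.label} ({peak.date.date()})"
            )
        lines.append("year-over-year shift vs year 1:")
        for cmp_ in self.yearly_shifts:
            lines.append(
                f"  {cmp_.pair[1]}: {cmp_.angle_degrees:+.1f} deg "
                f"({cmp_.weeks_equivalent:+.1f} weeks)"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out: dict = {
            "term": self.term,
            "significance": self.significance.to_dict(),
            "year_labels": self.year_labels,
        }
        if self.significant:
            out["component"] = [float(v) for v in self.component.values]
            out["peaks"] = [
                {
                    "year": p.year_label,
                    "date": p.date.date().isoformat(),
                    "label": p.label,
                    "week_in_window": p.week_in_window,
                    "value": p.value,
                }
                for p in self.peak_calendar.peaks
            ]
            out["yearly_shifts"] = [c.to_dict() for c in self.yearly_shifts]
            out["percent_change"] = self.change_summary.to_dict()
        return out


class SeasonalityStudy:
    """Study-level model over a panel of weekly series.

    Parameters
    ----------
    panel
        Mapping term -> series (iteration order fixes table ordering).
    config
        Shared wavelet configuration. Per-term surrogate seeds are derived
        deterministically from ``seed`` (one independent stream per term).
    seed
        Global seed governing every stochastic stage.
    """

    def __init__(
        self,
        panel: Mapping[str, WeeklySeries],
        config: WaveletConfig = WaveletConfig(),
        target_period: float = 52.0,
        band: tuple[float, float] = DEFAULT_BAND,
        seed: int = 0,
    ) -> None:
        self.panel = dict(panel)
        self.config = config
        self.target_period = float(target_period)
        self.band = band
        self.seed = int(seed)

    @classmethod
    def from_csvs(cls, paths, config: WaveletConfig = WaveletConfig(), **kwargs):
        panel = {}
        for path in paths:
            series = _io.read_trends_csv(path)
            panel[series.term] = series
        return cls(panel, config=config, **kwargs)

    def _term_seed(self, index: int) -> int:
        state = np.random.SeedSequence([self.seed, index]).generate_state(1)[0]
        return int(state % (2**31))

    def fit(self) -> "SeasonalityStudyResults":
        """Fit every term, gate on significance, and run cross-term stages."""
        term_results: dict[str, TermSeasonalityResults] = {}
        for i, (term, series) in enumerate(self.panel.items()):
            model = TermSeasonality(
                series,
                config=self.config.with_seed(self._term_seed(i)),
                target_period=self.target_period,
                band=self.band,
            )
            term_results[term] = model.fit()

        significant = [t for t, r in term_results.items() if r.significant]
        excluded = [t for t, r in term_results.items() if not r.significant]

        phase_pairs: list[dict] = []
        anova = None
        tukey: list[PairwiseComparison] = []
        if len(significant) >= 2:
            groups = {
                t: list(term_results[t].change_summary.per_year_pct)
                for t in significant
            }
            anova = one_way_anova(groups)
            tukey = tukey_hsd(groups)
            tukey_by_pair = {c.pair: c for c in tukey}
            from itertools import combinations

            for term_a, term_b in combinations(significant, 2):
                cmp_ = phase_angle_between(
                    term_results[term_a].peak_calendar,
                    term_results[term_b].peak_calendar,
                    self.target_period,
                )
                hsd = tukey_by_pair[(term_a, term_b)]
                phase_pairs.append(
                    {
                        "first": term_a,
                        "second": term_b,
                        "mean_difference_pct": hsd.mean_difference,
                        "p_adjusted": hsd.p_adjusted,
                        "angle_degrees": cmp_.angle_degrees,
                        "weeks_equivalent": cmp_.weeks_equivalent,
                    }
                )

        return SeasonalityStudyResults(
            model=self,
            term_results=term_results,
            significant_terms=significant,
            excluded_terms=excluded,
            phase_pairs=phase_pairs,
            anova=anova,
            tukey=tukey,
        )


@dataclass
class SeasonalityStudyResults:
    """Fitted study results: per-term fits plus the cross-term tables."""

    model: SeasonalityStudy
    term_results: dict[str, TermSeasonalityResults]
    significant_terms: list[str]
    excluded_terms: list[str]
    phase_pairs: list[dict]
    anova: AnovaResult | None
    tukey: list[PairwiseComparison]

    def phase_table(self) -> pd.DataFrame:
        """Between-term comparison table (percent-change difference with
        Tukey-adjusted p, phase angle and its week equivalent)."""
        return pd.DataFrame(
            self.phase_pairs,
            columns=[
                "first",
                "second",
                "mean_difference_pct",
                "p_adjusted",
                "angle_degrees",
                "weeks_equivalent",
            ],
        )

    def shift_table(self) -> pd.DataFrame:
        """Within-term year-over-year phase shifts vs year 1."""
        rows = []
        for term in self.significant_terms:
            res = self.term_results[term]
            row: dict = {
                "term": term,
                "peak_year_1": res.peak_calendar.peaks[0].label,
            }
            for cmp_ in res.yearly_shifts:
                row[f"{cmp_.pair[1]} angle"] = cmp_.angle_degrees
                row[f"{cmp_.pair[1]} weeks"] = cmp_.weeks_equivalent
            rows.append(row)
        return pd.DataFrame(rows)

    def changes_table(self) -> pd.DataFrame:
        """Per-term winter-summer percent-change summaries."""
        rows = []
        for term in self.significant_terms:
            cs = self.term_results[term].change_summary
            rows.append(
                {
                    "term": term,
                    "mean_pct": cs.mean_pct,
                    "sd_pct": cs.sd_pct,
                    "ci95_lower": cs.ci95[0],
                    "ci95_upper": cs.ci95[1],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Seasonality study summary",
            "=" * 60,
            f"terms analyzed        {len(self.term_results)}",
            f"significant (52-week) {len(self.significant_terms)}: "
            + ", ".join(self.significant_terms),
            f"excluded              {len(self.excluded_terms)}: "
            + ", ".join(self.excluded_terms),
            "",
        ]
        for term, res in self.term_results.items():
            s = res.significance
            mark = "*" if s.significant else " "
            lines.append(
                f"  {mark} {term:<15} p = {s.p_value:.4g}"
            )
        if self.anova is not None:
            a = self.anova
            lines += [
                "",
                "winter-summer percent change (significant terms):",
                self.changes_table().round(1).to_string(index=False),
                "",
                f"one-way ANOVA: F({a.df_between},{a.df_within}) = "
                f"{a.f_stat:.2f}, p = {a.p_value:.3g}, "
                f"partial eta sq = {a.partial_eta_sq:.3f}",
                "",
                "between-term comparisons (Tukey HSD and phase angles):",
                self.phase_table().round(
                    {
                        "mean_difference_pct": 1,
                        "p_adjusted": 3,
                        "angle_degrees": 1,
                        "weeks_equivalent": 1,
                    }
                ).to_string(index=False),
            ]
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Machine-readable report with every computed number."""
        report: dict = {
            "seed": self.model.seed,
            "target_period": self.model.target_period,
            "band": list(self.model.band),
            "config": {
                "omega0": self.model.config.omega0,
                "min_period": self.model.config.min_period,
                "max_period": self.model.config.max_period,
                "voices_per_octave": self.model.config.voices_per_octave,
                "n_surrogates": self.model.config.n_surrogates,
                "detrend": self.model.config.detrend,
                "coi_policy": self.model.config.coi_policy,
            },
            "terms": {t: r.to_dict() for t, r in self.term_results.items()},
            "series": {
                t: {
                    "weeks": [w.date().isoformat() for w in s.weeks],
                    "values": [float(v) for v in s.values],
                }
                for t, s in self.model.panel.items()
            },
            "significant_terms": self.significant_terms,
            "excluded_terms": self.excluded_terms,
        }
        if self.anova is not None:
            report["phase_table"] = self.phase_pairs
            report["anova"] = self.anova.to_dict()
            report["tukey"] = [c.to_dict() for c in self.tukey]
        return report
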
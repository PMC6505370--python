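"""Peak timing and phase-angle arithmetic for seasonal components.

Seasonal timing is defined peak-to-peak: within each 52-week analysis year
the week of maximum reconstructed seasonal signal is the annual peak, and
timing differences between two series (or between years of one series) are
expressed as phase angles on the annual cycle — a shift of one full period
is 360 degrees, so a difference of ``d`` weeks maps to ``d / 52 * 360``
degrees, wrapped to (-180, 180]. Positive angles mean the second label
peaks *later* in the year than the first. Angles convert back to weeks as
``angle / 360 * period``.

Per-year angles are aggregated with the circular mean (mean resultant
direction); arithmetic averaging of wrapped angles is biased near +/-180.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError
from .wavelet import SeasonalComponent

__all__ = [
    "AnnualPeak",
    "PeakCalendar",
    "PhaseComparison",
    "wrap_angle",
    "degrees_to_weeks",
    "weeks_to_degrees",
    "circular_mean_degrees",
    "study_year_windows",
    "annual_peaks",
    "phase_angle_between",
    "yearly_phase_shift",
    "month_week_label",
]


def wrap_angle(angle_degrees: float) -> float:
    """Wrap an angle to the interval (-180, 180].

    The +180 endpoint is kept (convention: exactly half a period out of
    phase is reported as +180, not -180).
    """
    w = float(angle_degrees) % 360.0
    if w > 180.0:
        w -= 360.0
    return w


def degrees_to_weeks(angle_degrees: float, period: float = 52.0) -> float:
    """Convert a phase angle to its signed week equivalent.

    ``angle / 360 * period``, exact; rounding for display is left to the
    presentation layer.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    return angle_degrees / 360.0 * period


def weeks_to_degrees(weeks: float, period: float = 52.0) -> float:
    """Inverse of :func:`degrees_to_weeks` (no wrapping applied)."""
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    return weeks / period * 360.0


def circular_mean_degrees(angles_degrees: np.ndarray) -> float:
    """Mean resultant direction of angles in degrees, wrapped to (-180, 180]."""
    rad = np.deg2rad(np.asarray(angles_degrees, dtype=float))
    mean = np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
    return wrap_angle(np.rad2deg(mean))


def month_week_label(date: pd.Timestamp) -> str:
    """Human-readable peak label: month name plus week-of-month ordinal.

    Days 1-7 are week 1, days 8-14 week 2, and so on; e.g. 2013-01-20 ->
    ``"January, week 3"``.
    """
    date = pd.Timestamp(date)
    return f"{calendar.month_name[date.month]}, week {(date.day - 1) // 7 + 1}"


@dataclass(frozen=True)
class AnnualPeak:
    """Peak of the seasonal component within one analysis-year window."""

    year_label: str
    date: pd.Timestamp
    week_in_window: int  # 0-based week offset from the window start
    value: float

    @property
    def label(self) -> str:
        return month_week_label(self.date)


@dataclass
class PeakCalendar:
    """One peak per analysis year for a single term."""

    term: str
    peaks: list[AnnualPeak]

    @property
    def year_labels(self) -> list[str]:
        return [p.year_label for p in self.peaks]

    def peak(self, year_label: str) -> AnnualPeak:
        for p in self.peaks:
            if p.year_label == year_label:
                return p
        raise KeyError(f"{self.term!r}: no year {year_label!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term,
                "year": self.year_labels,
                "peak_date": [p.date for p in self.peaks],
                "peak_label": [p.label for p in self.peaks],
                "week_in_window": [p.week_in_window for p in self.peaks],
                "value": [p.value for p in self.peaks],
            }
        )


@dataclass
class PhaseComparison:
    """Peak-to-peak phase-angle difference between two labels.

    ``angle_degrees`` is the circular mean of the per-year angles, in
    (-180, 180]; ``weeks_equivalent = angle_degrees / 360 * period``.
    Positive values mean the second label of ``pair`` peaks later in the
    year than the first.
    """

    pair: tuple[str, str]
    angle_degrees: float
    weeks_equivalent: float
    per_year_angles: list[float]
    period: float = 52.0

    def to_dict(self) -> dict:
        return {
            "first": self.pair[0],
            "second": self.pair[1],
            "angle_degrees": self.angle_degrees,
            "weeks_equivalent": self.weeks_equivalent,
            "per_year_angles": list(self.per_year_angles),
            "period": self.period,
        }


def study_year_windows(
    start: pd.Timestamp, n_years: int, period_weeks: int = 52
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Consecutive non-overlapping 52-week windows anchored at ``start``.

    Anchoring at the study start week (an August start for the motivating
    five-year design) places each winter mid-window, so every window
    contains exactly one winter peak. Windows are half-open
    ``[start, end)``.
    """
    start = pd.Timestamp(start)
    step = pd.Timedelta(days=7 * period_weeks)
    return [(start + i * step, start + (i + 1) * step) for i in range(n_years)]


def annual_peaks(
    component: SeasonalComponent,
    year_windows: list[tuple[pd.Timestamp, pd.Timestamp]],
    year_labels: list[str] | None = None,
) -> PeakCalendar:
    """Locate the seasonal-component peak within each analysis-year window.

    Per window the week of maximum component value is taken; ties break to
    the earliest week. Windows are half-open ``[start, end)`` and must be
    fully covered by the component's week grid.

    Raises
    ------
    ValueError
        If a window is not fully covered.
    DegenerateSeriesError
        If the component is constant within a window.
    """
    weeks = component.weeks
    values = np.asarray(component.values, dtype=float)
    if year_labels is None:
        year_labels = [f"year {i + 1}" for i in range(len(year_windows))]
    peaks: list[AnnualPeak] = []
    for label, (w_start, w_end) in zip(year_labels, year_windows):
        w_start, w_end = pd.Timestamp(w_start), pd.Timestamp(w_end)
        mask = (weeks >= w_start) & (weeks < w_end)
        n_expected = int((w_end - w_start).days // 7)
        if mask.sum() < n_expected:
            raise ValueError(
                f"{component.term!r}: window {w_start.date()}..{w_end.date()} "
                "not fully covered by the component"
            )
        window_vals = values[mask]
        if np.ptp(window_vals) == 0:
            raise DegenerateSeriesError(
                f"{component.term!r}: constant component in window starting "
                f"{w_start.date()}"
            )
        i_local = int(np.argmax(window_vals))  # argmax takes the first max
        i_global = np.flatnonzero(mask)[i_local]
        date = weeks[i_global]
        peaks.append(
            AnnualPeak(
                year_label=label,
                date=date,
                week_in_window=int((date - w_start).days // 7),
                value=float(values[i_global]),
            )
        )
    return PeakCalendar(term=component.term, peaks=peaks)


def phase_angle_between(
    a: PeakCalendar, b: PeakCalendar, period: float = 52.0
) -> PhaseComparison:
    """Mean peak-to-peak phase angle between two terms' peak calendars.

    Per shared year the angle is ``(peak_week_b - peak_week_a) / period *
    360`` wrapped to (-180, 180]; the summary angle is the circular mean of
    the per-year angles. Positive means ``b`` peaks later than ``a``.

    Raises
    ------
    ValueError
        If the calendars do not cover the same set of year labels.
    """
    if a.year_labels != b.year_labels:
        raise ValueError(
            f"year labels differ: {a.year_labels} vs {b.year_labels}"
        )
    per_year = [
        wrap_angle(
            weeks_to_degrees(
                b.peak(y).week_in_window - a.peak(y).week_in_window, period
            )
        )
        for y in a.year_labels
    ]
    angle = circular_mean_degrees(np.array(per_year))
    return PhaseComparison(
        pair=(a.term, b.term),
        angle_degrees=angle,
        weeks_equivalent=degrees_to_weeks(angle, period),
        per_year_angles=per_year,
        period=period,
    )


def yearly_phase_shift(
    calendar_: PeakCalendar, reference_year: str, period: float = 52.0
) -> list[PhaseComparison]:
    """Within-term phase shift of each year relative to a reference year.

    Returns one :class:`PhaseComparison` per non-reference year, with pair
    ``(reference_year, year)``; a negative angle means that year's peak
    falls earlier in its window than the reference year's peak did.
    """
    if reference_year not in calendar_.year_labels:
        raise ValueError(
            f"{calendar_.term!r}: reference year {reference_year!r} absent"
        )
    ref = calendar_.peak(reference_year)
    out: list[PhaseComparison] = []
    for peak in calendar_.peaks:
        if peak.year_label == reference_year:
            continue
        angle = wrap_angle(
            weeks_to_degrees(peak.week_in_window - ref.week_in_window, period)
        )
        out.append(
            PhaseComparison(
                pair=(reference_year, peak.year_label),
                angle_degrees=angle,
                weeks_equivalent=degrees_to_weeks(angle, period),
                per_year_angles=[angle],
                period=period,
            )
        )
    return out
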
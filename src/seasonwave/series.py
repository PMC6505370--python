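"""Weekly relative-search-volume series and the operations that shape them.

The central container is :class:`WeeklySeries`: one search term's weekly
relative search volume on the 0–100 scale used by public search-interest
exports, where the week with the highest search proportion over the whole
window scores 100 and every other week is scaled proportionally.

Operations here are deliberately small and pure: rescaling a series so its
maximum is exactly 100 (:func:`normalize_relative`) and averaging a primary
term with its retained related-search series (:func:`merge_related`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateSeriesError

__all__ = ["WeeklySeries", "TermQuery", "normalize_relative", "merge_related"]

#: Sampling interval of the data: one calendar week.
WEEK = pd.Timedelta(days=7)


@dataclass
class WeeklySeries:
    """One term's dated weekly relative search volume.

    Parameters
    ----------
    term
        Text label of the search term (e.g. ``"anxiety"``).
    weeks
        Ordered week start dates; coerced to a :class:`pandas.DatetimeIndex`.
        Must be strictly increasing with constant 7-day spacing.
    values
        Relative search volume per week, dimensionless. On ingest these lie
        in [0, 100]; intermediate (pre-normalization) volumes may exceed 100.
    """

    term: str
    weeks: pd.DatetimeIndex
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weeks = pd.DatetimeIndex(self.weeks)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.weeks) != len(self.values):
            raise AlignmentError(
                f"{self.term!r}: {len(self.weeks)} weeks but {len(self.values)} values"
            )
        if len(self.weeks) >= 2:
            steps = np.diff(self.weeks.values)
            if not (steps == np.timedelta64(7, "D")).all():
                raise AlignmentError(
                    f"{self.term!r}: weeks must be strictly increasing with 7-day spacing"
                )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.term!r}: non-finite volume values")
        if (self.values < 0).any():
            raise ValueError(f"{self.term!r}: negative volume values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_years(self) -> int:
        """Number of whole 52-week analysis years covered."""
        return len(self) // 52

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns ``term, week, value``."""
        return pd.DataFrame(
            {"term": self.term, "week": self.weeks, "value": self.values}
        )

    def replace(self, **kwargs) -> "WeeklySeries":
        """Return a copy with the given fields replaced."""
        data = {"term": self.term, "weeks": self.weeks, "values": self.values}
        data.update(kwargs)
        return WeeklySeries(**data)


@dataclass(frozen=True)
class TermQuery:
    """A primary search term with its related searches and exclusions.

    ``related_terms`` holds at most the top-10 related searches returned for
    the primary term; ``exclusions`` lists labels to drop before averaging
    (e.g. entertainment titles that match the term string but not the topic).
    Matching is exact but case-insensitive.
    """

    primary_term: str
    related_terms: tuple[str, ...] = ()
    exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "related_terms", tuple(self.related_terms))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        if len(self.related_terms) > 10:
            raise ValueError(
                f"{self.primary_term!r}: more than 10 related terms "
                f"({len(self.related_terms)})"
            )

    def is_excluded(self, term: str) -> bool:
        return term.lower() in {e.lower() for e in self.exclusions}


def normalize_relative(series: WeeklySeries) -> WeeklySeries:
    """Rescale a series so its maximum value is exactly 100.

    Every value is multiplied by ``100 / max(values)``, reproducing the
    relative-volume convention of the source exports: the busiest week
    scores 100, a value of 50 means half the maximum proportion. The
    operation is idempotent and invariant to positive rescaling of its
    input. Ties at the maximum are all mapped to 100.

    Raises
    ------
    DegenerateSeriesError
        If the series has no strictly positive value.
    """
    peak = series.values.max(initial=-np.inf)
    if not peak > 0:
        raise DegenerateSeriesError(
            f"{series.term!r}: cannot normalize a series with no positive value"
        )
    return series.replace(values=series.values * (100.0 / peak))


def merge_related(series_list: list[WeeklySeries], query: TermQuery) -> WeeklySeries:
    """Average a primary term's series with its retained related searches.

    Series whose ``term`` matches an entry of ``query.exclusions``
    (case-insensitively) are dropped; the remaining series are averaged
    week-by-week and the mean series re-normalized so its maximum is 100.
    The result carries ``query.primary_term`` as its label.

    Raises
    ------
    AlignmentError
        If the retained series do not share an identical week grid.
    ValueError
        If no series survives exclusion filtering.
    """
    retained = [s for s in series_list if not query.is_excluded(s.term)]
    if not retained:
        raise ValueError(
            f"{query.primary_term!r}: no series left after applying exclusions"
        )
    grid = retained[0].weeks
    for s in retained[1:]:
        if len(s.weeks) != len(grid) or not (s.weeks == grid).all():
            raise AlignmentError(
                f"{s.term!r}: week grid differs from {retained[0].term!r}"
            )
    mean = np.mean([s.values for s in retained], axis=0)
    merged = WeeklySeries(term=query.primary_term, weeks=grid, values=mean)
    return normalize_relative(merged)
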
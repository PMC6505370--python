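"""Reading and writing the weekly search-interest CSV dialect.

The public search-interest service exports one term per file as::

    Category: All categories
    <blank line>
    Week,anxiety: (Ontario)
    2012-08-05,64
    2012-08-12,<1
    ...

i.e. an optional two-line preamble, a header whose first column is ``Week``,
ISO ``YYYY-MM-DD`` week-start dates, and integer volumes where weeks below
the reporting floor appear as the censored token ``"<1"``. This module reads
that dialect (and a strict headerless-preamble variant), repairs interior
gaps by linear interpolation onto the uniform weekly grid, and writes both
the same dialect and a canonical tidy CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, SeriesLengthError, TrendsParseError
from .series import WEEK, WeeklySeries

__all__ = ["read_trends_csv", "write_trends_csv", "write_tidy_csv", "read_tidy_csv"]

logger = logging.getLogger(__name__)

#: Value substituted for the censored low-volume token "<1": the midpoint of
#: the censoring interval (0, 1), preserving positivity without inflating
#: low-volume weeks.
CENSORED_LOW_VALUE = 0.5

#: Minimum series length for downstream wavelet analysis: two full periods
#: of the 52-week annual cycle.
MIN_WEEKS = 104


def _parse_volume(token: str, path: Path, line_no: int) -> float:
    token = token.strip()
    if token == "<1":
        return CENSORED_LOW_VALUE
    try:
        return float(token)
    except ValueError:
        raise TrendsParseError(
            f"{path}, line {line_no}: non-numeric volume {token!r}"
        ) from None


def _parse_date(token: str, path: Path, line_no: int) -> pd.Timestamp:
    try:
        return pd.Timestamp(pd.to_datetime(token.strip(), format="%Y-%m-%d"))
    except (ValueError, TypeError):
        raise TrendsParseError(
            f"{path}, line {line_no}: malformed date {token!r}"
        ) from None


def read_trends_csv(
    path: str | Path,
    *,
    dialect: str = "auto",
    term: str | None = None,
    min_length: int = MIN_WEEKS,
) -> WeeklySeries:
    """Read one term's weekly series from a search-interest CSV export.

    Parameters
    ----------
    path
        CSV file with a date column and one volume column.
    dialect
        ``"auto"`` (default) skips an optional preamble by locating the
        header row whose first cell is ``Week``; ``"strict"`` requires the
        header on the first line.
    term
        Override for the term label; by default the volume column header is
        used, truncated at the first ``":"`` (the export appends the region,
        e.g. ``"anxiety: (Ontario)"``).
    min_length
        Minimum number of weeks required after gap repair (default 104, two
        full annual cycles as required by the wavelet stage).

    Returns
    -------
    WeeklySeries
        Values as exported (``"<1"`` parsed to 0.5); interior missing weeks
        filled by linear interpolation (logged as a warning).

    Raises
    ------
    TrendsParseError
        Malformed date or non-``"<1"`` non-numeric volume (names the line).
    AlignmentError
        Week spacing not a positive multiple of 7 days.
    SeriesLengthError
        Fewer than ``min_length`` weeks after repair.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    if dialect == "strict":
        header_idx = 0
    else:
        for i, line in enumerate(lines[:10]):
            first = line.split(",")[0].strip().lower()
            if first == "week":
                header_idx = i
                break
        if header_idx is None:
            raise TrendsParseError(f"{path}: no 'Week' header row found")

    header = [c.strip() for c in lines[header_idx].split(",")]
    if len(header) < 2:
        raise TrendsParseError(f"{path}: header must have a date and a volume column")
    if term is None:
        term = header[1].split(":")[0].strip()

    dates: list[pd.Timestamp] = []
    values: list[float] = []
    for offset, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) < 2:
            raise TrendsParseError(f"{path}, line {offset}: expected 2 columns")
        dates.append(_parse_date(cells[0], path, offset))
        values.append(_parse_volume(cells[1], path, offset))

    if not dates:
        raise TrendsParseError(f"{path}: no data rows")

    idx = pd.DatetimeIndex(dates)
    vals = np.asarray(values, dtype=float)
    order = np.argsort(idx.values)
    idx, vals = idx[order], vals[order]

    steps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
    if (steps <= 0).any():
        raise AlignmentError(f"{path}: duplicate or non-increasing week dates")
    if (steps % 7 != 0).any():
        raise AlignmentError(f"{path}: week spacing not a multiple of 7 days")

    if (steps != 7).any():
        full = pd.date_range(idx[0], idx[-1], freq="7D")
        n_missing = len(full) - len(idx)
        day0 = (idx - idx[0]).days.to_numpy(dtype=float)
        day_full = (full - full[0]).days.to_numpy(dtype=float)
        vals = np.interp(day_full, day0, vals)
        idx = full
        logger.warning(
            "%s (%s): interpolated %d missing interior week(s)", path, term, n_missing
        )

    if len(idx) < min_length:
        raise SeriesLengthError(
            f"{path}: {len(idx)} weeks < required minimum {min_length}"
        )
    return WeeklySeries(term=term, weeks=idx, values=vals)


def write_trends_csv(
    series: WeeklySeries,
    path: str | Path,
    *,
    preamble: bool = True,
    region: str = "",
    decimals: int = 1,
) -> Path:
    """Write a series back in the search-interest export dialect.

    Volumes are written with ``decimals`` decimal places (trailing ``.0``
    trimmed, so integer exports round-trip byte-for-byte); values below 1
    but above 0 are written as the censored token ``"<1"`` only when
    ``decimals`` is 0, otherwise numerically.
    """
    path = Path(path)
    label = f"{series.term}: ({region})" if region else series.term
    rows = []
    if preamble:
        rows += ["Category: All categories", ""]
    rows.append(f"Week,{label}")
    for week, value in zip(series.weeks, series.values):
        if decimals == 0 and 0 < value < 1:
            text = "<1"
        else:
            text = f"{value:.{decimals}f}".rstrip("0").rstrip(".")
            if text in ("", "-"):
                text = "0"
        rows.append(f"{week.date().isoformat()},{text}")
    path.write_text("\n".join(rows) + "\n")
    return path


def write_tidy_csv(series_list: list[WeeklySeries], path: str | Path) -> Path:
    """Write one or more series as canonical tidy CSV (term, week, value)."""
    path = Path(path)
    frame = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    frame["week"] = frame["week"].dt.date
    frame.to_csv(path, index=False)
    return path


def read_tidy_csv(path: str | Path) -> list[WeeklySeries]:
    """Read series written by :func:`write_tidy_csv`."""
    frame = pd.read_csv(path, parse_dates=["week"])
    out = []
    for term, grp in frame.groupby("term", sort=False):
        out.append(
            WeeklySeries(
                term=str(term),
                weeks=pd.DatetimeIndex(grp["week"]),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return out
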
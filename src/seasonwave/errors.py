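"""Exception hierarchy for seasonwave.

All exceptions derive from :class:`SeasonwaveError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (ValueError) for idiomatic handling.
"""


class SeasonwaveError(Exception):
    """Base class for all seasonwave errors."""


class TrendsParseError(SeasonwaveError, ValueError):
    """A CSV row could not be parsed (malformed date or volume token)."""


class SeriesLengthError(SeasonwaveError, ValueError):
    """A series is too short for the requested analysis."""


class AlignmentError(SeasonwaveError, ValueError):
    """Week grids are non-uniform or do not match across series."""


class DegenerateSeriesError(SeasonwaveError, ValueError):
    """A series is constant / all-zero where variation is required."""


class ConfigError(SeasonwaveError, ValueError):
    """An analysis configuration value is invalid or inconsistent."""
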
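"""Reference values from a published five-year study of weekly mental-health
search interest (Ontario, August 2012 - August 2017).

The study's raw weekly extracts were never deposited (and the upstream
service's normalization is time-varying), so its headline search volumes
cannot be recomputed. What *can* be reproduced exactly is the study's
printed arithmetic: the winter-summer percent-change summaries per term
(mean, SD over n = 5 years), the reported 95% confidence intervals, the
one-way ANOVA across terms, and every printed (phase angle, weeks) pair.
This module stores those printed values as inputs for worked examples and
reproduction checks.

Note: in the year-over-year shift table, the "health" row prints positive
week values against negative angles (inconsistent with the stated sign
convention, under which angle and weeks share a sign), and the depression
year-5 cell prints (-49.0 deg, -7.0 weeks) although -49.0/360*52 = -7.08;
both are preserved here as printed and flagged by the ``sign_consistent``
column where applicable.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "winter_summer_summary",
    "reported_confidence_intervals",
    "phase_week_pairs",
    "N_YEARS",
]

#: Number of analysis years behind each per-term summary.
N_YEARS = 5

# term -> (mean percent change, SD), n = 5 years each
_SUMMARY = {
    "anxiety": (21.2, 7.6),
    "autism": (37.5, 6.6),
    "bipolar": (26.6, 3.9),
    "depression": (28.7, 2.5),
    "ocd": (45.2, 4.9),
    "schizophrenia": (43.3, 10.5),
    "health": (31.6, 6.4),
}

# term -> reported 95% CI (lower, upper), percent
_REPORTED_CI = {
    "anxiety": (14.6, 27.8),
    "autism": (31.6, 43.4),
    "bipolar": (23.5, 29.7),
    "depression": (26.5, 30.9),
    "ocd": (40.8, 49.6),
    "schizophrenia": (34.1, 52.5),
    "health": (26.0, 37.2),
}

# (source, label, angle degrees, weeks) as printed; source is one of
# "results_text", "between_terms", "yearly_shift".
_PHASE_PAIRS = [
    ("results_text", "autism-depression", -36.9, -5.3),
    ("results_text", "ocd-schizophrenia", -3.3, -0.48),
    ("results_text", "autism year 5", -52.2, -7.5),
    ("results_text", "depression year 3", -58.7, -8.5),
    ("between_terms", "anxiety-autism", 10.1, 1.5),
    ("between_terms", "anxiety-bipolar", 14.6, 2.1),
    ("between_terms", "anxiety-depression", -22.3, -3.2),
    ("between_terms", "anxiety-ocd", -7.5, -1.1),
    ("between_terms", "anxiety-schizophrenia", -10.8, -1.6),
    ("between_terms", "anxiety-health", -21.0, -3.0),
    ("between_terms", "autism-bipolar", -4.5, -0.7),
    ("between_terms", "autism-depression", -36.9, -5.3),
    ("between_terms", "autism-ocd", -22.1, -3.2),
    ("between_terms", "autism-schizophrenia", -25.4, -3.7),
    ("between_terms", "autism-health", -16.7, -2.4),
    ("between_terms", "bipolar-depression", -32.4, -4.7),
    ("between_terms", "bipolar-ocd", -17.6, -2.5),
    ("between_terms", "bipolar-schizophrenia", -20.9, -3.0),
    ("between_terms", "bipolar-health", -12.2, -1.8),
    ("between_terms", "depression-ocd", 14.8, 2.1),
    ("between_terms", "depression-schizophrenia", 11.5, 1.7),
    ("between_terms", "depression-health", 20.2, 2.9),
    ("between_terms", "ocd-schizophrenia", -3.3, -0.5),
    ("between_terms", "ocd-health", 11.5, 1.7),
    ("between_terms", "schizophrenia-health", -5.4, -0.8),
    ("yearly_shift", "anxiety year 2", -31.3, -4.5),
    ("yearly_shift", "anxiety year 3", -44.7, -6.5),
    ("yearly_shift", "anxiety year 4", -48.4, -7.0),
    ("yearly_shift", "anxiety year 5", -42.3, -6.1),
    ("yearly_shift", "autism year 2", -29.8, -4.3),
    ("yearly_shift", "autism year 3", -52.7, -7.6),
    ("yearly_shift", "autism year 4", -53.9, -7.8),
    ("yearly_shift", "autism year 5", -52.2, -7.5),
    ("yearly_shift", "bipolar year 2", -17.2, -2.5),
    ("yearly_shift", "bipolar year 3", -33.3, -4.8),
    ("yearly_shift", "bipolar year 4", -36.2, -5.2),
    ("yearly_shift", "bipolar year 5", -29.5, -4.3),
    ("yearly_shift", "depression year 2", -50.7, -7.3),
    ("yearly_shift", "depression year 3", -58.7, -8.5),
    ("yearly_shift", "depression year 4", -54.7, -7.9),
    ("yearly_shift", "depression year 5", -49.0, -7.0),
    ("yearly_shift", "ocd year 2", 29.0, 4.2),
    ("yearly_shift", "ocd year 3", 19.5, 2.8),
    ("yearly_shift", "ocd year 4", 27.5, 4.0),
    ("yearly_shift", "ocd year 5", 38.3, 5.5),
    ("yearly_shift", "schizophrenia year 2", 41.8, 6.0),
    ("yearly_shift", "schizophrenia year 3", 34.0, 4.9),
    ("yearly_shift", "schizophrenia year 4", 28.9, 4.2),
    ("yearly_shift", "schizophrenia year 5", 27.0, 3.9),
    # "health" row: printed weeks are positive against negative angles.
    ("yearly_shift", "health year 2", -31.3, 4.5),
    ("yearly_shift", "health year 3", -44.7, 6.5),
    ("yearly_shift", "health year 4", -48.4, 7.0),
    ("yearly_shift", "health year 5", -42.3, 6.1),
]

#: Labels whose printed (angle, weeks) cells are internally inconsistent:
#: the "health" shift row mixes signs, and the depression year-5 cell's
#: printed weeks value differs from its angle's conversion by 0.078.
_SIGN_INCONSISTENT = {f"health year {y}" for y in (2, 3, 4, 5)}
_ROUNDING_INCONSISTENT = {("yearly_shift", "depression year 5")}


def winter_summer_summary() -> pd.DataFrame:
    """Printed per-term percent-change summaries: term, mean, SD, n."""
    rows = [
        {"term": t, "mean_pct": m, "sd_pct": s, "n": N_YEARS}
        for t, (m, s) in _SUMMARY.items()
    ]
    return pd.DataFrame(rows)


def reported_confidence_intervals() -> pd.DataFrame:
    """Printed 95% CIs per term: term, ci_lower, ci_upper."""
    rows = [
        {"term": t, "ci_lower": lo, "ci_upper": hi}
        for t, (lo, hi) in _REPORTED_CI.items()
    ]
    return pd.DataFrame(rows)


def phase_week_pairs() -> pd.DataFrame:
    """Every printed (phase angle, weeks) pair.

    Columns: source, label, angle_degrees, weeks, sign_consistent (False
    for the "health" shift row), rounding_consistent (False only for the
    depression year-5 cell).
    """
    frame = pd.DataFrame(
        _PHASE_PAIRS, columns=["source", "label", "angle_degrees", "weeks"]
    )
    frame["sign_consistent"] = ~frame["label"].isin(_SIGN_INCONSISTENT)
    frame["rounding_consistent"] = [
        (src, lab) not in _ROUNDING_INCONSISTENT
        for src, lab in zip(frame["source"], frame["label"])
    ]
    return frame
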
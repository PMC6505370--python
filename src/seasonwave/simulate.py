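"""Synthetic weekly search-interest panels with known seasonal structure.

No public archive of the motivating study's raw weekly extracts exists (the
upstream service's normalization is also time-varying, so a fresh download
would not reproduce it). This generator therefore emulates the *design* of
such data: ~261 weekly points spanning five years from an August anchor,
annual (52-week) cosine seasonality peaking in winter, geometric
year-over-year amplitude growth, slow phase drift, additive white or AR(1)
noise, one-decimal quantization, and normalization so the series maximum is
exactly 100.

Because every series is generated from an explicit :class:`SeriesSpec`, the
true peak weeks, phase offsets and noise-free percent changes are known in
closed form — the basis for the parameter-recovery tests of the full
pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .series import WeeklySeries, normalize_relative

__all__ = ["SeriesSpec", "generate_series", "generate_study_panel", "STUDY_START"]

#: Default study anchor: first week of August 2012 (a Sunday week start),
#: mirroring the five-year August-to-August design the generator emulates.
STUDY_START = pd.Timestamp("2012-08-05")


@dataclass(frozen=True)
class SeriesSpec:
    """Generating parameters for one synthetic weekly series.

    Attributes
    ----------
    term
        Series label.
    n_years
        Number of 52-week analysis years (>= 2); the series has
        ``52 * n_years + 1`` weekly points.
    base_level
        Mean volume before normalization, arbitrary units.
    seasonal_amplitude_year1
        Cosine amplitude in year 1, same units; 0 gives a pure-noise series.
    amplitude_growth
        Fractional amplitude change per year (geometric).
    peak_week_year1
        Week-of-window (0-based, from the August anchor) of the year-1
        winter peak.
    phase_drift_per_year
        Weeks of peak shift per year; negative = earlier each year.
    noise_sd
        Additive noise standard deviation, same units as ``base_level``.
    noise_model
        ``"white"`` (iid normal) or ``"ar1"`` (stationary AR(1) with
        marginal SD ``noise_sd`` and lag-1 correlation ``ar1_rho``).
    seed
        RNG seed; generation is fully reproducible.
    """

    term: str
    n_years: int = 5
    base_level: float = 60.0
    seasonal_amplitude_year1: float = 10.0
    amplitude_growth: float = 0.05
    peak_week_year1: float = 26.0
    phase_drift_per_year: float = 0.0
    noise_sd: float = 2.0
    noise_model: str = "white"
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError(f"{self.term!r}: n_years must be >= 2")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"{self.term!r}: unknown noise_model {self.noise_model!r}")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError(f"{self.term!r}: ar1_rho must be in [0, 1)")
        max_amp = self.seasonal_amplitude_year1 * (
            (1 + self.amplitude_growth) ** (self.n_years - 1)
        )
        if self.base_level <= max_amp + 4 * self.noise_sd:
            raise ValueError(
                f"{self.term!r}: base_level must exceed the final-year "
                "amplitude plus 4 noise SDs to keep volumes positive"
            )

    @property
    def n_weeks(self) -> int:
        return 52 * self.n_years + 1

    def amplitude(self, year_index: int) -> float:
        """Cosine amplitude in analysis year ``year_index`` (0-based)."""
        return self.seasonal_amplitude_year1 * (1 + self.amplitude_growth) ** year_index

    def peak_week(self, year_index: int) -> float:
        """True peak week-of-window in analysis year ``year_index`` (0-based)."""
        return self.peak_week_year1 + self.phase_drift_per_year * year_index

    def noise_free_percent_change(self, year_index: int) -> float:
        """Closed-form winter-summer percent change absent noise.

        Peak = base + A(y), trough = base - A(y), so the change is
        ``2 A(y) / (base - A(y)) * 100`` — strictly increasing in A(y).
        """
        a = self.amplitude(year_index)
        return 2 * a / (self.base_level - a) * 100.0

    def to_dict(self) -> dict:
        return asdict(self)


def _noise(spec: SeriesSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.standard_normal(n)
    if spec.noise_model == "white" or spec.ar1_rho == 0:
        return spec.noise_sd * z
    rho = spec.ar1_rho
    eps = np.empty(n)
    eps[0] = z[0]
    for t in range(1, n):  # innovations scaled for unit marginal variance
        eps[t] = rho * eps[t - 1] + np.sqrt(1 - rho**2) * z[t]
    return spec.noise_sd * eps


def generate_series(
    spec: SeriesSpec, start: pd.Timestamp = STUDY_START
) -> WeeklySeries:
    """Generate one synthetic weekly series from its spec.

    Week ``t`` of analysis year ``y`` takes the value ``base + A(y) *
    cos(2 pi (t_within - p(y)) / 52) + noise`` with ``A(y)`` growing
    geometrically and ``p(y)`` the drifting peak week; values are rounded
    to one decimal and the series normalized so its maximum is exactly 100.
    """
    n = spec.n_weeks
    t = np.arange(n)
    y = np.minimum(t // 52, spec.n_years - 1)
    t_within = t - 52 * y
    amp = spec.seasonal_amplitude_year1 * (1 + spec.amplitude_growth) ** y
    peak = spec.peak_week_year1 + spec.phase_drift_per_year * y
    signal = spec.base_level + amp * np.cos(2 * np.pi * (t_within - peak) / 52.0)
    rng = np.random.default_rng(spec.seed)
    values = np.round(signal + _noise(spec, rng, n), 1)
    weeks = pd.date_range(pd.Timestamp(start), periods=n, freq="7D")
    raw = WeeklySeries(term=spec.term, weeks=weeks, values=np.clip(values, 0, None))
    return normalize_relative(raw)


#: Study-panel design: seven seasonal terms (amplitudes spanning the ~20-45%
#: winter-summer range, winter peaks January-April, mostly drifting earlier
#: year over year, with the "ocd"/"schizophrenia" pair nearly in phase and
#: drifting later) plus two non-seasonal pure-noise controls.
_PANEL_DESIGN: tuple[dict, ...] = (
    dict(term="anxiety", seasonal_amplitude_year1=5.7, peak_week_year1=32.0,
         phase_drift_per_year=-1.5),
    dict(term="autism", seasonal_amplitude_year1=9.5, peak_week_year1=35.0,
         phase_drift_per_year=-1.9),
    dict(term="bipolar", seasonal_amplitude_year1=7.0, peak_week_year1=33.0,
         phase_drift_per_year=-1.1),
    dict(term="depression", seasonal_amplitude_year1=7.5, peak_week_year1=27.0,
         phase_drift_per_year=-1.8),
    dict(term="ocd", seasonal_amplitude_year1=11.2, peak_week_year1=24.0,
         phase_drift_per_year=1.4),
    dict(term="schizophrenia", seasonal_amplitude_year1=10.8, peak_week_year1=25.0,
         phase_drift_per_year=1.0),
    dict(term="health", seasonal_amplitude_year1=8.2, peak_week_year1=28.0,
         phase_drift_per_year=-1.5),
    dict(term="suicide", seasonal_amplitude_year1=0.0, noise_sd=5.0),
    dict(term="how", seasonal_amplitude_year1=0.0, noise_sd=5.0),
)


def panel_specs(panel_seed: int, n_years: int = 5) -> dict[str, SeriesSpec]:
    """The study-panel specs with per-term seeds derived from ``panel_seed``."""
    children = np.random.SeedSequence(panel_seed).spawn(len(_PANEL_DESIGN))
    specs: dict[str, SeriesSpec] = {}
    for design, child in zip(_PANEL_DESIGN, children):
        seed = int(child.generate_state(1)[0] % (2**31))
        spec = SeriesSpec(n_years=n_years, seed=seed, **design)
        specs[spec.term] = spec
    return specs


def generate_study_panel(
    panel_seed: int, n_years: int = 5, start: pd.Timestamp = STUDY_START
) -> tuple[dict[str, WeeklySeries], dict[str, SeriesSpec]]:
    """Generate the nine-term study-shaped panel.

    Returns the mapping term -> series together with the specs used, so
    parameter-recovery tests can compare pipeline estimates against the
    generating truth. Identical ``panel_seed`` gives identical panels.
    """
    specs = panel_specs(panel_seed, n_years=n_years)
    panel = {term: generate_series(spec, start=start) for term, spec in specs.items()}
    return panel, specs


def with_peak_offset(spec: SeriesSpec, delta_weeks: float, seed: int) -> SeriesSpec:
    """Copy of ``spec`` whose every yearly peak is shifted by ``delta_weeks``."""
    return replace(
        spec, peak_week_year1=spec.peak_week_year1 + delta_weeks, seed=seed
    )
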
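# Methods

This note documents the models and procedures implemented in `seasonwave`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a user auditing the
results should know about.

## Data model

A `WeeklySeries` is one term's weekly relative search volume: strictly
increasing week-start dates at exact 7-day spacing, values in [0, 100]
after normalization. The ingestion layer accepts the common export dialect
(optional two-line preamble, `Week,<term>` header, ISO dates) plus a strict
headerless variant. Two dialect rules matter for analysis:

* the censored token `"<1"` parses to 0.5, the midpoint of the censoring
  interval — this preserves positivity without inflating low-volume weeks;
* interior missing weeks are filled by linear interpolation (and logged),
  because the wavelet transform requires an uninterrupted uniform grid.
  Dropping them would silently shift every later phase estimate.

Week identity is the exported week-start date; no ISO-week renumbering is
applied. Related-search averaging (`merge_related`) takes the arithmetic
mean of the retained series per week and re-normalizes; exclusion matching
is exact but case-insensitive, and the exclusion list is an explicit input
rather than a judgment call buried in code. Any number of weeks may tie at
100 after normalization.

## Continuous wavelet transform

The transform uses the complex Morlet wavelet with central frequency
ω₀ = 6, the conventional choice for which the Fourier period is ≈ 1.033
times the scale. The frequency-domain filter at scale *s* is
`H_s(ω) = 2·exp(−(sω − ω₀)²/2)` for ω > 0 (zero otherwise). This amplitude
normalization makes a unit-amplitude sinusoid produce coefficients of
modulus ≈ 1 at the matching scale *independently of scale*, so wavelet
power is comparable across periods and scales quadratically with signal
amplitude — convenient when the statistic of interest is power at one
target period.

Defaults: periods 2–104 weeks (Nyquist to two octaves above the annual
cycle, so 52 weeks is bracketed by at least one octave on each side; the
104-week ceiling also respects the half-length precondition for 5-year
series), 12 voices per octave, OLS linear detrend plus mean removal before
transforming (multi-year search series carry secular trends that would
otherwise leak into low frequencies; detrending is on by default and
recorded in the spectrum).

The transform is computed by FFT with zero padding to the next power of
two covering the series **plus eight e-foldings of the widest wavelet's
envelope**. Padding only to twice the series length — a common shortcut —
leaves circular wraparound of order 10⁻¹ at the largest scales; with the
wider padding the frequency-domain route agrees with a direct time-domain
convolution against the analytic kernel to ~10⁻¹⁰ relative (verified in
the test suite for scales well below Nyquist, where the sampled analytic
kernel is itself exact). The cone of influence uses the standard Morlet
e-folding distance √2·s: at distance *d* from the nearer edge, periods up
to `1.033·d/√2` weeks are edge-free.

## Significance of the 52-week component

The test statistic is the time-averaged power at the grid period nearest
52 weeks (50.8 with the default grid; the grid period used is recorded in
the result). The null model is white Gaussian noise with the observed
series' length, mean and sample SD; each of the `n_surrogates` (default
1000, minimum 100) surrogate series runs through the identical pipeline
(detrend, transform at the target scale, time-average, same
cone-of-influence policy), and

    p = (1 + #{surrogate statistic ≥ observed}) / (n_surrogates + 1),

so the smallest attainable p is 1/(n+1) and seeded runs are bit-for-bit
reproducible. The seed is mandatory. By default all time points enter the
average (`include_all`); `exclude_coi` is available, and the choice is
recorded in the result. Against its own null the test is slightly
conservative — measured type-I error 0.041 at α = .05 over 3000 replicates
versus the nominal 0.045 — because the surrogates match the *sample*
moments of the observed series. Weekly search-interest noise is serially
correlated in reality; the white-noise null (mirroring the simulation
framework this analysis style descends from) is anti-conservative under
strong positive autocorrelation, which is why the generator offers an
AR(1) noise model for stress testing.

## Seasonal component and peak timing

The seasonal signal is reconstructed by summing the real parts of the
coefficients over the scales whose period falls in the band (default
40–68 weeks, bracketing the annual cycle symmetrically in log-period) and
dividing by a reconstruction constant. The constant is the band-restricted
discrete form of the standard Morlet admissibility sum, evaluated at the
band's geometric-center frequency: for a signal at the band center the
attenuation sum cancels exactly, and for a full-grid band the constant
converges to the usual continuous admissibility integral. A fixed
full-grid constant would under-reconstruct a 52-week signal taken from the
40–68-week band by ~14 % (the Gaussian attenuation mass outside the band),
biasing every amplitude read off the component.

Annual peaks are the argmax of the component inside each 52-week analysis
window (anchored at the study start week, so an August-anchored design
places each winter mid-window); ties break to the earliest week, and peak
arithmetic stays in integer weeks — the data resolution — with no sub-week
interpolation. Peak labels follow the "Month, week k" convention with
days 1–7 as week 1.

Phase angles: per shared year, `(peak_b − peak_a)/period × 360`, wrapped
to (−180°, 180°] with +180° kept at the boundary; per-year angles are
aggregated by the circular mean (mean resultant direction), since
arithmetic means of wrapped angles are biased near ±180°. Positive angles
mean the second label peaks later in the year. Week equivalents are exact
(`angle/360 × period`); rounding is left to presentation.

**Edge behaviour.** Zero padding attenuates the reconstructed component
near the series ends (the wavelet's Gaussian envelope extends ~±70 weeks
at the annual scale), which drags first- and last-year peak estimates
toward the series interior by up to 1–2 weeks when the phase drifts year
over year. An analytic erf-based edge-gain correction is available
(`reconstruct_band(..., edge_correction=True)`); it flattens the amplitude
ramp and reduces the average drift-year bias, but over-advances edge-year
peaks of signals sitting below the band center, so the plain standard
reconstruction remains the default. Consequently, *cumulative* year-5
shifts carry an irreducible ~1-week uncertainty, whereas the per-year
drift **rate** (OLS slope of the five yearly shifts) and *between-series*
offsets (both series share the edge bias, which cancels in the
difference) are recovered to within half a week on synthetic ground truth.

## Winter–summer amplitude statistics

Percent change per analysis year is `(winter peak − summer trough) /
summer trough × 100`, computed on the raw normalized series, not the
band-reconstructed component — the quantity describes search volume, not a
filtered signal. Winter defaults to October–March and summer to April
through the window end within each August-anchored year; both windows are
configurable since the underlying study design never fixes them. The
summary per term is the mean, sample SD (n−1) and the normal-approximation
95 % CI `mean ± 1.96·SD/√n`; the z multiplier, not t₄ = 2.776, is the
convention this analysis style reports.

A caveat documented rather than hidden: because the statistic is an
extreme (max over ~26 winter weeks, min over ~18 summer weeks), additive
noise inflates it by roughly `1.8σ` in each tail. At the generator's
default noise level the measured percent change therefore sits well above
the noise-free closed form; the closed form is recovered only as noise
vanishes. Comparisons *between* terms measured under the same noise are
unaffected in expectation.

Between-term inference is a classical balanced fixed-effects one-way
ANOVA (computable identically from raw values or per-group mean/SD/n
sufficient statistics — the latter lets published summary tables be
re-analyzed), with partial η² = SS_between/(SS_between + SS_within), and
Tukey HSD post-hoc comparisons via the studentized range distribution
(Tukey–Kramer standard error, exact for balanced groups). Mean differences
are oriented first-minus-second in the pair's label order. No
heteroscedastic or non-parametric variants are provided.

## Synthetic-data generator

`generate_series` produces `52·n_years + 1` weekly values from an August
2012 anchor: `base + A(y)·cos(2π(t_within − p(y))/52) + ε`, with A(y)
growing geometrically (`amplitude_growth` per year), p(y) the per-year
peak week drifting by `phase_drift_per_year`, and ε white or stationary
AR(1) noise. Values are rounded to one decimal (mimicking coarse export
quantization), clipped at zero, and normalized so the maximum is exactly
100. A validity invariant keeps the pre-normalization signal positive
(base exceeds final-year amplitude plus 4 noise SDs).

`generate_study_panel` emulates the motivating study design: seven
seasonal terms whose amplitudes span the reported ~20–45 % winter–summer
range, winter peaks between January and April, year-over-year drifts of
−1.9…+1.4 weeks/year with one nearly in-phase pair drifting later, plus
two pure-noise controls ("suicide", "how"); per-term seeds derive from one
panel seed. Defaults: base 60, year-1 amplitude 10, growth 5 %/year, noise
SD 2 (signal-to-noise ≈ 5, matching the clearly visible seasonality of the
study's figures).

What the generator does **not** emulate: the export's integer
quantization, the window-dependent renormalization of real extracts,
calendar effects (leap weeks, moving holidays), multiplicative or
heavy-tailed noise, and cross-term correlation. Passing tests therefore
demonstrate that the pipeline recovers known structure under an idealized
single-harmonic model of seasonal search interest — not that real search
data satisfy those assumptions.

## Degenerate inputs and errors

All-zero or constant series are rejected where variation is required
(normalization, periodicity testing, peak detection); a zero summer trough
makes percent change undefined and raises; year windows not fully covered
by the data, mismatched week grids, periods outside the scale grid, and
bands missing the grid all fail loudly with the offending term and window
in the message. The pipeline wraps stage failures with the stage name.

## Problem sizes used in the checks

The test suite and acceptance script run at the study's own scale: 9 terms
× 261 weeks, 1000 surrogates per significance test (199 inside the
repeated-calibration loops), 1500 white-noise replicates for the type-I
calibration, 21 injected offsets for phase recovery, and a 10 000-sample
permutation reference for one Tukey comparison.
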
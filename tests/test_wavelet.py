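import numpy as np
import pytest

from _oracles import cwt_direct_convolution
from seasonwave import (
    ConfigError,
    DegenerateSeriesError,
    SeriesLengthError,
    WaveletConfig,
    WeeklySeries,
    build_scale_grid,
    cwt_morlet,
    reconstruct_band,
    time_avg_power,
)
from seasonwave import test_periodicity as periodicity_test  # avoid pytest collection
from seasonwave.wavelet import _cwt_rows, nearest_grid_period


class TestConfig:
    def test_rejects_small_omega0(self):
        with pytest.raises(ConfigError):
            WaveletConfig(omega0=4)

    def test_rejects_sub_nyquist_min_period(self):
        with pytest.raises(ConfigError):
            WaveletConfig(min_period=1)


class TestScaleGrid:
    def test_geometric_grid_count_and_ratio(self):
        cfg = WaveletConfig(min_period=2, max_period=128, voices_per_octave=12)
        grid = build_scale_grid(cfg, 600)
        assert len(grid) == 73  # floor(12 * log2(64)) + 1
        np.testing.assert_allclose(np.diff(np.log2(grid)), 1 / 12, rtol=1e-12)
        assert grid[0] == 2 and grid[-1] == pytest.approx(128)
        assert grid[0] < 52 < grid[-1]

    def test_degenerate_single_period(self):
        cfg = WaveletConfig(min_period=2, max_period=2)
        np.testing.assert_allclose(build_scale_grid(cfg, 600), [2.0])

    def test_max_period_beyond_half_length_errors(self):
        cfg = WaveletConfig(max_period=200)
        with pytest.raises(ConfigError):
            build_scale_grid(cfg, 261)


class TestTransform:
    def test_zero_series_transforms_to_zero(self, weekly_index):
        s = WeeklySeries("z", weekly_index(261), np.zeros(261))
        spec = cwt_morlet(s, WaveletConfig())
        assert np.all(spec.power == 0)
        assert time_avg_power(spec, 52.0) == 0.0

    def test_matches_direct_convolution_oracle(self, cosine_series):
        # independent oracle: explicit time-domain convolution with the
        # analytic Morlet kernel, at scales far below the Nyquist limit
        s = cosine_series(n=261, noise_sd=2.0, seed=5)
        cfg = WaveletConfig(min_period=16, max_period=104, detrend=True)
        spectrum = cwt_morlet(s, cfg)
        x = s.values - np.polyval(
            np.polyfit(np.arange(261), s.values, 1), np.arange(261)
        )
        x = x - x.mean()
        oracle = cwt_direct_convolution(x, spectrum.periods, cfg.omega0)
        rel = np.max(np.abs(spectrum.coefficients - oracle)) / np.max(np.abs(oracle))
        assert rel < 1e-6

    def test_cosine_power_peaks_within_one_grid_step_of_52(self, cosine_series):
        s = cosine_series(n=260)
        spec = cwt_morlet(s, WaveletConfig())
        avg = [time_avg_power(spec, p) for p in spec.periods]
        best = spec.periods[int(np.argmax(avg))]
        assert abs(np.log2(best / 52.0)) <= 1 / 12 + 1e-9

    def test_power_is_quadratic_in_amplitude(self, cosine_series):
        cfg = WaveletConfig()
        p1 = time_avg_power(cwt_morlet(cosine_series(amplitude=5), cfg), 52.0)
        p2 = time_avg_power(cwt_morlet(cosine_series(amplitude=10), cfg), 52.0)
        assert p2 == pytest.approx(4 * p1, rel=1e-2)

    def test_linearity(self, weekly_index):
        rng = np.random.default_rng(7)
        idx = weekly_index(261)
        x = rng.normal(50, 5, 261)
        y = rng.normal(50, 5, 261)
        cfg = WaveletConfig()
        wx = cwt_morlet(WeeklySeries("x", idx, x), cfg).coefficients
        wy = cwt_morlet(WeeklySeries("y", idx, y), cfg).coefficients
        wz = cwt_morlet(WeeklySeries("z", idx, 0.4 * x + 0.6 * y + 10), cfg).coefficients
        np.testing.assert_allclose(wz, 0.4 * wx + 0.6 * wy, atol=1e-10)

    def test_time_shift_rotates_phase(self, weekly_index):
        # shifting a sinusoid by k weeks rotates every coefficient's phase
        # by 2*pi*k/period of the signal (checked mid-series)
        n, k, period = 400, 5, 52.0
        t = np.arange(n + k)
        x_long = 50 + 10 * np.cos(2 * np.pi * t / period)
        cfg = WaveletConfig(detrend=False)
        w0 = cwt_morlet(WeeklySeries("a", weekly_index(n), x_long[:n]), cfg)
        w1 = cwt_morlet(WeeklySeries("b", weekly_index(n), x_long[k : n + k]), cfg)
        rows = (w0.periods >= 40) & (w0.periods <= 68)
        mid = n // 2
        dphi = np.angle(
            w1.coefficients[rows, mid] / w0.coefficients[rows, mid]
        )
        np.testing.assert_allclose(dphi, 2 * np.pi * k / period, atol=2e-2)

    def test_short_series_rejected(self, cosine_series):
        s = cosine_series(n=150)
        with pytest.raises(SeriesLengthError):
            cwt_morlet(s, WaveletConfig(max_period=104))

    def test_coi_policy_changes_column_count_not_sign(self, cosine_series):
        s = cosine_series(noise_sd=5.0, seed=1)
        spec = cwt_morlet(s, WaveletConfig())
        incl = time_avg_power(spec, 52.0, "include_all")
        excl = time_avg_power(spec, 52.0, "exclude_coi")
        assert incl > 0 and excl > 0
        # mid-series plateau dominates once edge columns are dropped
        assert excl > incl

    def test_power_outside_grid_errors(self, cosine_series):
        spec = cwt_morlet(cosine_series(), WaveletConfig())
        with pytest.raises(ValueError):
            time_avg_power(spec, 200.0)

    def test_nearest_grid_period_is_log_nearest(self):
        periods = np.array([32.0, 45.25, 64.0])
        assert nearest_grid_period(periods, 52.0) == 1


class TestSignificance:
    def test_seeded_runs_identical(self, cosine_series):
        s = cosine_series(noise_sd=1.0)
        cfg = WaveletConfig(seed=42, n_surrogates=200)
        r1 = periodicity_test(s, 52.0, cfg)
        r2 = periodicity_test(s, 52.0, cfg)
        assert r1.p_value == r2.p_value
        assert r1.observed_stat == r2.observed_stat

    def test_strong_sinusoid_hits_simulation_floor(self, cosine_series):
        # amplitude 10 vs noise SD 1: no white-noise surrogate can match
        s = cosine_series(n=260, amplitude=10.0, noise_sd=1.0, seed=3)
        cfg = WaveletConfig(seed=0, n_surrogates=1000)
        res = periodicity_test(s, 52.0, cfg)
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.significant

    def test_constant_series_rejected(self, weekly_index):
        s = WeeklySeries("c", weekly_index(261), np.full(261, 50.0))
        with pytest.raises(DegenerateSeriesError):
            periodicity_test(s, 52.0, WaveletConfig(seed=0))

    def test_seed_required(self, cosine_series):
        with pytest.raises(ConfigError):
            periodicity_test(cosine_series(), 52.0, WaveletConfig(seed=None))

    def test_surrogate_count_floor_enforced(self, cosine_series):
        with pytest.raises(ConfigError):
            periodicity_test(
                cosine_series(), 52.0, WaveletConfig(seed=0, n_surrogates=50)
            )

    def test_p_value_bounds(self, weekly_index):
        rng = np.random.default_rng(9)
        s = WeeklySeries("n", weekly_index(261), rng.uniform(20, 80, 261))
        res = periodicity_test(s, 52.0, WaveletConfig(seed=1, n_surrogates=199))
        assert 1 / 200 <= res.p_value <= 1.0


class TestReconstruction:
    def test_zero_spectrum_gives_zero_component(self, weekly_index):
        s = WeeklySeries("z", weekly_index(261), np.zeros(261))
        comp = reconstruct_band(cwt_morlet(s, WaveletConfig()), (40, 68))
        np.testing.assert_allclose(comp.values, 0.0)

    def test_recovers_cosine_in_band(self, cosine_series):
        s = cosine_series(n=261, amplitude=10.0)
        comp = reconstruct_band(cwt_morlet(s, WaveletConfig()), (40, 68))
        t = np.arange(261)
        ideal = 10 * np.cos(2 * np.pi * (t - 26) / 52)
        mid = slice(30, 231)  # away from edges
        rel = np.linalg.norm(comp.values[mid] - ideal[mid]) / np.linalg.norm(
            ideal[mid]
        )
        assert rel <= 0.10
        assert abs(comp.values.mean()) < 0.1
        assert len(comp) == len(s)

    def test_full_band_reconstruction_correlates_with_input(self, weekly_index):
        # band-limited test signal: two tones inside the analyzed band
        t = np.arange(261)
        x = 8 * np.cos(2 * np.pi * t / 52) + 4 * np.cos(2 * np.pi * t / 26 + 1.0)
        s = WeeklySeries("two-tone", weekly_index(261), x + 50)
        cfg = WaveletConfig(detrend=False)
        comp = reconstruct_band(cwt_morlet(s, cfg), (2, 104))
        mid = slice(30, 231)
        r = np.corrcoef(comp.values[mid], x[mid])[0, 1]
        assert r >= 0.95

    def test_empty_band_errors(self, cosine_series):
        spec = cwt_morlet(cosine_series(), WaveletConfig())
        with pytest.raises(ValueError):
            reconstruct_band(spec, (200, 300))

    def test_edge_correction_flattens_amplitude_ramp(self, cosine_series):
        s = cosine_series(n=261, amplitude=10.0)
        spec = cwt_morlet(s, WaveletConfig())
        plain = reconstruct_band(spec, (40, 68), edge_correction=False)
        fixed = reconstruct_band(spec, (40, 68), edge_correction=True)
        # first-year envelope is attenuated without the correction
        assert np.max(np.abs(fixed.values[:26])) > np.max(np.abs(plain.values[:26]))
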
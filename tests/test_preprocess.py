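import numpy as np
import pytest

from maldiderep.io import Spectrum
from maldiderep.preprocess import (
    PreprocessParams,
    detect_peaks,
    estimate_noise_supersmoother,
    normalize_tic,
    preprocess_pipeline,
    smooth_savitzky_golay,
    snip_baseline,
    sqrt_transform,
    trim,
)


def flat(n, value=1.0, start=4000.0):
    return Spectrum("s", start + np.arange(n, dtype=float), np.full(n, value))


class TestSqrt:
    def test_perfect_squares(self):
        s = Spectrum("s", [1.0, 2, 3, 4], [0.0, 1, 4, 9])
        assert np.allclose(sqrt_transform(s).intensities, [0, 1, 2, 3])

    def test_negative_rejected(self):
        s = Spectrum("s", [1.0, 2], [1.0, 4.0])
        s.intensities[0] = -1.0  # bypass constructor check
        with pytest.raises(ValueError):
            sqrt_transform(s)


class TestTrim:
    def test_inclusive_boundaries(self):
        s = Spectrum("s", [4000.0, 7000, 10000], [1.0, 2, 3])
        t = trim(s, 4000, 10000)
        assert len(t) == 3

    def test_too_few_points_remaining(self):
        s = Spectrum("s", [3000.0, 5000, 12000], [1.0, 2, 3])
        with pytest.raises(ValueError):
            trim(s, 4000, 10000)

    def test_wide_window_is_identity(self):
        s = Spectrum("s", [4000.0, 7000, 10000], [1.0, 2, 3])
        t = trim(s, 2000, 20000)
        assert np.array_equal(t.masses, s.masses)


class TestSavitzkyGolay:
    def test_constant_preserved(self):
        out = smooth_savitzky_golay(flat(100, 3.0))
        assert np.allclose(out.intensities, 3.0, atol=1e-9)

    def test_cubic_reproduced(self):
        n = 200
        x = np.arange(n, dtype=float)
        y = 1e-4 * x**3 - 0.01 * x**2 + x + 5
        s = Spectrum("s", 4000 + x, y)
        out = smooth_savitzky_golay(s, half_window=20, poly_order=3)
        interior = slice(20, n - 20)
        assert np.allclose(out.intensities[interior], y[interior], atol=1e-9)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        y = 10 + rng.normal(0, 1, 10001)
        s = Spectrum("s", 4000 + np.arange(10001.0), y)
        out = smooth_savitzky_golay(s)
        assert out.intensities.var() < y.var()

    def test_too_short(self):
        with pytest.raises(ValueError):
            smooth_savitzky_golay(flat(30), half_window=20)


class TestSnip:
    def test_constant_fully_removed(self):
        base, corr = snip_baseline(flat(200, 5.0))
        assert np.allclose(base, 5.0)
        assert np.allclose(corr.intensities, 0.0)

    def test_narrow_peak_survives(self):
        n = 500
        x = np.arange(n, dtype=float)
        y = 100.0 * np.exp(-0.5 * ((x - 250) / 3.0) ** 2)
        _, corr = snip_baseline(Spectrum("s", 4000 + x, y), iterations=50)
        assert corr.intensities.max() >= 0.95 * 100.0

    def test_linear_ramp_removed_off_peak(self):
        n = 1000
        x = np.arange(n, dtype=float)
        ramp = 1 + x / (n - 1) * 50.0  # amplitude 50
        peak = 80.0 * np.exp(-0.5 * ((x - 500) / 3.0) ** 2)
        base, corr = snip_baseline(Spectrum("s", 4000 + x, ramp + peak), iterations=50)
        off_peak = np.abs(x - 500) > 60
        assert corr.intensities[off_peak].max() < 0.01 * 50.0

    def test_baseline_never_exceeds_trace(self):
        rng = np.random.default_rng(1)
        y = np.abs(rng.normal(2, 1, 800))
        s = Spectrum("s", 4000 + np.arange(800.0), y)
        base, corr = snip_baseline(s)
        assert np.all(base <= y + 1e-12)
        assert np.all(corr.intensities >= 0)

    def test_bad_iterations(self):
        with pytest.raises(ValueError):
            snip_baseline(flat(50), iterations=0)


class TestTic:
    def test_proportions(self):
        s = Spectrum("s", [1.0, 2, 3], [2.0, 3, 5])
        assert np.allclose(normalize_tic(s).intensities, [0.2, 0.3, 0.5])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_tic(flat(10, 0.0))

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        s = Spectrum("s", np.arange(50.0), rng.uniform(0, 9, 50))
        assert abs(normalize_tic(s).intensities.sum() - 1) < 1e-9


class TestSupersmootherNoise:
    def test_constant_reproduced(self):
        noise = estimate_noise_supersmoother(flat(300, 4.2))
        assert np.allclose(noise, 4.2, atol=1e-6)

    def test_iid_noise_tracks_mean(self):
        rng = np.random.default_rng(3)
        mu, sd, n = 5.0, 0.5, 2000
        s = Spectrum("s", 4000 + np.arange(float(n)), np.abs(rng.normal(mu, sd, n)))
        noise = estimate_noise_supersmoother(s)
        span = 0.05 * n
        assert np.all(np.abs(noise - mu) < 3 * sd / np.sqrt(span) + 0.1)

    def test_zero_spectrum_floored(self):
        noise = estimate_noise_supersmoother(flat(100, 0.0))
        assert np.all(noise >= np.finfo(float).eps)
        assert np.all(noise <= 1e-10)

    def test_too_short(self):
        with pytest.raises(ValueError):
            estimate_noise_supersmoother(flat(5))


class TestDetectPeaks:
    def test_single_spike_in_flat_noise(self):
        rng = np.random.default_rng(7)
        n, sigma = 2000, 0.1
        y = rng.uniform(0, sigma, n)
        y[1000] += 10 * sigma
        s = Spectrum("s", 4000 + np.arange(float(n)), y)
        peaks = detect_peaks(s, snr_threshold=3.0, half_window=20)
        assert len(peaks) == 1
        assert peaks.peak_masses[0] == 5000.0
        assert peaks.snr[0] >= 3.0

    def test_monotone_trace_has_no_peaks(self):
        s = Spectrum("s", np.arange(100.0), np.arange(100.0) + 1)
        assert len(detect_peaks(s)) == 0

    def test_close_spikes_keep_only_taller(self):
        y = np.full(200, 0.01)
        y[100] = 10.0
        y[105] = 8.0
        s = Spectrum("s", 4000 + np.arange(200.0), y)
        peaks = detect_peaks(s, half_window=20)
        assert len(peaks) == 1
        assert peaks.peak_masses[0] == 4100.0

    def test_peak_masses_strictly_increasing(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(0, 0.05, 3000)
        for pos in (300, 900, 1500, 2100, 2700):
            y[pos] += 5.0
        s = Spectrum("s", 4000 + np.arange(3000.0), y)
        peaks = detect_peaks(s)
        assert len(peaks) == 5
        assert np.all(np.diff(peaks.peak_masses) > 0)


def three_peak_spectrum(scale=1.0, seed=5):
    """Raw synthetic spectrum: 3 protein peaks in 4-10 kDa on a decaying
    baseline, grid 1 Da over 2-20 kDa."""
    rng = np.random.default_rng(seed)
    grid = np.arange(2000.0, 20001.0)
    trace = 2.0 * np.exp(-(grid - 2000) / 4000)
    for m0, h in ((5000, 40.0), (6500, 25.0), (8000, 50.0)):
        trace += h * np.exp(-0.5 * ((grid - m0) / 5.0) ** 2)
    trace = np.clip(trace + rng.normal(0, 0.02, grid.size), 0, None)
    return Spectrum("s", grid, trace * scale)


class TestPipeline:
    def test_three_peaks_recovered(self):
        trace, peaks = preprocess_pipeline(three_peak_spectrum())
        assert len(peaks) == 3
        assert np.allclose(peaks.peak_masses, [5000, 6500, 8000], atol=3)

    def test_tic_invariant(self):
        trace, _ = preprocess_pipeline(three_peak_spectrum())
        assert abs(trace.intensities.sum() - 1) < 1e-9
        assert np.all(trace.intensities >= 0)
        assert np.all((trace.masses >= 4000) & (trace.masses <= 10000))

    def test_out_of_window_spectrum_errors(self):
        s = Spectrum("s", np.arange(2000.0, 3000.0), np.ones(1000))
        with pytest.raises(ValueError):
            preprocess_pipeline(s)

    def test_deterministic(self):
        t1, p1 = preprocess_pipeline(three_peak_spectrum())
        t2, p2 = preprocess_pipeline(three_peak_spectrum())
        assert np.array_equal(t1.intensities, t2.intensities)
        assert np.array_equal(p1.peak_masses, p2.peak_masses)

    def test_intensity_scale_invariance(self):
        t1, p1 = preprocess_pipeline(three_peak_spectrum(scale=1.0))
        t2, p2 = preprocess_pipeline(three_peak_spectrum(scale=7.3))
        assert np.allclose(t1.intensities, t2.intensities, atol=1e-12)
        assert np.array_equal(p1.peak_masses, p2.peak_masses)

    def test_equals_step_composition(self):
        params = PreprocessParams()
        raw = three_peak_spectrum()
        trace, peaks = preprocess_pipeline(raw, params)
        s = sqrt_transform(raw)
        s = trim(s, params.mass_low, params.mass_high)
        s = smooth_savitzky_golay(s, params.sg_half_window, params.sg_order)
        _, s = snip_baseline(s, params.snip_iterations)
        s = normalize_tic(s)
        manual_peaks = detect_peaks(s, params.snr, params.peak_half_window)
        assert np.array_equal(trace.intensities, s.intensities)
        assert np.array_equal(peaks.peak_masses, manual_peaks.peak_masses)
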
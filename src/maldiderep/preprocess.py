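"""Spectral preprocessing for whole-cell MALDI-TOF profiles.

The chain, applied in this fixed order, mirrors standard linear-mode
practice for protein fingerprints:

1. square-root intensity transformation (variance stabilisation),
2. mass-range trimming (default 4-10 kDa, the range populated with
   stable, species-informative protein signals),
3. Savitzky-Golay smoothing (half-window 20 points, cubic),
4. SNIP baseline estimation and subtraction (50 clipping iterations),
5. total-ion-current normalisation (intensities sum to 1),
6. peak detection: strict local maxima over a 41-point window with
   signal-to-noise >= 3 against a supersmoother noise estimate.

Because step 1 is followed by TIC normalisation, the whole chain is
invariant to rescaling the raw intensities by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import Spectrum

__all__ = [
    "PreprocessedSpectrum",
    "PeakList",
    "PreprocessParams",
    "sqrt_transform",
    "trim",
    "smooth_savitzky_golay",
    "snip_baseline",
    "normalize_tic",
    "estimate_noise_supersmoother",
    "detect_peaks",
    "preprocess_pipeline",
]


@dataclass
class PreprocessedSpectrum:
    """Continuous trace after steps 1-5; used for feature back-filling."""

    sample_id: str
    masses: np.ndarray
    intensities: np.ndarray
    mass_window: tuple[float, float]

    def interpolate(self, masses: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary masses in-window."""
        masses = np.atleast_1d(np.asarray(masses, dtype=float))
        lo, hi = self.mass_window
        if np.any((masses < lo) | (masses > hi)):
            raise ValueError("requested mass outside the spectrum's mass window")
        return np.interp(masses, self.masses, self.intensities)


@dataclass
class PeakList:
    """Detected peaks for one spectrum (masses strictly increasing)."""

    sample_id: str
    peak_masses: np.ndarray
    peak_intensities: np.ndarray
    snr: np.ndarray

    def __len__(self) -> int:
        return int(self.peak_masses.size)


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable knobs of the chain with their conventional defaults."""

    mass_low: float = 4000.0
    mass_high: float = 10000.0
    sg_half_window: int = 20
    sg_order: int = 3
    snip_iterations: int = 50
    snr: float = 3.0
    peak_half_window: int = 20


def sqrt_transform(spectrum: Spectrum) -> Spectrum:
    """Square-root each intensity (stabilises shot-noise-like variance)."""
    if np.any(spectrum.intensities < 0):
        raise ValueError("negative intensities")
    return spectrum.replace_intensities(np.sqrt(spectrum.intensities))


def trim(spectrum: Spectrum, low: float, high: float) -> Spectrum:
    """Keep points with low <= mass <= high (both ends inclusive)."""
    if low >= high:
        raise ValueError("trim window requires low < high")
    keep = (spectrum.masses >= low) & (spectrum.masses <= high)
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 points remain in [{low}, {high}] for {spectrum.sample_id!r}"
        )
    return Spectrum(spectrum.sample_id, spectrum.masses[keep], spectrum.intensities[keep])


def smooth_savitzky_golay(
    spectrum: Spectrum, half_window: int = 20, poly_order: int = 3
) -> Spectrum:
    """Savitzky-Golay least-squares smoothing over 2*half_window+1 points.

    The filter operates on the index domain; for the (nearly) uniform mass
    grids produced by linear-TOF exports this is equivalent to operating in
    Da. Negative filter outputs are clipped to zero.
    """
    n = len(spectrum)
    window = 2 * half_window + 1
    if n <= 2 * half_window:
        raise ValueError(f"spectrum length {n} too short for window {window}")
    smoothed = savgol_filter(spectrum.intensities, window_length=window, polyorder=poly_order)
    return spectrum.replace_intensities(np.clip(smoothed, 0.0, None))


def snip_baseline(spectrum: Spectrum, iterations: int = 50) -> tuple[np.ndarray, Spectrum]:
    """SNIP baseline estimation (decreasing clipping-window sweep).

    At sweep width k every interior point is replaced by
    ``min(y[i], (y[i-k] + y[i+k]) / 2)``; k runs from ``iterations`` down
    to 1. Each step can only lower the trace, so the baseline never
    exceeds the input and the corrected spectrum is non-negative.

    Returns ``(baseline, corrected)``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if np.any(spectrum.intensities < 0):
        raise ValueError("negative intensities")
    y = spectrum.intensities.copy()
    n = y.size
    for k in range(min(iterations, n - 1), 0, -1):
        mid = 0.5 * (y[: n - 2 * k] + y[2 * k :])
        y[k : n - k] = np.minimum(y[k : n - k], mid)
    corrected = np.clip(spectrum.intensities - y, 0.0, None)
    return y, spectrum.replace_intensities(corrected)


def normalize_tic(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the total ion current (their sum) equals 1."""
    total = float(spectrum.intensities.sum())
    if total <= 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    return spectrum.replace_intensities(spectrum.intensities / total)


def _running_linear(y: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Running least-squares line fit on the index axis.

    Returns the fitted value and the regression leverage at each point,
    using a symmetric window of ``2*half+1`` points truncated at the edges.
    Cumulative sums keep this O(n) per span.
    """
    n = y.size
    idx = np.arange(n, dtype=float)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)  # inclusive

    def winsum(v: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(v)))
        return c[hi + 1] - c[lo]

    m = (hi - lo + 1).astype(float)
    sx = winsum(idx)
    sy = winsum(y)
    sxx = winsum(idx * idx)
    sxy = winsum(idx * y)
    xbar = sx / m
    ybar = sy / m
    sxx_c = np.maximum(sxx - m * xbar * xbar, 1e-12)
    slope = (sxy - m * xbar * ybar) / sxx_c
    fit = ybar + slope * (idx - xbar)
    leverage = 1.0 / m + (idx - xbar) ** 2 / sxx_c
    return fit, np.clip(leverage, 0.0, 0.999)


def supersmoother(y: np.ndarray) -> np.ndarray:
    """Friedman-style variable-span smoother on an index grid.

    Three running-line smoothers (tweeter 5%, midrange 20%, woofer 50% of
    the trace) compete per point via smoothed leave-one-out absolute
    residuals; the locally best span wins, the winning values are blended
    and passed once more through the tweeter span. Constant input is
    reproduced exactly up to floating-point error.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 points")
    spans = [0.05, 0.2, 0.5]
    halves = [max(2, int(round(s * n / 2))) for s in spans]
    fits, cv = [], []
    for h in halves:
        fit, lev = _running_linear(y, h)
        fits.append(fit)
        cv.append(np.abs(y - fit) / np.maximum(1.0 - lev, 1e-3))
    mid_half = halves[1]
    cv_smooth = [_running_linear(c, mid_half)[0] for c in cv]
    cv_arr = np.vstack(cv_smooth)
    best = np.argmin(cv_arr, axis=0)
    chosen = np.choose(best, fits)
    # final pass with the tweeter span removes the span-switching seams
    out = _running_linear(chosen, halves[0])[0]
    return out


def estimate_noise_supersmoother(spectrum: Spectrum) -> np.ndarray:
    """Local noise level: supersmoother fit of the intensity trace.

    The smooth fit tracks the typical local intensity, so isolated sharp
    peaks rise far above it; the ratio intensity/noise is the SNR used by
    :func:`detect_peaks`. Floored at machine epsilon so the ratio is
    always defined.
    """
    if len(spectrum) < 10:
        raise ValueError("need at least 10 points for noise estimation")
    noise = supersmoother(spectrum.intensities)
    return np.maximum(noise, np.finfo(float).eps)


def detect_peaks(
    spectrum: Spectrum, snr_threshold: float = 3.0, half_window: int = 20
) -> PeakList:
    """Strict windowed local maxima with SNR >= threshold.

    A point qualifies iff it is the unique maximum of the
    ``2*half_window+1`` window centred on it and its intensity is at least
    ``snr_threshold`` times the local supersmoother noise level. Boundary
    points, where the window does not fit, are never peaks.
    """
    y = spectrum.intensities
    n = y.size
    if n < 2 * half_window + 1 or n < 10:
        return PeakList(spectrum.sample_id, np.empty(0), np.empty(0), np.empty(0))
    noise = estimate_noise_supersmoother(spectrum)

    # sliding-window maximum via stride tricks
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(y, 2 * half_window + 1)
    centers = np.arange(half_window, n - half_window)
    center_vals = y[centers]
    is_max = center_vals >= win.max(axis=1)
    # strictness: the centre value must occur exactly once in its window
    strict = (win == center_vals[:, None]).sum(axis=1) == 1
    snr = center_vals / noise[centers]
    keep = is_max & strict & (snr >= snr_threshold) & (center_vals > 0)
    idx = centers[keep]
    return PeakList(spectrum.sample_id, spectrum.masses[idx], y[idx], snr[keep])


def preprocess_pipeline(
    spectrum: Spectrum, params: PreprocessParams = PreprocessParams()
) -> tuple[PreprocessedSpectrum, PeakList]:
    """Run the full chain in order and return (trace, peaks)."""
    s = sqrt_transform(spectrum)
    s = trim(s, params.mass_low, params.mass_high)
    s = smooth_savitzky_golay(s, params.sg_half_window, params.sg_order)
    _, s = snip_baseline(s, params.snip_iterations)
    s = normalize_tic(s)
    peaks = detect_peaks(s, params.snr, params.peak_half_window)
    trace = PreprocessedSpectrum(
        s.sample_id, s.masses, s.intensities, (params.mass_low, params.mass_high)
    )
    return trace, peaks
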
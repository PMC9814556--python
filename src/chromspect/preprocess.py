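"""Signal conditioning: absorbance conversion, grid harmonisation,
smoothing, differentiation, channel extraction and peak detection.

Reference spectra arrive from heterogeneous sources, so before any
comparison they are linearly interpolated onto a common wavelength grid,
smoothed with a Savitzky–Golay filter (polynomial order 5, half-window
4.5 nm) and differentiated once to cancel constant baseline offsets.
Chromatographic detection works on single-wavelength channels averaged
over a ±2 nm window around the monitoring wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .io import ReferenceSpectrum, SpectralChromatogram, ValidationError

__all__ = [
    "ChannelChromatogram",
    "Peak",
    "compute_absorbance",
    "resample_to_grid",
    "savgol_window_length",
    "savgol_smooth",
    "first_derivative",
    "extract_channel",
    "detect_peaks",
    "robust_noise_sd",
]


@dataclass
class ChannelChromatogram:
    """Absorbance vs time at one monitoring wavelength (±half_window nm)."""

    time: np.ndarray
    absorbance: np.ndarray
    center_wavelength: float
    half_window: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.absorbance = np.asarray(self.absorbance, dtype=float).ravel()
        if self.time.size != self.absorbance.size:
            raise ValidationError("time/absorbance length mismatch")
        if self.half_window < 0:
            raise ValidationError("half_window must be >= 0")

    def crop(self, t_start: float, t_end: float) -> "ChannelChromatogram":
        mask = (self.time >= t_start) & (self.time <= t_end)
        return ChannelChromatogram(
            self.time[mask], self.absorbance[mask], self.center_wavelength, self.half_window
        )


@dataclass
class Peak:
    """A detected chromatographic peak with 10%-of-apex flank times.

    ``rise_time_10pct`` / ``trail_time_10pct`` are the times at which the
    baseline-subtracted signal falls to 10% of the baseline-subtracted
    apex height, found by walking outward from the apex.
    """

    apex_time: float
    apex_absorbance: float
    rise_time_10pct: float
    trail_time_10pct: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.rise_time_10pct < self.apex_time < self.trail_time_10pct):
            raise ValidationError("flank times must bracket the apex")

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.rise_time_10pct <= other.trail_time_10pct
            and other.rise_time_10pct <= self.trail_time_10pct
        )


def compute_absorbance(
    sample_intensity: np.ndarray,
    reference_intensity: np.ndarray,
    dark: np.ndarray | float = 0.0,
    a_max: float = 4.0,
) -> np.ndarray:
    """Absorbance A = -log10((I - dark) / (I0 - dark)).

    Channels where the dark-corrected sample intensity is <= 0 are clipped
    to ``a_max`` (detector floor); a blank that does not exceed the dark
    signal is an error.
    """
    i = np.asarray(sample_intensity, dtype=float)
    i0 = np.asarray(reference_intensity, dtype=float)
    d = np.broadcast_to(np.asarray(dark, dtype=float), i.shape)
    if i.shape != i0.shape:
        raise ValidationError("intensity vectors must have the same shape")
    denom = i0 - d
    if np.any(denom <= 0):
        raise ValidationError("invalid blank: reference intensity <= dark signal")
    num = i - d
    with np.errstate(divide="ignore", invalid="ignore"):
        a = -np.log10(num / denom)
    a = np.where(num <= 0, a_max, a)
    return np.minimum(a, a_max)


def resample_to_grid(spectrum: ReferenceSpectrum, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a spectrum onto ``grid`` (nm).

    Returns ``(values, valid)`` where ``valid`` flags grid points inside
    the spectrum's support; points outside are NaN and must be excluded
    from downstream feature vectors rather than zero-filled.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.support
    valid = (grid >= lo) & (grid <= hi)
    if not valid.any():
        raise ValidationError(
            f"grid [{grid.min():g}, {grid.max():g}] nm does not overlap "
            f"spectrum support [{lo:g}, {hi:g}] nm"
        )
    values = np.full(grid.shape, np.nan)
    values[valid] = np.interp(grid[valid], spectrum.wavelength, spectrum.absorbance)
    return values, valid


def savgol_window_length(grid_step: float, half_window_nm: float) -> int:
    """Odd filter length in samples covering ±half_window_nm."""
    return 2 * int(round(half_window_nm / grid_step)) + 1


def savgol_smooth(
    values: np.ndarray,
    grid_step: float,
    poly_order: int = 5,
    half_window_nm: float = 4.5,
) -> np.ndarray:
    """Savitzky–Golay smoothing (order 5, window ±4.5 nm by default)."""
    values = np.asarray(values, dtype=float)
    wl = savgol_window_length(grid_step, half_window_nm)
    if wl <= poly_order:
        min_span = (poly_order + 1) * grid_step / 2.0
        raise ValidationError(
            f"window ±{half_window_nm} nm too small for order {poly_order}; "
            f"needs at least ±{min_span:g} nm at {grid_step:g} nm spacing"
        )
    if values.size < wl:
        raise ValidationError(f"need at least {wl} samples for the smoothing window")
    return savgol_filter(values, window_length=wl, polyorder=poly_order, mode="interp")


def first_derivative(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Central-difference first derivative (one-sided at the ends), AU/nm.

    Removes any constant baseline offset: d/dλ (s + c) = d/dλ s.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 3:
        raise ValidationError("need at least 3 samples to differentiate")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing")
    return np.gradient(values, grid)


def extract_channel(
    chrom: SpectralChromatogram, center_nm: float, half_window_nm: float = 2.0
) -> ChannelChromatogram:
    """Mean absorbance over wavelengths in [center − hw, center + hw].

    The mean (not the sum) keeps the scale comparable across window
    widths. ``half_window_nm=0`` selects the single nearest on-grid
    wavelength only if it matches exactly.
    """
    wl = chrom.wavelength
    mask = (wl >= center_nm - half_window_nm) & (wl <= center_nm + half_window_nm)
    if not mask.any():
        raise ValidationError(
            f"no wavelengths within {center_nm}±{half_window_nm} nm "
            f"(axis spans {wl[0]:g}–{wl[-1]:g} nm)"
        )
    values = chrom.absorbance[:, mask].mean(axis=1)
    return ChannelChromatogram(chrom.time.copy(), values, center_nm, half_window_nm)


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise sd as 1.4826 × MAD of the difference-detrended signal.

    Second differences remove any smooth trend — including the
    chromatographic peaks themselves, whose curvature contributes only
    O(dt²) — so the median absolute deviation reflects the noise even on
    peak-dense traces; the √6 accounts for the variance of the second
    difference of white noise.
    """
    values = np.asarray(values, dtype=float)
    d = np.diff(values, n=2)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(6.0))


def _walk_to_fraction(
    time: np.ndarray, signal: np.ndarray, apex_idx: int, target: float, direction: int
) -> float:
    """Walk outward from the apex to the first crossing of ``target``.

    Linear interpolation between the bracketing samples; falls back to
    the trace edge (nudged outward by half a sample so flank times always
    strictly bracket the apex) when the signal never reaches the target.
    """
    i = apex_idx
    n = signal.size
    while 0 <= i + direction < n:
        j = i + direction
        if signal[j] <= target:
            # crossing between i and j
            if signal[i] == signal[j]:
                return float(time[j])
            frac = (signal[i] - target) / (signal[i] - signal[j])
            return float(time[i] + frac * (time[j] - time[i]))
        i = j
    dt = float(np.mean(np.diff(time))) if n > 1 else 1.0
    return float(time[i] + direction * 0.5 * dt)


def detect_peaks(
    channel: ChannelChromatogram,
    min_snr: float = 8.0,
    min_separation_min: float = 0.1,
) -> list[Peak]:
    """Detect local maxima with SNR and separation thresholds.

    The baseline is the median of the lowest decile of the channel; apex
    height and the 10% flank rule are applied to baseline-subtracted
    absorbance, making detection invariant to constant offsets. Noise sd
    is 1.4826 × MAD of the detrended signal. Returns an empty list when
    nothing clears the threshold.
    """
    t = channel.time
    y = channel.absorbance
    if t.size < 10:
        raise ValidationError("need at least 10 time points for peak detection")
    noise = robust_noise_sd(y)
    anchor = float(np.quantile(y, 0.1))
    base_samples = y[y <= anchor + 4.0 * noise]
    baseline = float(np.median(base_samples)) if base_samples.size else anchor
    s = y - baseline
    dt = float(np.mean(np.diff(t)))
    distance = max(1, int(round(min_separation_min / dt)))
    # prominence gate rejects noise wiggles riding on a real peak's flank,
    # which would otherwise pass the apex-height SNR test
    prominence = min_snr * noise if noise > 0 else None
    idx, _ = find_peaks(s, distance=distance, prominence=prominence)
    peaks: list[Peak] = []
    for i in idx:
        height = s[i]
        snr = height / noise if noise > 0 else np.inf
        if snr < min_snr:
            continue
        target = 0.1 * height
        rise = _walk_to_fraction(t, s, i, target, -1)
        trail = _walk_to_fraction(t, s, i, target, +1)
        peaks.append(
            Peak(
                apex_time=float(t[i]),
                apex_absorbance=float(y[i]),
                rise_time_10pct=rise,
                trail_time_10pct=trail,
                snr=float(snr),
            )
        )
    return peaks
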
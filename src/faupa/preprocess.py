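"""Preprocessing: smoothing, bandpass, percent signal change.

Pipeline order is smooth -> bandpass -> percent change.  The bandpass is a
discrete-Fourier frequency mask (zero phase, idempotent); the percent
conversion divides by the pre-bandpass temporal mean, since the bandpassed
series itself has mean ~0 and could not serve as a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

DEFAULT_BAND_HZ = (0.009, 0.08)
DEFAULT_FWHM_MM = 4.0
DEFAULT_MASK_FRACTION = 0.3


@dataclass
class PercentChangeImage:
    """Bandpassed relative-signal-change (%) series inside a brain mask.

    Out-of-mask voxels hold NaN so they can never silently enter statistics.
    """

    data: np.ndarray  # (x, y, z, t), percent units, NaN outside mask
    mask: np.ndarray  # 3D bool
    tr_s: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def series(self, voxel: tuple[int, int, int]) -> np.ndarray:
        if not self.mask[voxel]:
            raise ValueError(f"voxel {voxel} is outside the mask")
        return self.data[voxel]


def make_mask(image4d: np.ndarray, threshold_fraction: float = DEFAULT_MASK_FRACTION) -> np.ndarray:
    """Intensity mask: temporal mean >= fraction of the robust (99th
    percentile) maximum of the temporal-mean volume."""
    image4d = np.asarray(image4d, dtype=float)
    tmean = image4d.mean(axis=-1)
    robust_max = np.percentile(tmean, 99)
    if robust_max <= 0:
        raise ValueError("image appears to be empty (non-positive robust maximum)")
    mask = tmean >= threshold_fraction * robust_max
    if not mask.any():
        raise ValueError("mask is empty at this threshold fraction")
    return mask


def smooth(image4d: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 3.5) -> np.ndarray:
    """Volume-wise Gaussian smoothing; fwhm 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    image4d = np.asarray(image4d, dtype=float)
    if fwhm_mm == 0:
        return image4d.copy()
    sigma_vox = fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_size_mm)
    out = np.empty_like(image4d)
    for t in range(image4d.shape[-1]):
        out[..., t] = gaussian_filter(image4d[..., t], sigma=sigma_vox)
    return out


def bandpass(
    series: np.ndarray,
    tr_s: float,
    f_lo: float = DEFAULT_BAND_HZ[0],
    f_hi: float = DEFAULT_BAND_HZ[1],
    axis: int = -1,
) -> np.ndarray:
    """Frequency-mask bandpass along ``axis``.

    Keeps DFT bins with f_lo <= f <= f_hi, always removing DC; zero phase
    distortion and exactly idempotent.  Frequencies are validated against
    the Nyquist limit 1 / (2 TR).
    """
    series = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr_s
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"f_hi ({f_hi} Hz) exceeds Nyquist ({nyquist} Hz)")
    n = series.shape[axis]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    keep[0] = False  # DC always removed
    spec = np.fft.rfft(series, axis=axis)
    shape = [1] * series.ndim
    shape[axis] = len(freqs)
    spec *= keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def to_percent_change(image4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Relative signal change: 100 * (x - mean) / mean per in-mask voxel.

    Out-of-mask voxels are NaN.  Raises if any in-mask temporal mean is
    non-positive (percent change would be meaningless).
    """
    image4d = np.asarray(image4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    tmean = image4d.mean(axis=-1)
    if np.any(tmean[mask] <= 0):
        raise ValueError("non-positive temporal mean inside the mask")
    out = np.full(image4d.shape, np.nan)
    out[mask] = 100.0 * (image4d[mask] - tmean[mask, None]) / tmean[mask, None]
    return out


def preprocess(
    image4d: np.ndarray,
    tr_s: float,
    mask: np.ndarray | None = None,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    voxel_size_mm: float = 3.5,
    f_lo: float = DEFAULT_BAND_HZ[0],
    f_hi: float = DEFAULT_BAND_HZ[1],
    mask_fraction: float = DEFAULT_MASK_FRACTION,
) -> PercentChangeImage:
    """Full preprocessing chain: smooth, bandpass, percent change.

    The percent conversion uses the smoothed series' temporal mean as the
    denominator; the numerator is the bandpassed deviation (the bandpass
    already removes the mean), so each output series has mean ~0.
    """
    image4d = np.asarray(image4d, dtype=float)
    smoothed = smooth(image4d, fwhm_mm, voxel_size_mm)
    if mask is None:
        mask = make_mask(smoothed, mask_fraction)
    tmean = smoothed.mean(axis=-1)
    if np.any(tmean[mask] <= 0):
        raise ValueError("non-positive temporal mean inside the mask")
    bp = bandpass(smoothed[mask], tr_s, f_lo, f_hi, axis=-1)
    data = np.full(image4d.shape, np.nan)
    data[mask] = 100.0 * bp / tmean[mask, None]
    return PercentChangeImage(data=data, mask=mask, tr_s=tr_s)
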
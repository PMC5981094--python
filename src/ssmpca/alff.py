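"""Amplitude of Low Frequency Fluctuation (ALFF) from 4D BOLD series.

ALFF of a voxel is the mean single-sided spectral amplitude of its
(detrended) time course over a low-frequency band, conventionally
0.01–0.08 Hz.  The single-sided amplitude at DFT bin k is (2/T)·|X_k|
(DC and, for even T, the Nyquist bin are not doubled); band endpoints are
inclusive.  Amplitude maps are usually divided by their global (in-mask)
mean before any group analysis, which cancels the amplitude convention and
any global scanner gain.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from .imageio import BrainMask, VolumeImage

DEFAULT_BAND = (0.01, 0.08)


@dataclasses.dataclass
class BoldSeries:
    """4D BOLD data (grid × T) with repetition time in seconds."""

    data: np.ndarray
    tr: float
    mask: BrainMask | None = None
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD series must be 4D (x, y, z, t)")
        if self.data.shape[3] < 8:
            raise ValueError("BOLD series must have at least 8 timepoints")
        if not self.tr > 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclasses.dataclass
class AlffMap:
    """Voxelwise ALFF with the band it was computed over."""

    volume: VolumeImage
    band: tuple[float, float]
    normalized: bool = False
    n_bins: int | None = None


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel least-squares line (intercept + slope)."""
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to remove a linear trend")
    detrended = scipy.signal.detrend(series.data, axis=3, type="linear")
    return BoldSeries(detrended, tr=series.tr, mask=series.mask, affine=series.affine)


def band_bins(n_timepoints: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Indices k of DFT bins with f_low ≤ k/(T·tr) ≤ f_high."""
    f_low, f_high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < f_low <= f_high):
        raise ValueError(f"invalid band {band}: need 0 < f_low <= f_high")
    if f_high > nyquist + 1e-12:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {nyquist:g} Hz")
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    sel = np.flatnonzero((freqs >= f_low - 1e-12) & (freqs <= f_high + 1e-12))
    if sel.size == 0:
        raise ValueError(
            f"band {band} contains no DFT bins at T={n_timepoints}, tr={tr}"
        )
    return sel


def compute_alff(
    series: BoldSeries, band: tuple[float, float] = DEFAULT_BAND
) -> AlffMap:
    """Mean single-sided amplitude over the in-band DFT bins, per voxel."""
    T = series.n_timepoints
    sel = band_bins(T, series.tr, band)
    spectrum = np.fft.rfft(series.data, axis=3)
    amplitude = (2.0 / T) * np.abs(spectrum)
    amplitude[..., 0] /= 2.0  # DC is not doubled
    if T % 2 == 0:
        amplitude[..., -1] /= 2.0  # neither is Nyquist for even T
    alff = amplitude[..., sel].mean(axis=3)
    return AlffMap(
        volume=VolumeImage(alff, affine=series.affine),
        band=(float(band[0]), float(band[1])),
        normalized=False,
        n_bins=int(sel.size),
    )


def normalize_global_mean(alff: AlffMap, mask: BrainMask) -> AlffMap:
    """Divide the map by its mean over in-mask voxels (global-mean scaling)."""
    in_mask = mask.flatten(alff.volume)
    mean = float(in_mask.mean())
    if mean <= 0:
        raise ValueError(f"in-mask mean must be positive, got {mean:g}")
    return AlffMap(
        volume=VolumeImage(alff.volume.data / mean, affine=alff.volume.affine),
        band=alff.band,
        normalized=True,
        n_bins=alff.n_bins,
    )
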
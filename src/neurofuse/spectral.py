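"""ALFF and fALFF baseline feature maps from 4D resting-state time series.

ALFF (amplitude of low-frequency fluctuation) is the mean amplitude of a
voxel's spectrum within a low-frequency band, conventionally 0.01-0.08 Hz.
fALFF divides the band amplitude by the total amplitude from the lowest
positive frequency to Nyquist (DC excluded), giving a scale-free ratio in
[0, 1].  Each series is demeaned before the Fourier transform; because
the DC bin is excluded from every sum this leaves a pure sinusoid's
spectrum exact (one bin carries all its mass).  Least-squares linear
detrending is available as an option for data with scanner drift, at the
cost of a small leakage of any oscillatory signal across bins (the
fitted slope of a finite sampled sinusoid is not exactly zero).  No
whole-brain standardization is applied here; downstream min-max
normalization supersedes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .ivip import FeatureVolume
from .volumes import VolumeGrid

__all__ = [
    "TimeSeriesVolume",
    "FrequencyBand",
    "DEFAULT_BAND",
    "compute_alff",
    "compute_falff",
]


@dataclass
class TimeSeriesVolume:
    """4D resting-state data: one series of T samples per voxel."""

    grid: VolumeGrid
    values: np.ndarray  # (x, y, z, T)
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4 or self.values.shape[:3] != self.grid.dims:
            raise ValueError(
                f"time series shape {self.values.shape} incompatible with grid {self.grid.dims}"
            )
        if self.t < 8:
            raise ValueError(f"need at least 8 time points, got {self.t}")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")

    @property
    def t(self) -> int:
        return int(self.values.shape[-1])

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass(frozen=True)
class FrequencyBand:
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError(f"need 0 <= lo < hi, got [{self.lo_hz}, {self.hi_hz}]")

    def validate_for(self, ts: TimeSeriesVolume) -> None:
        if self.hi_hz > ts.nyquist_hz + 1e-12:
            raise ValueError(
                f"band upper edge {self.hi_hz} Hz exceeds Nyquist {ts.nyquist_hz} Hz"
            )


#: the standard low-frequency band of the ALFF literature
DEFAULT_BAND = FrequencyBand(0.01, 0.08)


def _amplitude_spectrum(ts: TimeSeriesVolume, detrend_method: str = "demean"
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum per voxel after demeaning/detrending.

    Returns (freqs, amp) with amp shaped (x, y, z, n_bins); DC is dropped.
    """
    if detrend_method == "demean":
        x = detrend(ts.values, axis=-1, type="constant")
    elif detrend_method == "linear":
        x = detrend(ts.values, axis=-1, type="linear")
    else:
        raise ValueError(f"detrend_method must be 'demean' or 'linear', got {detrend_method!r}")
    spec = np.fft.rfft(x, axis=-1)
    amp = np.abs(spec)
    freqs = np.fft.rfftfreq(ts.t, d=ts.tr_seconds)
    return freqs[1:], amp[..., 1:]


def _band_bins(freqs: np.ndarray, band: FrequencyBand) -> np.ndarray:
    # closed interval on bin centers
    return (freqs >= band.lo_hz - 1e-12) & (freqs <= band.hi_hz + 1e-12)


def compute_alff(ts: TimeSeriesVolume, band: FrequencyBand = DEFAULT_BAND,
                 detrend_method: str = "demean") -> FeatureVolume:
    """Mean spectral amplitude over the band bins, per voxel."""
    band.validate_for(ts)
    freqs, amp = _amplitude_spectrum(ts, detrend_method)
    in_band = _band_bins(freqs, band)
    if not in_band.any():
        raise ValueError(
            f"no FFT bin falls in [{band.lo_hz}, {band.hi_hz}] Hz for T={ts.t}, "
            f"TR={ts.tr_seconds}s"
        )
    values = amp[..., in_band].mean(axis=-1)
    return FeatureVolume(
        ts.grid, values, "alff", f"ALFF {band.lo_hz}-{band.hi_hz} Hz, T={ts.t}"
    )


def compute_falff(ts: TimeSeriesVolume, band: FrequencyBand = DEFAULT_BAND,
                  detrend_method: str = "demean") -> FeatureVolume:
    """Band amplitude as a fraction of total amplitude (DC excluded).

    0/0 (a flat series) is defined as 0.
    """
    band.validate_for(ts)
    freqs, amp = _amplitude_spectrum(ts, detrend_method)
    in_band = _band_bins(freqs, band)
    if not in_band.any():
        raise ValueError(
            f"no FFT bin falls in [{band.lo_hz}, {band.hi_hz}] Hz for T={ts.t}, "
            f"TR={ts.tr_seconds}s"
        )
    num = amp[..., in_band].sum(axis=-1)
    den = amp.sum(axis=-1)
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return FeatureVolume(
        ts.grid, values, "falff", f"fALFF {band.lo_hz}-{band.hi_hz} Hz, T={ts.t}"
    )
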
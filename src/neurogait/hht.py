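"""Hilbert-Huang spectral features.

Each IMF from :mod:`neurogait.emd` is lifted to its analytic signal
z(t) = imf(t) + j H[imf](t), giving instantaneous amplitude a(t) = |z|,
unwrapped phase phi(t) and pulsation omega(t) = dphi/dt.  The Hilbert
spectrum H(omega, t) deposits the squared amplitude of every mode at its
instantaneous frequency, on a 1-Hz grid spanning (0, 250] Hz — the same
resolution as the 1-s FFT, which keeps the three feature paths comparable.
Samples whose instantaneous frequency is non-positive (a known artifact of
riding waves in the Hilbert phase) are dropped and counted, not clamped.

Integrating H over the 1-s epoch yields the marginal spectrum h(omega)
(µV²·s); the per-band feature is the peak of h within the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import BandSet, ValidationError
from .emd import EmdParams, emd

__all__ = [
    "AnalyticMode",
    "TimeFrequencySpectrum",
    "MarginalSpectrum",
    "analytic_mode",
    "hilbert_spectrum",
    "marginal_spectrum",
    "band_peaks",
    "hht_band_features",
]

MAX_FREQ_HZ = 250.0
BIN_HZ = 1.0


@dataclass
class AnalyticMode:
    """Instantaneous amplitude (µV), unwrapped phase (rad) and pulsation (rad/s)."""

    amplitude: np.ndarray
    phase: np.ndarray
    pulsation: np.ndarray

    @property
    def frequency_hz(self) -> np.ndarray:
        return self.pulsation / (2.0 * np.pi)


@dataclass
class TimeFrequencySpectrum:
    """Energy grid H(omega, t): squared amplitude per frequency bin and sample.

    ``freqs_hz`` are bin centres; bin k covers [k - bin_hz/2, k + bin_hz/2).
    """

    grid: np.ndarray  # freq_bins x time_samples, µV²
    freqs_hz: np.ndarray
    dt_s: float
    n_dropped: int = 0  # samples discarded for non-positive instantaneous frequency


@dataclass
class MarginalSpectrum:
    """Time-integrated energy per frequency bin over one epoch (µV²·s)."""

    h: np.ndarray
    freqs_hz: np.ndarray


def analytic_mode(imf: np.ndarray, sample_rate: float) -> AnalyticMode:
    """Analytic-signal amplitude/phase/pulsation of one IMF."""
    imf = np.asarray(imf, dtype=float)
    if not np.all(np.isfinite(imf)):
        raise ValidationError("IMF contains non-finite samples")
    z = hilbert(imf)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    # central differences inside, one-sided at the edges
    pulsation = np.gradient(phase) * sample_rate
    return AnalyticMode(amplitude=amplitude, phase=phase, pulsation=pulsation)


def _freq_grid(bin_hz: float, max_freq_hz: float) -> np.ndarray:
    return np.arange(bin_hz, max_freq_hz + bin_hz / 2, bin_hz)


def hilbert_spectrum(
    modes: list[AnalyticMode],
    n_samples: int,
    sample_rate: float,
    *,
    bin_hz: float = BIN_HZ,
    max_freq_hz: float = MAX_FREQ_HZ,
) -> TimeFrequencySpectrum:
    """Accumulate per-mode squared amplitude on the shared time-frequency grid."""
    freqs = _freq_grid(bin_hz, max_freq_hz)
    grid = np.zeros((len(freqs), n_samples))
    dropped = 0
    for mode in modes:
        if len(mode.amplitude) != n_samples:
            raise ValidationError("all modes must share the epoch length")
        f = mode.frequency_hz
        bins = np.round(f / bin_hz).astype(int)  # bin centre k covers [k-.5, k+.5)
        valid = (f > 0) & (bins >= 1) & (bins <= len(freqs))
        dropped += int(np.sum(~valid))
        t_idx = np.nonzero(valid)[0]
        np.add.at(grid, (bins[valid] - 1, t_idx), mode.amplitude[valid] ** 2)
    return TimeFrequencySpectrum(grid=grid, freqs_hz=freqs, dt_s=1.0 / sample_rate, n_dropped=dropped)


def marginal_spectrum(spectrum: TimeFrequencySpectrum) -> MarginalSpectrum:
    """h(omega) = integral of H(omega, t) over the epoch (rectangle rule)."""
    return MarginalSpectrum(h=spectrum.grid.sum(axis=1) * spectrum.dt_s, freqs_hz=spectrum.freqs_hz)


def band_peaks(marginal: MarginalSpectrum, bands: BandSet) -> np.ndarray:
    """Peak of h(omega) within each half-open band [lo, hi)."""
    out = np.zeros(len(bands))
    for b, (lo, hi) in enumerate(bands):
        sel = (marginal.freqs_hz >= lo) & (marginal.freqs_hz < hi)
        if np.any(sel):
            out[b] = marginal.h[sel].max()
    return out


def hht_band_features(
    epoch: np.ndarray,
    sample_rate: float,
    bands: BandSet = BandSet(),
    params: EmdParams = EmdParams(),
) -> np.ndarray:
    """Full HHT path per channel: EMD -> analytic modes -> H -> h -> band peaks.

    Channels whose decomposition yields no IMF (e.g. a flat signal) report
    zero features.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_ch, n_samples = epoch.shape
    out = np.zeros((n_ch, len(bands)))
    for c in range(n_ch):
        imf_set = emd(epoch[c], params)
        if not imf_set.imfs:
            continue
        modes = [analytic_mode(m, sample_rate) for m in imf_set.imfs]
        H = hilbert_spectrum(modes, n_samples, sample_rate)
        out[c] = band_peaks(marginal_spectrum(H), bands)
    return out
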
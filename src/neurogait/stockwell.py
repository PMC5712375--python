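"""Discrete Stockwell transform (S-transform) and its band features.

The S-transform is a Fourier analysis with a frequency-scaled Gaussian
window: the voice at frequency f is

    S(tau, f) = int x(t) (|f| / sqrt(2 pi)) exp(-(tau - t)^2 f^2 / 2)
                exp(-j 2 pi f t) dt,

so window width shrinks as 1/f — time resolution improves and frequency
resolution degrades with increasing frequency.  Its defining property is
that summing a voice over tau collapses to the Fourier coefficient of the
input at that frequency.

The discrete transform is computed in the spectral domain (the standard
fast algorithm): the voice at DFT bin n > 0 is the inverse DFT over m of
X[m + n] * exp(-2 pi^2 m^2 / n^2), with X the DFT of the input and m the
signed bin offset; the n = 0 voice is the signal mean.  For 1-s epochs at
500 Hz the voices land exactly on the shared 1-Hz analysis grid.

Features follow the same recipe as the Hilbert-Huang path: squared voice
amplitude forms H(omega, t), the 1-s time integral gives the marginal
spectrum h(omega), and the per-band feature is the peak of h in the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BandSet, ValidationError
from .hht import (
    BIN_HZ,
    MAX_FREQ_HZ,
    TimeFrequencySpectrum,
    band_peaks,
    marginal_spectrum,
)

__all__ = ["STVoices", "stockwell_transform", "st_energy_spectrum", "st_band_features"]


@dataclass
class STVoices:
    """Complex voices S[voice, tau]; row v corresponds to ``freqs_hz[v]``."""

    S: np.ndarray  # (n_voices, n_samples) complex, voice 0 = DC (signal mean)
    freqs_hz: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.S)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.S)


def stockwell_transform(
    x: np.ndarray, sample_rate: float, *, max_freq_hz: float | None = None
) -> STVoices:
    """All voices at DFT bins 0..N/2 (optionally capped at ``max_freq_hz``)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("stockwell_transform expects a 1-D signal")
    n = len(x)
    if n < 4:
        raise ValidationError(f"signal too short for the S-transform: {n} samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")
    n_max = n // 2
    if max_freq_hz is not None:
        n_max = min(n_max, int(np.floor(max_freq_hz * n / sample_rate)))
    X = np.fft.fft(x)
    m = np.fft.fftfreq(n, d=1.0 / n)  # signed DFT bin offsets
    voices = np.arange(1, n_max + 1)
    # shifted spectra X[(m + n_voice) mod N] for all voices at once
    idx = (np.arange(n)[None, :] + voices[:, None]) % n
    gauss = np.exp(-2.0 * np.pi**2 * m[None, :] ** 2 / voices[:, None] ** 2)
    S = np.fft.ifft(X[idx] * gauss, axis=1)
    dc = np.full(n, x.mean(), dtype=complex)
    return STVoices(
        S=np.vstack([dc[None, :], S]),
        freqs_hz=np.concatenate([[0.0], voices * sample_rate / n]),
    )


def st_energy_spectrum(
    voices: STVoices,
    sample_rate: float,
    *,
    bin_hz: float = BIN_HZ,
    max_freq_hz: float = MAX_FREQ_HZ,
) -> TimeFrequencySpectrum:
    """Squared voice amplitude mapped onto the shared 1-Hz grid (DC excluded)."""
    freqs = np.arange(bin_hz, max_freq_hz + bin_hz / 2, bin_hz)
    n_samples = voices.S.shape[1]
    grid = np.zeros((len(freqs), n_samples))
    bins = np.round(voices.freqs_hz / bin_hz).astype(int)
    energy = np.abs(voices.S) ** 2
    sel = np.arange(voices.S.shape[0]) >= 1  # skip the DC voice
    sel &= (bins >= 1) & (bins <= len(freqs))
    np.add.at(grid, bins[sel] - 1, energy[sel])
    return TimeFrequencySpectrum(grid=grid, freqs_hz=freqs, dt_s=1.0 / sample_rate)


def st_band_features(
    epoch: np.ndarray,
    sample_rate: float,
    bands: BandSet = BandSet(),
) -> np.ndarray:
    """Full S-transform path per channel; returns ``channels x bands``."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    out = np.zeros((epoch.shape[0], len(bands)))
    hi = max(h for _, h in bands)
    for c in range(epoch.shape[0]):
        voices = stockwell_transform(epoch[c], sample_rate, max_freq_hz=hi)
        H = st_energy_spectrum(voices, sample_rate)
        out[c] = band_peaks(marginal_spectrum(H), bands)
    return out
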
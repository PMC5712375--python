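"""Per-epoch harmonic band content via the DFT.

For a 1-s, 500-sample epoch the DFT bins fall on integer frequencies, so a
band [lo, hi) simply collects bins lo..hi-1.  The per-bin statistic is the
one-sided power (2/N^2)|X_k|^2 in µV², which assigns a unit-amplitude
sinusoid its mean-square power of 0.5; the band feature is the sum over the
band's bins ("power", default) or the largest single bin ("peak", for
parity with the peak-picking used by the time-frequency methods).
No taper is applied (rectangular window).
"""

from __future__ import annotations

import numpy as np

from .core import BandSet, ValidationError

__all__ = ["fft_band_features", "one_sided_power"]


def one_sided_power(epoch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum per channel.

    Returns ``(freqs_hz, power)`` with ``power[c, k]`` in µV² such that the
    sum over all bins equals the per-channel mean square (Parseval).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if not np.all(np.isfinite(epoch)):
        raise ValidationError("epoch contains non-finite samples")
    n = epoch.shape[1]
    X = np.fft.rfft(epoch, axis=1)
    p = (2.0 / n**2) * np.abs(X) ** 2
    p[:, 0] /= 2.0  # DC is not mirrored
    if n % 2 == 0:
        p[:, -1] /= 2.0  # neither is the Nyquist bin
    return np.arange(X.shape[1], dtype=float), p


def fft_band_features(
    epoch: np.ndarray,
    sample_rate: float,
    bands: BandSet = BandSet(),
    mode: str = "power",
) -> np.ndarray:
    """Band features for one epoch; returns ``channels x bands`` (µV²)."""
    if mode not in ("power", "peak"):
        raise ValidationError(f"fft feature mode must be 'power' or 'peak', got {mode!r}")
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = epoch.shape[1]
    bin_idx, p = one_sided_power(epoch)
    freqs = bin_idx * sample_rate / n
    out = np.zeros((epoch.shape[0], len(bands)))
    for b, (lo, hi) in enumerate(bands):
        sel = (freqs >= lo) & (freqs < hi)
        if not np.any(sel):
            continue
        out[:, b] = p[:, sel].sum(axis=1) if mode == "power" else p[:, sel].max(axis=1)
    return out
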
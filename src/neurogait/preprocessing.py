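"""Spatial and frequency preprocessing.

The spatial filter is a distance-weighted surface Laplacian: each channel
has the inverse-distance weighted average of every other channel subtracted,

    V_i^Lp = V_i - sum_{j != i} g_ij V_j,   g_ij = (1/d_ij) / sum_{k != i} 1/d_ik,

with d_ij the 3-D Euclidean distance between electrodes on the unit sphere.
It is applied over the full recorded montage before any channel subsetting,
so the subtraction sees every recorded neighbour.

The optional 4th-order, 0.2 Hz Butterworth high-pass removes the DC drift
that would otherwise dominate low FFT bins; the Hilbert-Huang and Stockwell
paths operate on instantaneous amplitude and skip it.  The filter is applied
zero-phase (forward-backward) over the whole trial so heavily overlapping
1-s epochs see no group-delay misalignment against the event labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import DegenerateGeometryError, ElectrodeLayout, Trial, ValidationError

__all__ = [
    "LaplacianWeights",
    "FilterSpec",
    "laplacian_weights",
    "laplacian_filter",
    "butterworth_highpass",
    "select_channels",
]


@dataclass
class LaplacianWeights:
    """Inverse-distance weight matrix g (zero diagonal, rows sum to 1)."""

    g: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        if self.g.shape != (n, n):
            raise ValidationError("weight matrix shape must match channel count")
        if np.any(np.abs(np.diag(self.g)) > 0):
            raise ValidationError("weight matrix diagonal must be zero")
        if not np.allclose(self.g.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each weight row must sum to 1")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth high-pass specification (defaults: order 4, 0.2 Hz)."""

    order: int = 4
    cutoff_hz: float = 0.2
    kind: str = "highpass"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValidationError("cutoff must be > 0")
        if self.kind != "highpass":
            raise ValidationError("only high-pass filtering is supported")


def laplacian_weights(
    layout: ElectrodeLayout, names: Sequence[str] | None = None
) -> LaplacianWeights:
    """Inverse-distance Laplacian weights over ``names`` (default: all)."""
    names = list(names) if names is not None else list(layout.names)
    if len(names) < 2:
        raise ValidationError("Laplacian needs at least 2 electrodes")
    d = layout.distance_matrix(names)
    off = ~np.eye(len(names), dtype=bool)
    if np.any(d[off] <= 0):
        raise DegenerateGeometryError("coincident electrodes: zero inter-electrode distance")
    inv = np.zeros_like(d)
    inv[off] = 1.0 / d[off]
    g = inv / inv.sum(axis=1, keepdims=True)
    return LaplacianWeights(g=g, channel_names=names)


def laplacian_filter(trial: Trial, weights: LaplacianWeights) -> Trial:
    """Apply the surface Laplacian per sample; events pass through unchanged."""
    if trial.channel_names != weights.channel_names:
        raise ValidationError(
            "trial channels do not match Laplacian weights "
            f"({trial.channel_names[:3]}... vs {weights.channel_names[:3]}...)"
        )
    out = trial.data - weights.g @ trial.data
    return trial.with_data(out)


def butterworth_highpass(trial: Trial, spec: FilterSpec = FilterSpec()) -> Trial:
    """Zero-phase Butterworth high-pass over the whole trial."""
    nyq = trial.sample_rate / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValidationError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz")
    min_len = 3 * (2 * spec.order + 1)  # sosfiltfilt padding requirement
    if trial.n_samples < min_len:
        raise ValidationError(
            f"trial too short to filter: {trial.n_samples} samples < {min_len}"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=trial.sample_rate, output="sos")
    # the default reflect-padding is far shorter than the ~1/cutoff settling
    # time of a 0.2 Hz filter; extend it so edge transients stay at the edges
    padlen = int(min(trial.n_samples - 1, round(3 * trial.sample_rate / spec.cutoff_hz)))
    out = sps.sosfiltfilt(sos, trial.data, axis=1, padlen=padlen)
    return trial.with_data(out)


def select_channels(trial: Trial, names: Sequence[str]) -> Trial:
    """Subset/reorder channels by name (after spatial filtering)."""
    names = list(names)
    unknown = [n for n in names if n not in trial.channel_names]
    if unknown:
        raise ValidationError(f"unknown channels: {unknown}")
    idx = [trial.channel_names.index(n) for n in names]
    return trial.with_data(trial.data[idx], channel_names=names)
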
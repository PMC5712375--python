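"""Empirical Mode Decomposition by envelope sifting.

The signal is repeatedly split into a fast oscillation (an Intrinsic Mode
Function, IMF) and a remainder.  Each sifting pass fits natural cubic
splines through the local maxima and minima to form upper and lower
envelopes e+(t), e-(t), subtracts the local mean m = (e+ + e-)/2, and
repeats on the proto-mode p = x - m until it qualifies as an IMF.

Stopping follows the amplitude-ratio criterion of Rilling and co-workers:
with sigma(t) = |m(t)| / a(t), a = (e+ - e-)/2 the envelope amplitude, a
pass qualifies when sigma < theta1 on at least a fraction (1 - alpha) of
samples and sigma < theta2 everywhere, and the extrema and zero-crossing
counts differ by at most one.  To avoid accepting accidental modes the
conditions must hold on ``confirm_iters`` (default 3) consecutive passes.
Defaults theta1 = 0.05, theta2 = 0.5, alpha = 0.05 are the values in common
use for this criterion.

End effects are mitigated by mirroring the two extrema nearest each edge
across the signal boundary before the spline fit.  Extraction stops when
the residue has fewer than two extrema of either kind (monotone residue) or
``max_imfs`` modes have been pulled out.  By construction the IMFs plus the
residue always sum back to the input exactly (to float round-off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import ValidationError

__all__ = ["EmdParams", "IMFSet", "emd", "orthogonality_index"]


@dataclass(frozen=True)
class EmdParams:
    theta1: float = 0.05
    theta2: float = 0.5
    alpha: float = 0.05
    confirm_iters: int = 3
    max_imfs: int = 10
    max_sift: int = 100


@dataclass
class IMFSet:
    """The ordered IMFs (fastest first) and the monotone residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    n_samples: int

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for m in self.imfs:
            out += m
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateaus take their midpoint)."""
    dx = np.diff(x)
    s = np.sign(dx)
    # carry the sign of the previous non-flat segment across plateaus
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    ds = np.diff(s)
    maxima = np.where(ds < 0)[0] + 1
    minima = np.where(ds > 0)[0] + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[:-1] * s[1:] < 0))


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray | None:
    """Natural cubic spline through extrema, mirror-extended 2 points per end."""
    n = len(x)
    if len(idx) < 2:
        return None
    t = idx.astype(float)
    v = x[idx]
    k = min(2, len(idx))
    # reflect about the first and last sample positions
    t_pre = 2 * 0.0 - t[1 : k + 1][::-1]
    v_pre = v[1 : k + 1][::-1]
    t_post = 2 * (n - 1.0) - t[-k - 1 : -1][::-1]
    v_post = v[-k - 1 : -1][::-1]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, vv = tt[keep], vv[keep]
    if len(tt) < 2:
        return None
    spline = CubicSpline(tt, vv, bc_type="natural")
    return spline(np.arange(n, dtype=float))


def _is_monotone_residue(x: np.ndarray) -> bool:
    maxima, minima = _local_extrema(x)
    return len(maxima) < 2 or len(minima) < 2


def emd(x: np.ndarray, params: EmdParams = EmdParams()) -> IMFSet:
    """Decompose ``x`` into IMFs plus a residue by envelope sifting."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("emd expects a 1-D signal")
    if len(x) < 8:
        raise ValidationError(f"signal too short for EMD: {len(x)} samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    scale = np.max(np.abs(x)) or 1.0
    while len(imfs) < params.max_imfs and not _is_monotone_residue(residue):
        p = residue.copy()
        confirmed = 0
        for _ in range(params.max_sift):
            maxima, minima = _local_extrema(p)
            upper = _mirrored_envelope(p, maxima)
            lower = _mirrored_envelope(p, minima)
            if upper is None or lower is None:
                break
            m = 0.5 * (upper + lower)
            a = 0.5 * (upper - lower)
            tiny = 1e-12 * scale
            sigma = np.abs(m) / np.maximum(a, tiny)
            ok_amp = (np.mean(sigma < params.theta1) >= 1.0 - params.alpha) and np.all(
                sigma < params.theta2
            )
            n_ext = len(maxima) + len(minima)
            ok_count = abs(n_ext - _zero_crossings(p)) <= 1
            if ok_amp and ok_count:
                confirmed += 1
                if confirmed >= params.confirm_iters:
                    break
            else:
                confirmed = 0
            p = p - m
        imfs.append(p)
        residue = residue - p
    return IMFSet(imfs=imfs, residue=residue, n_samples=len(x))


def orthogonality_index(imf_set: IMFSet) -> float:
    """Huang's index of orthogonality: cross-energy of mode pairs over total energy.

    Small values (< ~0.2 on clean multi-tone signals) indicate the modes are
    nearly orthogonal; it is a diagnostic, not an enforced bound.
    """
    comps = imf_set.imfs + [imf_set.residue]
    total = imf_set.reconstruct()
    denom = float(np.sum(total**2))
    if denom == 0:
        return 0.0
    cross = 0.0
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            cross += float(np.sum(comps[i] * comps[j]))
    return abs(2.0 * cross) / denom
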
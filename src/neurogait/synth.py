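"""Synthetic gait-EEG generator.

No public recording accompanies the study conditions this package targets,
so every stage is exercised on surrogate trials that reproduce their
statistical structure: four gait cycles per trial, each cycle a rest phase
followed by a ``start`` event, a gait phase and a ``stop`` event, with
band-limited alpha/beta/gamma rhythms over 1/f background noise on a 10/10
montage sampled at 500 Hz.

The detectable physiology is modelled as event-related (de)synchronization:
around each event the sustained narrow-band oscillators are multiplicatively
scaled by (1 - depth) (ERD, default for gait start) or (1 + depth) (ERS,
default for gait stop) inside a window ``[e - lead, e - lead + duration]``.
The default window (lead 4 s, duration 6 s) spans the whole pre-movement
intention period that the analysis windows interrogate plus 2 s past the
event.  Oscillator amplitude falls off with unit-sphere distance from Cz
(Gaussian topography), mimicking the sensorimotor focus over the leg area.

The generator is fully reproducible from its seed.  What it does **not**
emulate: volume-conducted correlations between channels, non-stationary
artifacts (ocular, muscular, cable sway during walking) and gait-cycle
kinematic rhythmicity; see the methods note for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import EventMark, Trial, ValidationError
from .layout import ANALYSIS_ELECTRODES, standard_1010_layout

__all__ = ["Oscillator", "SynthConfig", "generate_trial", "generate_dataset"]


@dataclass(frozen=True)
class Oscillator:
    """A sustained narrow-band rhythm: centre frequency, half-bandwidth, RMS at Cz."""

    centre_hz: float
    rms_uv: float
    half_bw_hz: float = 2.0


@dataclass
class SynthConfig:
    """Generator parameters; defaults reproduce the study's trial structure."""

    n_trials: int = 10
    cycles_per_trial: int = 4
    relax_s: float = 11.0  # rest-phase duration (long enough for offline windows)
    gait_s: float = 11.0
    jitter_s: float = 1.0  # uniform +/- jitter on each phase duration
    tail_s: float = 3.0  # trailing rest after the last stop
    sample_rate: float = 500.0
    channels: Sequence[str] | None = None  # default: full 31-electrode montage
    background_rms_uv: float = 8.0
    background_exponent: float = 1.0  # 1/f^exponent power slope
    oscillators: tuple[Oscillator, ...] = (
        Oscillator(10.0, 16.0),  # alpha/mu
        Oscillator(22.0, 12.0),  # beta
        Oscillator(40.0, 8.0),  # low gamma
    )
    topography_sigma: float = 1.0  # Gaussian falloff of oscillator RMS with distance to Cz
    erd_depth: float = 0.8  # in [0, 1]
    erd_lead_s: float = 4.0  # modulation starts this long before the event
    erd_duration_s: float = 6.0
    ramp_s: float = 0.2  # raised-cosine edges of the modulation gate
    start_modulation: str = "erd"  # amplitude x (1 - depth)
    stop_modulation: str = "ers"  # amplitude x (1 + depth)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValidationError("erd_depth must lie in [0, 1]")
        if self.n_trials < 1 or self.cycles_per_trial < 1:
            raise ValidationError("need at least one trial and one cycle")
        min_phase = min(self.relax_s, self.gait_s) - self.jitter_s
        if min_phase <= self.erd_lead_s:
            raise ValidationError(
                f"phases ({min_phase:.1f}s minimum) must outlast the modulation lead "
                f"({self.erd_lead_s}s)"
            )
        for m in (self.start_modulation, self.stop_modulation):
            if m not in ("erd", "ers", "none"):
                raise ValidationError(f"modulation must be 'erd', 'ers' or 'none', got {m!r}")

    def channel_names(self) -> list[str]:
        return list(self.channels) if self.channels is not None else list(standard_1010_layout().names)


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(X * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float, osc: Oscillator, rms: float) -> np.ndarray:
    """Band-limited Gaussian rhythm centred on the oscillator frequency."""
    lo = max(0.5, osc.centre_hz - osc.half_bw_hz)
    hi = min(fs / 2 - 0.5, osc.centre_hz + osc.half_bw_hz)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _modulation_gate(
    t: np.ndarray, events: list[EventMark], config: SynthConfig
) -> np.ndarray:
    """Multiplicative amplitude gate: 1 outside event windows, 1 -/+ depth inside."""
    gate = np.ones_like(t)
    for ev in events:
        mode = config.start_modulation if ev.kind == "start" else config.stop_modulation
        if mode == "none" or config.erd_depth == 0:
            continue
        delta = -config.erd_depth if mode == "erd" else config.erd_depth
        t0 = ev.time_s - config.erd_lead_s
        t1 = t0 + config.erd_duration_s
        r = config.ramp_s
        # raised-cosine ramp in, plateau, ramp out
        env = np.zeros_like(t)
        rise = (t >= t0) & (t < t0 + r)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / r))
        env[(t >= t0 + r) & (t <= t1 - r)] = 1.0
        fall = (t > t1 - r) & (t <= t1)
        env[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - t[fall]) / r))
        gate += delta * env
    return np.clip(gate, 0.0, None)


def generate_trial(config: SynthConfig, rng: np.random.Generator) -> Trial:
    """One trial: jittered event schedule, 1/f background, gated rhythms."""
    names = config.channel_names()
    layout = standard_1010_layout()
    fs = config.sample_rate

    events: list[EventMark] = []
    t = 0.0
    for _ in range(config.cycles_per_trial):
        t = round(t + config.relax_s + rng.uniform(-config.jitter_s, config.jitter_s), 3)
        events.append(EventMark("start", t))
        t = round(t + config.gait_s + rng.uniform(-config.jitter_s, config.jitter_s), 3)
        events.append(EventMark("stop", t))
    duration = t + config.tail_s
    n = int(round(duration * fs))
    tt = np.arange(n) / fs

    gate = _modulation_gate(tt, events, config)
    cz = layout.position("Cz")
    data = np.zeros((len(names), n))
    for c, name in enumerate(names):
        x = _one_over_f_noise(rng, n, fs, config.background_exponent, config.background_rms_uv)
        d_cz = float(np.linalg.norm(layout.position(name) - cz))
        w = np.exp(-((d_cz / config.topography_sigma) ** 2))
        for osc in config.oscillators:
            if osc.rms_uv > 0 and w > 0:
                x = x + gate * _narrowband(rng, n, fs, osc, w * osc.rms_uv)
        data[c] = x
    return Trial(data=data, sample_rate=fs, channel_names=names, events=events)


def generate_dataset(config: SynthConfig) -> tuple[list[Trial], dict]:
    """Independent trials plus a manifest of the seed and per-trial event times."""
    rng = np.random.default_rng(config.seed)
    trials = [generate_trial(config, rng) for _ in range(config.n_trials)]
    manifest = {
        "seed": config.seed,
        "n_trials": config.n_trials,
        "sample_rate_hz": config.sample_rate,
        "channels": config.channel_names(),
        "trials": [
            {
                "index": i,
                "duration_s": tr.duration,
                "events": [{"kind": e.kind, "time_s": e.time_s} for e in tr.events],
            }
            for i, tr in enumerate(trials)
        ],
    }
    return trials, manifest
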
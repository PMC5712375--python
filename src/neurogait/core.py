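"""Core domain types: trials, events, frequency bands and electrode geometry.

All signal amplitudes are in microvolts (µV), times in seconds from the
first sample of a trial, and sample ``k`` spans the half-open interval
``[k/fs, (k+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "EventMark",
    "Trial",
    "BandSet",
    "ElectrodeLayout",
    "DEFAULT_BANDS",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


#: Analysis bands in Hz: alpha (8-13), beta (13-32) and low gamma (32-50),
#: the rhythms whose event-related (de)synchronization accompanies gait.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((8.0, 13.0), (13.0, 32.0), (32.0, 50.0))


@dataclass(frozen=True)
class EventMark:
    """A gait event: the instant the motion-capture system flags start or stop."""

    kind: str  # "start" | "stop"
    time_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("start", "stop"):
            raise ValidationError(f"event kind must be 'start' or 'stop', got {self.kind!r}")
        if not np.isfinite(self.time_s) or self.time_s < 0:
            raise ValidationError(f"event time must be finite and >= 0, got {self.time_s}")


@dataclass
class Trial:
    """One multichannel EEG recording with its gait-event annotations.

    Parameters
    ----------
    data
        ``channels x samples`` array, microvolts.
    sample_rate
        Sampling frequency in Hz (500 in the nominal setup).
    channel_names
        Ordered channel labels matching the rows of ``data``.
    events
        Gait start/stop marks, sorted by time.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: list[str]
    events: list[EventMark] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D (channels x samples), got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("trial data contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        self.events = sorted(self.events, key=lambda e: e.time_s)
        for e in self.events:
            if e.time_s > self.duration + 1e-9:
                raise ValidationError(
                    f"event {e.kind}@{e.time_s}s lies beyond trial duration {self.duration}s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds (samples / rate)."""
        return self.n_samples / self.sample_rate

    def events_of_kind(self, kind: str) -> list[EventMark]:
        return [e for e in self.events if e.kind == kind]

    def with_data(self, data: np.ndarray, channel_names: Sequence[str] | None = None) -> "Trial":
        """Copy of this trial with new data (events and rate carried over)."""
        return Trial(
            data=data,
            sample_rate=self.sample_rate,
            channel_names=list(channel_names) if channel_names is not None else list(self.channel_names),
            events=list(self.events),
        )


@dataclass(frozen=True)
class BandSet:
    """Ordered list of (low, high) frequency intervals in Hz.

    Band membership is half-open, ``low <= f < high``, so adjacent bands
    such as 8-13 and 13-32 Hz do not double-count the shared edge.
    """

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    nyquist_hz: float = 250.0

    def __post_init__(self) -> None:
        prev_low = -np.inf
        for lo, hi in self.bands:
            if not (0 < lo < hi < self.nyquist_hz + 1e-9):
                raise ValidationError(f"band ({lo}, {hi}) must satisfy 0 < low < high < Nyquist")
            if lo < prev_low:
                raise ValidationError("bands must be ordered by lower edge")
            prev_low = lo

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


class DegenerateGeometryError(ValidationError):
    """Two electrodes share a position, so distance weighting is undefined."""


@dataclass
class ElectrodeLayout:
    """Electrode montage on a unit sphere.

    ``names`` orders the full recorded montage; ``feature_subset`` lists the
    electrodes retained for feature extraction (the ring around Cz over the
    leg sensorimotor area).
    """

    names: list[str]
    coords: np.ndarray  # n x 3, unit vectors
    feature_subset: list[str]

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise ValidationError("coords must be (n_electrodes, 3)")
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("electrode coordinates must lie on the unit sphere")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("electrode names must be unique")
        missing = set(self.feature_subset) - set(self.names)
        if missing:
            raise ValidationError(f"feature subset electrodes not in layout: {sorted(missing)}")
        d = self.distance_matrix()
        off = d[~np.eye(len(self.names), dtype=bool)]
        if np.any(off <= 0):
            raise DegenerateGeometryError("two electrodes share the same position")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown electrode {name!r}") from None

    def position(self, name: str) -> np.ndarray:
        return self.coords[self.index(name)]

    def distance(self, a: str, b: str) -> float:
        """3-D Euclidean (chord) distance between two electrodes."""
        return float(np.linalg.norm(self.position(a) - self.position(b)))

    def distance_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        idx = [self.index(n) for n in names] if names is not None else slice(None)
        c = self.coords[idx]
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def subset(self, names: Sequence[str]) -> "ElectrodeLayout":
        idx = [self.index(n) for n in names]
        keep = [n for n in self.feature_subset if n in names]
        return ElectrodeLayout(list(names), self.coords[idx], keep)
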
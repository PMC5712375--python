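"""Analysis windows, 1-s epoch slicing and train/test splits.

Two labelled-window schemes around each gait event ``e`` (seconds):

* ``pseudo_online`` — active (state 1) spans ``[e-2, e+2]`` (intention
  builds before the measured movement onset and carries past it);
  non-active (state 0) covers the whole preceding phase — rest for the
  start model, gait for the stop model — ending 0.5 s before the active
  window to keep a guard gap.
* ``offline`` — active spans the 4 s leading up to the event, ``[e-4, e]``;
  non-active is a matched 4-s window ending 0.5 s before the active one,
  ``[e-8.5, e-4.5]``.

Windows are cut into 1-s epochs every 0.2 s; an epoch must lie wholly
inside its window (a 4-s window therefore yields exactly 16 epochs).
Events whose windows would run off either end of the trial are skipped and
counted rather than truncated, so every epoch keeps a fixed sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trial, ValidationError

__all__ = [
    "Window",
    "WindowSet",
    "Epoch",
    "EpochStream",
    "SplitPlan",
    "build_windows",
    "slice_epochs",
    "make_split",
]

ACTIVE_LEN_S = 4.0
PRE_EVENT_S = 2.0
GAP_S = 0.5
EPOCH_LEN_S = 1.0
HOP_S = 0.2


@dataclass(frozen=True)
class Window:
    t_begin: float
    t_end: float
    state: int  # 1 = intention (active), 0 = rest/gait (non-active)
    event_kind: str  # which detection model ("start" | "stop") this serves

    def __post_init__(self) -> None:
        if self.t_begin >= self.t_end:
            raise ValidationError(f"window [{self.t_begin}, {self.t_end}] has no extent")
        if self.state not in (0, 1):
            raise ValidationError("window state must be 0 or 1")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_begin


@dataclass
class WindowSet:
    windows: list[Window]
    protocol: str  # "offline" | "pseudo_online"
    n_skipped: int = 0  # events dropped because a window fell outside the trial

    def active(self) -> list[Window]:
        return [w for w in self.windows if w.state == 1]

    def non_active(self) -> list[Window]:
        return [w for w in self.windows if w.state == 0]


@dataclass
class Epoch:
    """One 1-s, per-channel slice with its window label."""

    t_begin: float
    data: np.ndarray  # channels x samples
    state: int
    window_index: int
    event_kind: str


@dataclass
class EpochStream:
    epochs: list[Epoch]
    hop_s: float = HOP_S
    length_s: float = EPOCH_LEN_S

    def __len__(self) -> int:
        return len(self.epochs)

    def labels(self) -> np.ndarray:
        return np.array([e.state for e in self.epochs], dtype=int)


@dataclass
class SplitPlan:
    """Trial-level train/test assignment (0-based trial indices)."""

    mode: str  # "loocv" | "fixed"
    folds: list[tuple[list[int], list[int]]] = field(default_factory=list)

    @property
    def train_trials(self) -> list[int]:
        if self.mode != "fixed":
            raise ValidationError("train_trials is only defined for fixed splits")
        return self.folds[0][0]

    @property
    def test_trials(self) -> list[int]:
        if self.mode != "fixed":
            raise ValidationError("test_trials is only defined for fixed splits")
        return self.folds[0][1]


def _phase_begin(trial: Trial, event_kind: str, e: float) -> float:
    """Onset of the phase preceding event ``e`` (rest for start, gait for stop)."""
    prior_kind = "stop" if event_kind == "start" else "start"
    prior = [ev.time_s for ev in trial.events_of_kind(prior_kind) if ev.time_s < e]
    return max(prior) if prior else 0.0


def build_windows(
    trial: Trial,
    event_kind: str,
    protocol: str,
    *,
    active_len_s: float = ACTIVE_LEN_S,
    pre_event_s: float = PRE_EVENT_S,
    gap_s: float = GAP_S,
) -> WindowSet:
    """Labelled active/non-active windows for one detection model."""
    if event_kind not in ("start", "stop"):
        raise ValidationError(f"event_kind must be 'start' or 'stop', got {event_kind!r}")
    if protocol not in ("offline", "pseudo_online"):
        raise ValidationError(f"protocol must be 'offline' or 'pseudo_online', got {protocol!r}")
    events = trial.events_of_kind(event_kind)
    if not events:
        raise ValidationError(f"trial has no {event_kind!r} events")
    windows: list[Window] = []
    skipped = 0
    for ev in events:
        e = ev.time_s
        if protocol == "pseudo_online":
            a0, a1 = e - pre_event_s, e - pre_event_s + active_len_s
            n0 = _phase_begin(trial, event_kind, e)
            n1 = a0 - gap_s
        else:
            a0, a1 = e - active_len_s, e
            n1 = a0 - gap_s
            n0 = n1 - active_len_s
        if a0 < 0 or a1 > trial.duration + 1e-9 or n0 < 0 or n1 - n0 <= 0:
            skipped += 1
            continue
        windows.append(Window(n0, n1, 0, event_kind))
        windows.append(Window(a0, a1, 1, event_kind))
    windows.sort(key=lambda w: w.t_begin)
    return WindowSet(windows=windows, protocol=protocol, n_skipped=skipped)


def slice_epochs(
    trial: Trial,
    windows: WindowSet,
    *,
    epoch_len_s: float = EPOCH_LEN_S,
    hop_s: float = HOP_S,
) -> EpochStream:
    """Cut each window into fixed-length epochs at the configured hop."""
    fs = trial.sample_rate
    n_epoch = int(round(epoch_len_s * fs))
    epochs: list[Epoch] = []
    for wi, w in enumerate(windows.windows):
        if w.t_end > trial.duration + 1e-9:
            raise ValidationError(f"window ends at {w.t_end}s beyond trial ({trial.duration}s)")
        k = 0
        while True:
            t0 = w.t_begin + k * hop_s
            if t0 + epoch_len_s > w.t_end + 1e-9:
                break
            s0 = int(round(t0 * fs))
            epochs.append(
                Epoch(
                    t_begin=t0,
                    data=trial.data[:, s0 : s0 + n_epoch],
                    state=w.state,
                    window_index=wi,
                    event_kind=w.event_kind,
                )
            )
            k += 1
    return EpochStream(epochs=epochs, hop_s=hop_s, length_s=epoch_len_s)


def make_split(
    n_trials: int,
    protocol: str,
    ratio: tuple[int, int] | None = None,
) -> SplitPlan:
    """Trial split: leave-one-out offline, fixed first-train/last-test pseudo-online.

    ``ratio`` is (n_train, n_test) and must cover all trials in fixed mode;
    it defaults to the 6/4 pattern scaled to ``n_trials``.
    """
    if n_trials < 2:
        raise ValidationError("need at least 2 trials to split")
    if protocol == "offline":
        folds = [
            ([j for j in range(n_trials) if j != i], [i]) for i in range(n_trials)
        ]
        return SplitPlan(mode="loocv", folds=folds)
    if protocol != "pseudo_online":
        raise ValidationError(f"unknown protocol {protocol!r}")
    if ratio is None:
        n_test = max(1, int(round(0.4 * n_trials)))
        ratio = (n_trials - n_test, n_test)
    n_train, n_test = ratio
    if n_train < 1 or n_test < 1 or n_train + n_test != n_trials:
        raise ValidationError(
            f"ratio {n_train}/{n_test} does not partition {n_trials} trials"
        )
    folds = [(list(range(n_train)), list(range(n_train, n_trials)))]
    return SplitPlan(mode="fixed", folds=folds)
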
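"""Detection scoring: from per-epoch hits to TPR, Acc, FP/min, FPR and WD.

Per epoch the classifier label is compared with the true window state,
giving a true (T) / false (F) outcome sequence per window.  Detection
rules differ by protocol:

* offline — an active window counts as a detected event when T outnumbers
  F; a non-active window contributes (at most) one false activation when F
  outnumbers T.
* pseudo-online — an active window is detected when it contains a run of
  at least 5 consecutive T; every maximal run of at least 5 consecutive F
  inside a non-active span counts one false activation (a sustained
  spurious command would trigger the device once, however long it lasts;
  ``fp_counting="floor_div"`` instead counts floor(run/5) per run).

Indices (percent where noted):

    TPR    = detected events / true events                      (%)
    Acc    = detected events / (detected events + false activ.) (%)
    FP/min = false activations / non-active time in minutes
    FPR    = FP/min x duration of a single false positive
             (4/60 min offline, 1/60 min pseudo-online)
    WD     = 0.4 TPR + 0.6 Acc - FPR   (TPR, Acc per-unit)

WD ranges from 1 (all events caught, nothing spurious) down to -1.  Acc is
undefined when there are no detections at all; undefined values propagate
as ``None`` and are excluded (and counted) when averaging across trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError

__all__ = [
    "FP_DURATION_MIN",
    "DetectionRecord",
    "EvaluationReport",
    "ReportSummary",
    "score_epochs",
    "detect_events",
    "compute_indices",
    "weighted_discriminator",
    "round_half_away",
    "aggregate_reports",
]

#: Duration of a single false positive, in minutes, by protocol.  Offline a
#: false non-active window spans its full 4 s; pseudo-online a false
#: activation is the 5-epoch run at 0.2-s hop, i.e. 1 s.
FP_DURATION_MIN = {"offline": 4.0 / 60.0, "pseudo_online": 1.0 / 60.0}

CONSECUTIVE = 5


@dataclass
class DetectionRecord:
    """Per-window epoch outcomes plus the detection decisions derived from them."""

    active_outcomes: list[np.ndarray]  # one boolean T/F sequence per active window
    nonactive_outcomes: list[np.ndarray]  # one per non-active span
    nonactive_minutes: float
    protocol: str
    detected: list[bool] = field(default_factory=list)
    false_activations: int = 0
    n_empty_windows: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in FP_DURATION_MIN:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.nonactive_minutes < 0:
            raise ValidationError("non-active time cannot be negative")


def score_epochs(true_labels: np.ndarray, predicted_labels: np.ndarray) -> np.ndarray:
    """Element-wise outcome sequence: True where prediction matches the state."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValidationError(f"label length mismatch: {t.shape} vs {p.shape}")
    return t == p


def _run_lengths(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a boolean sequence."""
    runs: list[int] = []
    count = 0
    for v in mask:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def detect_events(
    record: DetectionRecord,
    *,
    consecutive: int = CONSECUTIVE,
    fp_counting: str = "per_run",
) -> DetectionRecord:
    """Fill in per-window detections and the false-activation count."""
    if fp_counting not in ("per_run", "floor_div"):
        raise ValidationError(f"fp_counting must be 'per_run' or 'floor_div', got {fp_counting!r}")
    detected: list[bool] = []
    empty = 0
    for outcomes in record.active_outcomes:
        outcomes = np.asarray(outcomes, dtype=bool)
        if len(outcomes) == 0:
            empty += 1
            detected.append(False)
            continue
        if record.protocol == "offline":
            detected.append(int(outcomes.sum()) > len(outcomes) - int(outcomes.sum()))
        else:
            detected.append(any(r >= consecutive for r in _run_lengths(outcomes)))
    fps = 0
    for outcomes in record.nonactive_outcomes:
        outcomes = np.asarray(outcomes, dtype=bool)
        if len(outcomes) == 0:
            empty += 1
            continue
        n_false = len(outcomes) - int(outcomes.sum())
        if record.protocol == "offline":
            fps += 1 if n_false > int(outcomes.sum()) else 0
        else:
            runs = _run_lengths(~outcomes)
            if fp_counting == "per_run":
                fps += sum(1 for r in runs if r >= consecutive)
            else:
                fps += sum(r // consecutive for r in runs)
    record.detected = detected
    record.false_activations = fps
    record.n_empty_windows = empty
    return record


@dataclass
class EvaluationReport:
    """Indices for one model over one trial (or an average of trials)."""

    tpr_pct: float
    acc_pct: float | None  # None when no detections occurred at all
    fp_per_min: float
    fp_duration_min: float
    protocol: str
    n_events: int = 0
    n_detected: int = 0
    n_false: int = 0

    @property
    def fpr(self) -> float:
        return self.fp_per_min * self.fp_duration_min

    @property
    def wd(self) -> float | None:
        if self.acc_pct is None:
            return None
        return weighted_discriminator(
            self.tpr_pct, self.acc_pct, self.fp_per_min, self.fp_duration_min, round_to=None
        )


def compute_indices(record: DetectionRecord) -> EvaluationReport:
    """TPR, Acc and FP/min from a scored-and-detected record."""
    if not record.active_outcomes:
        raise ValidationError("record has no true events")
    if len(record.detected) != len(record.active_outcomes):
        raise ValidationError("run detect_events() before compute_indices()")
    n_events = len(record.active_outcomes)
    n_detected = int(np.sum(record.detected))
    n_total = n_detected + record.false_activations
    tpr = 100.0 * n_detected / n_events
    acc = 100.0 * n_detected / n_total if n_total > 0 else None
    if record.nonactive_minutes <= 0:
        raise ValidationError("zero non-active time: FP/min undefined")
    fp_per_min = record.false_activations / record.nonactive_minutes
    return EvaluationReport(
        tpr_pct=tpr,
        acc_pct=acc,
        fp_per_min=fp_per_min,
        fp_duration_min=FP_DURATION_MIN[record.protocol],
        protocol=record.protocol,
        n_events=n_events,
        n_detected=n_detected,
        n_false=record.false_activations,
    )


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (0.915 -> 0.92, -0.915 -> -0.92)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def weighted_discriminator(
    tpr_pct: float,
    acc_pct: float,
    fp_per_min: float,
    fp_duration_min: float,
    *,
    round_to: int | None = 2,
) -> float:
    """WD = 0.4 TPR + 0.6 Acc - FP/min x FP-duration, TPR and Acc per-unit.

    Reported values are conventionally rounded to two decimals (half away
    from zero); pass ``round_to=None`` for the raw value.
    """
    for v in (tpr_pct, acc_pct, fp_per_min, fp_duration_min):
        if not np.isfinite(v):
            raise ValidationError("WD inputs must be finite")
    wd = 0.4 * (tpr_pct / 100.0) + 0.6 * (acc_pct / 100.0) - fp_per_min * fp_duration_min
    return round_half_away(wd, round_to) if round_to is not None else wd


@dataclass
class ReportSummary:
    """Across-trial mean and sample standard deviation of each defined index."""

    mean: EvaluationReport
    sd: dict[str, float]
    n_reports: int
    n_acc_undefined: int


def aggregate_reports(reports: list[EvaluationReport]) -> ReportSummary:
    """Arithmetic mean per index; undefined Acc entries are excluded and counted."""
    if not reports:
        raise ValidationError("no reports to aggregate")
    protocols = {r.protocol for r in reports}
    if len(protocols) != 1:
        raise ValidationError(f"cannot aggregate across protocols: {protocols}")
    tpr = np.array([r.tpr_pct for r in reports])
    fp = np.array([r.fp_per_min for r in reports])
    acc = np.array([r.acc_pct for r in reports if r.acc_pct is not None])
    n_undef = sum(1 for r in reports if r.acc_pct is None)

    def _sd(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    mean = EvaluationReport(
        tpr_pct=float(tpr.mean()),
        acc_pct=float(acc.mean()) if len(acc) else None,
        fp_per_min=float(fp.mean()),
        fp_duration_min=reports[0].fp_duration_min,
        protocol=reports[0].protocol,
        n_events=int(np.sum([r.n_events for r in reports])),
        n_detected=int(np.sum([r.n_detected for r in reports])),
        n_false=int(np.sum([r.n_false for r in reports])),
    )
    wds = np.array([r.wd for r in reports if r.wd is not None])
    sd = {
        "tpr_pct": _sd(tpr),
        "acc_pct": _sd(acc) if len(acc) else float("nan"),
        "fp_per_min": _sd(fp),
        "wd": _sd(wds) if len(wds) else float("nan"),
    }
    return ReportSummary(mean=mean, sd=sd, n_reports=len(reports), n_acc_undefined=n_undef)
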
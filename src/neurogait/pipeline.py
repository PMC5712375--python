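"""End-to-end orchestration: preprocess -> features -> split -> SVM -> indices.

`extract_features` turns one trial into labelled 27-value epoch features
for a chosen method ("fft" | "hht" | "st"), event model and protocol.
`run_offline` evaluates by leave-one-out cross-validation over trials;
`run_pseudo_online` trains on the first trials and replays the remaining
ones in acquisition order.  Both return per-test-trial evaluation reports
plus their across-trial aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import SvmConfig, classify, train
from .core import BandSet, ElectrodeLayout, Trial, ValidationError
from .evaluate import (
    DetectionRecord,
    EvaluationReport,
    ReportSummary,
    aggregate_reports,
    compute_indices,
    detect_events,
    score_epochs,
)
from .fft_features import fft_band_features
from .hht import hht_band_features
from .layout import standard_1010_layout
from .preprocessing import (
    FilterSpec,
    butterworth_highpass,
    laplacian_filter,
    laplacian_weights,
    select_channels,
)
from .protocol import EpochStream, WindowSet, build_windows, make_split, slice_epochs
from .stockwell import st_band_features

__all__ = ["METHODS", "FeatureSet", "extract_features", "run_offline", "run_pseudo_online"]

METHODS = ("fft", "hht", "st")


@dataclass
class FeatureSet:
    """Labelled epoch features for one trial/model, with window bookkeeping."""

    X: np.ndarray  # n_epochs x (n_electrodes * n_bands)
    y: np.ndarray  # epoch state labels
    window_index: np.ndarray  # epoch -> index into windows.windows
    windows: WindowSet
    method: str
    event: str

    @property
    def n_epochs(self) -> int:
        return len(self.y)


def _epoch_features(
    stream: EpochStream, method: str, sample_rate: float, bands: BandSet
) -> np.ndarray:
    rows = []
    for ep in stream.epochs:
        if method == "fft":
            f = fft_band_features(ep.data, sample_rate, bands)
        elif method == "hht":
            f = hht_band_features(ep.data, sample_rate, bands)
        elif method == "st":
            f = st_band_features(ep.data, sample_rate, bands)
        else:
            raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
        rows.append(f.ravel())  # electrode-major: e1b1 e1b2 e1b3 e2b1 ...
    n_feat = rows[0].size if rows else 0
    return np.array(rows).reshape(len(rows), n_feat)


def extract_features(
    trial: Trial,
    method: str,
    event: str,
    protocol: str,
    *,
    bands: BandSet = BandSet(),
    layout: ElectrodeLayout | None = None,
    highpass: FilterSpec = FilterSpec(),
) -> FeatureSet:
    """Preprocess one trial and extract per-epoch band features.

    The Laplacian runs over every recorded channel before subsetting to the
    layout's analysis electrodes; the high-pass applies to the FFT path only.
    """
    layout = layout if layout is not None else standard_1010_layout()
    weights = laplacian_weights(layout, trial.channel_names)
    prep = laplacian_filter(trial, weights)
    if method == "fft":
        prep = butterworth_highpass(prep, highpass)
    analysis = [n for n in layout.feature_subset if n in trial.channel_names]
    if not analysis:
        raise ValidationError("trial contains none of the layout's analysis electrodes")
    prep = select_channels(prep, analysis)
    windows = build_windows(prep, event, protocol)
    stream = slice_epochs(prep, windows)
    X = _epoch_features(stream, method, prep.sample_rate, bands)
    return FeatureSet(
        X=X,
        y=stream.labels(),
        window_index=np.array([ep.window_index for ep in stream.epochs], dtype=int),
        windows=windows,
        method=method,
        event=event,
    )


def _detection_record(fs: FeatureSet, predictions: np.ndarray, protocol: str) -> DetectionRecord:
    outcomes = score_epochs(fs.y, predictions)
    active, nonactive = [], []
    nonactive_minutes = 0.0
    for wi, w in enumerate(fs.windows.windows):
        seq = outcomes[fs.window_index == wi]
        if w.state == 1:
            active.append(seq)
        else:
            nonactive.append(seq)
            nonactive_minutes += w.duration / 60.0
    return DetectionRecord(
        active_outcomes=active,
        nonactive_outcomes=nonactive,
        nonactive_minutes=nonactive_minutes,
        protocol=protocol,
    )


@dataclass
class RunResult:
    """Per-test-trial reports and their aggregate for one model."""

    reports: list[EvaluationReport]
    summary: ReportSummary
    test_trials: list[int]
    method: str = ""
    event: str = ""
    protocol: str = ""
    svm: SvmConfig = field(default_factory=SvmConfig)


def _evaluate_split(
    feature_sets: list[FeatureSet],
    folds: list[tuple[list[int], list[int]]],
    protocol: str,
    svm: SvmConfig,
    consecutive: int,
    fp_counting: str,
) -> tuple[list[EvaluationReport], list[int]]:
    reports: list[EvaluationReport] = []
    test_order: list[int] = []
    for train_idx, test_idx in folds:
        Xtr = np.vstack([feature_sets[i].X for i in train_idx])
        ytr = np.concatenate([feature_sets[i].y for i in train_idx])
        model = train(Xtr, ytr, svm)
        for i in test_idx:
            fs = feature_sets[i]
            pred = classify(model, fs.X)
            record = detect_events(
                _detection_record(fs, pred, protocol),
                consecutive=consecutive,
                fp_counting=fp_counting,
            )
            reports.append(compute_indices(record))
            test_order.append(i)
    return reports, test_order


def _run(
    trials: Sequence[Trial],
    method: str,
    event: str,
    protocol: str,
    folds,
    *,
    bands: BandSet,
    layout: ElectrodeLayout | None,
    svm: SvmConfig,
    consecutive: int,
    fp_counting: str,
) -> RunResult:
    feature_sets = [
        extract_features(t, method, event, protocol, bands=bands, layout=layout) for t in trials
    ]
    reports, test_order = _evaluate_split(
        feature_sets, folds, protocol, svm, consecutive, fp_counting
    )
    return RunResult(
        reports=reports,
        summary=aggregate_reports(reports),
        test_trials=test_order,
        method=method,
        event=event,
        protocol=protocol,
        svm=svm,
    )


def run_offline(
    trials: Sequence[Trial],
    method: str,
    event: str,
    *,
    bands: BandSet = BandSet(),
    layout: ElectrodeLayout | None = None,
    svm: SvmConfig = SvmConfig(),
) -> RunResult:
    """Leave-one-out cross-validation: every trial is the test trial once."""
    plan = make_split(len(trials), "offline")
    return _run(
        trials, method, event, "offline", plan.folds,
        bands=bands, layout=layout, svm=svm, consecutive=5, fp_counting="per_run",
    )


def run_pseudo_online(
    trials: Sequence[Trial],
    method: str,
    event: str,
    *,
    ratio: tuple[int, int] | None = None,
    bands: BandSet = BandSet(),
    layout: ElectrodeLayout | None = None,
    svm: SvmConfig = SvmConfig(),
    consecutive: int = 5,
    fp_counting: str = "per_run",
) -> RunResult:
    """Train on the first trials, replay the remaining ones as if live."""
    plan = make_split(len(trials), "pseudo_online", ratio)
    return _run(
        trials, method, event, "pseudo_online", plan.folds,
        bands=bands, layout=layout, svm=svm, consecutive=consecutive, fp_counting=fp_counting,
    )
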
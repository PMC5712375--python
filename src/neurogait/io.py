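"""Plain-text readers and writers for trials and event annotations.

Trial files are TSV with a two-line comment header::

    # sample_rate_hz=500
    # channels=Fz<TAB>FC1<TAB>...
    time_s<TAB>v1<TAB>...<TAB>vN

followed by one row per sample (values in µV, 17 significant digits so a
write/read round-trip is exact).  Event files are TSV with a ``kind\ttime_s``
header and one ``start|stop`` row per event.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .core import EventMark, Trial, ValidationError

__all__ = ["FormatError", "read_trial", "write_trial", "read_events", "write_events"]


class FormatError(ValueError):
    """A trial or events file does not conform to the TSV dialect."""


def write_trial(trial: Trial, signal_path: os.PathLike, events_path: os.PathLike | None = None) -> None:
    """Write a trial (and optionally its events) to TSV files."""
    signal_path = Path(signal_path)
    with open(signal_path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate_hz={trial.sample_rate:.17g}\n")
        fh.write("# channels=" + "\t".join(trial.channel_names) + "\n")
        fh.write("time_s\t" + "\t".join(trial.channel_names) + "\n")
        t = np.arange(trial.n_samples) / trial.sample_rate
        for k in range(trial.n_samples):
            row = "\t".join(f"{v:.17g}" for v in trial.data[:, k])
            fh.write(f"{t[k]:.17g}\t{row}\n" if row else f"{t[k]:.17g}\n")
    if events_path is not None:
        write_events(trial.events, events_path)


def write_events(events: list[EventMark], events_path: os.PathLike) -> None:
    with open(events_path, "w", encoding="utf-8") as fh:
        fh.write("kind\ttime_s\n")
        for e in events:
            fh.write(f"{e.kind}\t{e.time_s:.17g}\n")


def read_events(events_path: os.PathLike) -> list[EventMark]:
    events: list[EventMark] = []
    with open(events_path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["kind", "time_s"]:
            raise FormatError(f"bad events header: {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"events line {ln}: expected 2 fields, got {len(parts)}")
            kind, t = parts
            try:
                events.append(EventMark(kind=kind, time_s=float(t)))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"events line {ln}: {exc}") from None
    return sorted(events, key=lambda e: e.time_s)


def read_trial(signal_path: os.PathLike, events_path: os.PathLike | None = None) -> Trial:
    """Read a trial TSV (and optional events TSV) back into a :class:`Trial`."""
    signal_path = Path(signal_path)
    sample_rate: float | None = None
    channels: list[str] | None = None
    with open(signal_path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# sample_rate_hz="):
            try:
                sample_rate = float(line.split("=", 1)[1])
            except ValueError:
                raise FormatError(f"line {i + 1}: unparseable sample rate: {line!r}") from None
        elif line.startswith("# channels="):
            channels = line.split("=", 1)[1].split("\t")
        elif line.startswith("#"):
            continue
        else:
            body_start = i
            break
    else:
        body_start = len(lines)
    if sample_rate is None:
        raise FormatError("missing '# sample_rate_hz=' header line")
    if channels is None:
        raise FormatError("missing '# channels=' header line")
    if channels == [""]:
        channels = []
    if body_start < len(lines):
        expect = "time_s" + ("\t" if channels else "") + "\t".join(channels)
        if lines[body_start] != expect:
            raise FormatError(f"line {body_start + 1}: bad column header: {lines[body_start]!r}")
        body_start += 1
    rows = []
    for ln, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(channels) + 1:
            raise FormatError(
                f"line {ln}: expected {len(channels) + 1} columns, got {len(parts)}"
            )
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            raise FormatError(f"line {ln}: non-numeric sample value") from None
    data = np.asarray(rows, dtype=float).T if rows else np.empty((len(channels), 0))
    events = read_events(events_path) if events_path is not None else []
    try:
        return Trial(data=data, sample_rate=sample_rate, channel_names=channels, events=events)
    except ValidationError as exc:
        raise ValidationError(f"{signal_path.name}: {exc}") from None
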
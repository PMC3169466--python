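"""Compression event streams: domain types and CSV reading/writing.

One resuscitation attempt is stored as a single CSV file holding one row per
recorded event, with a metadata comment line carrying the attempt id and
scenario duration::

    # attempt_id=A01 duration_s=720.0
    time_s,event_type,depth_mm
    0.545,compression,44.2
    1.1,compression,43.8
    ...

Times are seconds from scenario start (t = 0 at "patient found"), depth is the
peak sternal displacement of that compression in millimetres.  Ventilation
rows carry an empty depth field and are skipped on input (this package
analyses the compression channel only).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CohortError, FormatError, ValidationError

logger = logging.getLogger(__name__)

HEADER = ["time_s", "event_type", "depth_mm"]
_META_RE = re.compile(r"#\s*attempt_id=(\S+)\s+duration_s=(\S+)\s*$")


@dataclass(frozen=True)
class CompressionEvent:
    """One delivered chest compression.

    Attributes
    ----------
    time : float
        Seconds from scenario start; non-negative.
    depth : float
        Peak compression depth in mm; non-negative.
    """

    time: float
    depth: float

    def __post_init__(self) -> None:
        if not self.time >= 0:
            raise ValidationError(f"event time must be >= 0, got {self.time}")
        if not self.depth >= 0:
            raise ValidationError(f"compression depth must be >= 0, got {self.depth}")


@dataclass(frozen=True)
class AttemptRecord:
    """One resuscitation attempt: an ordered compression event stream.

    Events must be strictly increasing in time and all fall before
    ``duration`` (the scenario length in seconds).
    """

    attempt_id: str
    events: tuple[CompressionEvent, ...] = field(default_factory=tuple)
    duration: float = 720.0

    def __post_init__(self) -> None:
        if not self.attempt_id:
            raise ValidationError("attempt_id must be non-empty")
        if not self.duration > 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        object.__setattr__(self, "events", tuple(self.events))
        prev = -1.0
        for i, ev in enumerate(self.events):
            if ev.time <= prev:
                raise ValidationError(
                    f"attempt {self.attempt_id!r}: event times must be strictly "
                    f"increasing; event {i} at t={ev.time} follows t={prev}"
                )
            prev = ev.time
        if self.events and self.events[-1].time >= self.duration:
            raise ValidationError(
                f"attempt {self.attempt_id!r}: last event at t={self.events[-1].time} "
                f"is not before duration {self.duration}"
            )

    @property
    def times(self) -> list[float]:
        return [ev.time for ev in self.events]

    @property
    def depths(self) -> list[float]:
        return [ev.depth for ev in self.events]


def read_attempt(path: str | Path) -> AttemptRecord:
    """Read one attempt CSV, validating layout and event ordering.

    Ventilation rows are skipped (with a logged count); the returned record
    contains compression events only.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        meta_line = fh.readline()
        m = _META_RE.match(meta_line.strip())
        if m is None:
            raise FormatError(
                f"{path}: first line must be '# attempt_id=<id> duration_s=<s>', "
                f"got {meta_line.strip()!r}"
            )
        attempt_id = m.group(1)
        try:
            duration = float(m.group(2))
        except ValueError as exc:
            raise FormatError(f"{path}: bad duration_s {m.group(2)!r}") from exc

        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise FormatError(f"{path}: missing header row") from exc
        if header != HEADER:
            raise FormatError(
                f"{path}: header must be {','.join(HEADER)!r}, got {','.join(header)!r}"
            )

        events: list[CompressionEvent] = []
        n_vent = 0
        prev_time = -1.0
        for rownum, row in enumerate(reader, start=1):
            if len(row) != 3:
                raise FormatError(
                    f"{path}: row {rownum} has {len(row)} fields, expected 3"
                )
            time_s, event_type, depth_mm = row
            try:
                t = float(time_s)
            except ValueError as exc:
                raise FormatError(f"{path}: row {rownum}: bad time {time_s!r}") from exc
            if event_type == "ventilation":
                n_vent += 1
                continue
            if event_type != "compression":
                raise FormatError(
                    f"{path}: row {rownum}: unknown event_type {event_type!r}"
                )
            try:
                d = float(depth_mm)
            except ValueError as exc:
                raise FormatError(f"{path}: row {rownum}: bad depth {depth_mm!r}") from exc
            if d < 0:
                raise ValidationError(f"{path}: row {rownum}: negative depth {d}")
            if t <= prev_time:
                raise ValidationError(
                    f"{path}: row {rownum}: non-monotone time {t} (previous {prev_time})"
                )
            prev_time = t
            events.append(CompressionEvent(time=t, depth=d))

    if n_vent:
        logger.info("%s: skipped %d ventilation rows", path, n_vent)
    return AttemptRecord(attempt_id=attempt_id, events=tuple(events), duration=duration)


def write_attempt(record: AttemptRecord, path: str | Path) -> None:
    """Write an attempt CSV readable by :func:`read_attempt`.

    Output is deterministic: fixed column order and shortest round-trip float
    formatting, so identical records produce byte-identical files.
    """
    path = Path(path)
    lines = [f"# attempt_id={record.attempt_id} duration_s={record.duration!r}"]
    lines.append(",".join(HEADER))
    for ev in record.events:
        lines.append(f"{ev.time!r},compression,{ev.depth!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cohort(records: Sequence[AttemptRecord], out_dir: str | Path) -> Path:
    """Write one CSV per attempt plus a ``manifest.txt`` listing them.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for rec in records:
        name = f"{rec.attempt_id}.csv"
        write_attempt(rec, out_dir / name)
        names.append(name)
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(names) + "\n", encoding="utf-8")
    return manifest


def read_cohort(path: str | Path) -> list[AttemptRecord]:
    """Read a cohort from a directory of attempt CSVs or a manifest file.

    A manifest is a plain-text file of attempt-file paths (relative paths are
    resolved against the manifest's directory).  Records are returned sorted
    by attempt_id; duplicate ids or any unreadable file abort the load.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.glob("*.csv"))
    elif path.is_file():
        base = path.parent
        files = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = Path(line)
            files.append(p if p.is_absolute() else base / p)
    else:
        raise CohortError(f"cohort path {path} does not exist")

    if not files:
        raise CohortError(f"no attempt files found under {path}")

    records: list[AttemptRecord] = []
    for f in files:
        try:
            records.append(read_attempt(f))
        except (FormatError, ValidationError, OSError) as exc:
            raise CohortError(f"failed to read attempt file {f}: {exc}") from exc

    seen: dict[str, Path] = {}
    for rec, f in zip(records, files):
        if rec.attempt_id in seen:
            raise CohortError(
                f"duplicate attempt_id {rec.attempt_id!r} in {f} and {seen[rec.attempt_id]}"
            )
        seen[rec.attempt_id] = f
    records.sort(key=lambda r: r.attempt_id)
    return records


def events_from_arrays(
    attempt_id: str,
    times: Iterable[float],
    depths: Iterable[float],
    duration: float = 720.0,
) -> AttemptRecord:
    """Convenience constructor from parallel time/depth sequences."""
    events = tuple(
        CompressionEvent(time=float(t), depth=float(d)) for t, d in zip(times, depths)
    )
    return AttemptRecord(attempt_id=attempt_id, events=events, duration=duration)
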
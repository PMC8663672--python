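"""Data model and I/O for heart-rate sample streams and activity-label intervals.

A heart-rate stream is an ordered sequence of timestamped beats-per-minute
readings, each carrying the sensor's reliability flag, as produced by a
wrist-worn PPG (photoplethysmography) device sampling at a fixed cadence.
Activity intervals are labelled, non-overlapping time spans from an activity
recognizer (still, walking, running, ...) that downstream modules use to
gate cues and to exclude exercise from baseline calibration.

All timestamps are UTC seconds since the epoch; the local timezone offset
needed for clock-time rules lives in configuration, never in the samples.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

ACTIVITY_LABELS = frozenset(
    {"still", "walking", "running", "cycling", "in_vehicle", "unknown"}
)

#: Physiological plausibility window for wrist heart rate, bpm.
DEFAULT_MIN_BPM = 30.0
DEFAULT_MAX_BPM = 220.0


class StreamValidationError(ValueError):
    """Raised when a stream violates an ordering or overlap invariant."""


class StreamParseError(ValueError):
    """Raised when a CSV row cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class HeartRateSample:
    """One timestamped heart-rate measurement.

    Attributes
    ----------
    t : float
        UTC seconds since the epoch.
    bpm : float
        Beats per minute (positive when the sample is reliable).
    reliable : bool
        Sensor-confidence flag, possibly re-flagged by :func:`mark_reliability`.
    """

    t: float
    bpm: float
    reliable: bool

    def __post_init__(self) -> None:
        if self.reliable and not self.bpm > 0:
            raise ValueError(f"reliable sample must have bpm > 0, got {self.bpm}")


@dataclass(frozen=True)
class ActivityInterval:
    """A labelled half-open time span [start, end) in UTC epoch seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.label!r}")


def _iso_to_epoch(text: str) -> float:
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _epoch_to_iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat()


def validate_stream(samples: Sequence[HeartRateSample]) -> None:
    """Check strict timestamp monotonicity; name the first offending index."""
    for i in range(1, len(samples)):
        if samples[i].t <= samples[i - 1].t:
            raise StreamValidationError(
                f"timestamps not strictly increasing at sample {i + 1} "
                f"(t={samples[i].t} follows t={samples[i - 1].t})"
            )


def read_hr_stream(path: str | Path) -> list[HeartRateSample]:
    """Read a heart-rate stream CSV with header ``timestamp_iso,bpm,reliable``.

    Timestamps are ISO-8601 (naive timestamps are taken as UTC); ``reliable``
    is 0 or 1.  Raises :class:`StreamParseError` with the offending line
    number for malformed rows and :class:`StreamValidationError` if
    timestamps are not strictly increasing.
    """
    samples: list[HeartRateSample] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["timestamp_iso", "bpm", "reliable"]:
            raise StreamParseError(
                f"expected header timestamp_iso,bpm,reliable, got {header}", 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise StreamParseError(f"expected 3 fields, got {len(row)}", lineno)
            try:
                t = _iso_to_epoch(row[0])
                bpm = float(row[1])
                rel_raw = int(row[2])
            except (ValueError, OverflowError) as exc:
                raise StreamParseError(str(exc), lineno) from exc
            if rel_raw not in (0, 1):
                raise StreamParseError(f"reliable must be 0 or 1, got {row[2]}", lineno)
            if samples and t <= samples[-1].t:
                raise StreamValidationError(
                    f"line {lineno}: timestamp {row[0]} not after previous sample"
                )
            samples.append(HeartRateSample(t=t, bpm=bpm, reliable=bool(rel_raw)))
    return samples


def write_hr_stream(samples: Iterable[HeartRateSample], path: str | Path) -> None:
    """Write samples in the canonical CSV form read by :func:`read_hr_stream`.

    Floats are written with ``repr`` so a read/write cycle is byte-stable.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["timestamp_iso", "bpm", "reliable"])
        for s in samples:
            writer.writerow([_epoch_to_iso(s.t), repr(s.bpm), int(s.reliable)])


def mark_reliability(
    samples: Sequence[HeartRateSample],
    min_bpm: float = DEFAULT_MIN_BPM,
    max_bpm: float = DEFAULT_MAX_BPM,
) -> list[HeartRateSample]:
    """Re-flag reliability as: sensor flag AND bpm within [min_bpm, max_bpm].

    The sensor flag is necessary but not sufficient; the plausibility window
    guards against motion-artifact readings that PPG confidence heuristics
    miss.  Idempotent.
    """
    if not min_bpm < max_bpm:
        raise ValueError("min_bpm must be below max_bpm")
    return [
        replace(s, reliable=s.reliable and min_bpm <= s.bpm <= max_bpm)
        for s in samples
    ]


def validate_intervals(intervals: Sequence[ActivityInterval]) -> None:
    """Reject overlapping intervals (ambiguous activity must surface, not merge)."""
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise StreamValidationError(
                f"activity intervals overlap: [{prev.start}, {prev.end}) "
                f"{prev.label!r} and [{cur.start}, {cur.end}) {cur.label!r}"
            )


def read_activity_stream(path: str | Path) -> list[ActivityInterval]:
    """Read an activity CSV with header ``start_iso,end_iso,label``."""
    intervals: list[ActivityInterval] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["start_iso", "end_iso", "label"]:
            raise StreamParseError(
                f"expected header start_iso,end_iso,label, got {header}", 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise StreamParseError(f"expected 3 fields, got {len(row)}", lineno)
            try:
                iv = ActivityInterval(
                    start=_iso_to_epoch(row[0]),
                    end=_iso_to_epoch(row[1]),
                    label=row[2],
                )
            except ValueError as exc:
                raise StreamParseError(str(exc), lineno) from exc
            intervals.append(iv)
    validate_intervals(intervals)
    return sorted(intervals, key=lambda iv: iv.start)


def write_activity_stream(
    intervals: Iterable[ActivityInterval], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["start_iso", "end_iso", "label"])
        for iv in intervals:
            writer.writerow([_epoch_to_iso(iv.start), _epoch_to_iso(iv.end), iv.label])


def activity_at(intervals: Sequence[ActivityInterval], t: float) -> str:
    """Label of the interval covering ``t`` ([start, end)), else ``"unknown"``.

    ``intervals`` must be non-overlapping; they are binary-searched by start.
    """
    if not intervals:
        return "unknown"
    ordered = sorted(intervals, key=lambda iv: iv.start)
    i = bisect.bisect_right([iv.start for iv in ordered], t) - 1
    if i >= 0 and ordered[i].start <= t < ordered[i].end:
        return ordered[i].label
    return "unknown"
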
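"""Annotatable event timeline: persistence and export.

The timeline is the user's chronological record of everything the engine
did — measurements, level changes, vibrations, messages — to which the user
can attach free-text notes and a subjective arousal rating (an integer 0–10
SUD-style scale: 0 calm, 10 maximal inner tension).  Pairing the sensor's
level with the user's own rating at the same moment is the point of the
record.

Storage is an append-only JSON-lines file; JSONL export/import is lossless,
CSV export flattens event fields for spreadsheet use.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

from .cueing import CueEvent
from .levels import LevelEvent

Event = Union[LevelEvent, CueEvent]

CSV_COLUMNS = ["t", "kind", "bpm", "z", "level", "prev", "cue_text", "note",
               "subjective_arousal"]


class TimelineError(ValueError):
    pass


@dataclass(frozen=True)
class TimelineEntry:
    entry_id: int
    event: Event
    note: str = ""
    subjective_arousal: int | None = None

    @property
    def t(self) -> float:
        return self.event.t


@dataclass
class Timeline:
    """Append-only, annotatable sequence of engine events."""

    entries: list[TimelineEntry] = field(default_factory=list)
    _next_id: int = 1

    def __len__(self) -> int:
        return len(self.entries)

    def append(self, event: Event) -> TimelineEntry:
        """Append an event; its timestamp must not precede the last entry's."""
        if self.entries and event.t < self.entries[-1].t:
            raise TimelineError(
                f"event at t={event.t} precedes last entry t={self.entries[-1].t}"
            )
        entry = TimelineEntry(entry_id=self._next_id, event=event)
        self._next_id += 1
        self.entries.append(entry)
        return entry

    def extend(self, events) -> None:
        for e in sorted(events, key=lambda e: e.t):
            self.append(e)

    def annotate(
        self,
        entry_id: int,
        note: str = "",
        subjective_arousal: int | None = None,
    ) -> TimelineEntry:
        """Attach a note and/or subjective arousal rating; overwrites prior
        annotation.  The event payload, timestamp and ordering never change."""
        if subjective_arousal is not None and not 0 <= subjective_arousal <= 10:
            raise TimelineError(
                f"subjective_arousal must be in [0, 10], got {subjective_arousal}"
            )
        for i, entry in enumerate(self.entries):
            if entry.entry_id == entry_id:
                updated = replace(entry, note=note,
                                  subjective_arousal=subjective_arousal)
                self.entries[i] = updated
                return updated
        raise TimelineError(f"no timeline entry with id {entry_id}")

    # -- serialization -----------------------------------------------------

    def _entry_dict(self, entry: TimelineEntry) -> dict:
        e = entry.event
        if isinstance(e, LevelEvent):
            ev = {"t": e.t, "kind": e.kind, "bpm": e.bpm, "z": e.z,
                  "level": e.level, "prev": e.previous_level}
        else:
            ev = {"t": e.t, "kind": e.kind, "level": e.level, "text": e.text}
        return {"id": entry.entry_id, "event": ev, "note": entry.note,
                "subjective_arousal": entry.subjective_arousal}

    def export(self, path: str | Path, format: str = "jsonl") -> None:
        """Write the timeline; ``jsonl`` is lossless, ``csv`` flattens."""
        if format == "jsonl":
            with open(path, "w") as fh:
                for entry in self.entries:
                    fh.write(json.dumps(self._entry_dict(entry)) + "\n")
        elif format == "csv":
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh, lineterminator="\n")
                writer.writerow(CSV_COLUMNS)
                for entry in self.entries:
                    e = entry.event
                    if isinstance(e, LevelEvent):
                        row = [e.t, e.kind, e.bpm, e.z, e.level,
                               e.previous_level, ""]
                    else:
                        row = [e.t, e.kind, "", "", e.level, "", e.text]
                    row += [entry.note,
                            "" if entry.subjective_arousal is None
                            else entry.subjective_arousal]
                    writer.writerow(row)
        else:
            raise TimelineError(f"unknown export format {format!r}")

    @classmethod
    def load(cls, path: str | Path) -> "Timeline":
        """Re-import a JSONL export; inverse of ``export(format='jsonl')``."""
        tl = cls()
        max_id = 0
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                ev = d["event"]
                if ev["kind"] in ("measurement", "level_change"):
                    event: Event = LevelEvent(
                        t=ev["t"], kind=ev["kind"], bpm=ev["bpm"], z=ev["z"],
                        level=ev["level"], previous_level=ev.get("prev"))
                else:
                    event = CueEvent(t=ev["t"], kind=ev["kind"],
                                     level=ev["level"], text=ev.get("text", ""))
                tl.entries.append(TimelineEntry(
                    entry_id=d["id"], event=event, note=d.get("note", ""),
                    subjective_arousal=d.get("subjective_arousal")))
                max_id = max(max_id, d["id"])
        tl._next_id = max_id + 1
        return tl
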
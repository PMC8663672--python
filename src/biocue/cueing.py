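"""Cue generation: vibrations and feedback messages from level changes.

Every level change in a permitted activity context produces a notifying
vibration; a change whose new level reaches the message threshold (default
level 3, i.e. more than 2 baseline SDs above the mean) additionally shows a
feedback message — by default "your heart rate is higher than average", or
a personalized text.  Activity gating suppresses cues (both kinds) while
the wearer's recognized activity is outside the permitted set, but never
removes events from the underlying level stream: measurement and logging
continue so the timeline stays complete.

Messages fire on the transition into a qualifying level, one per qualifying
level change, never per sample while elevated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .hrstream import ACTIVITY_LABELS, ActivityInterval, activity_at
from .levels import LEVEL_MAX, LEVEL_MIN, LevelEvent

DEFAULT_MESSAGE_TEXT = "your heart rate is higher than average"
DEFAULT_MESSAGE_MIN_LEVEL = 3


class CueConfigError(ValueError):
    """Raised for contradictory or out-of-range cue configuration."""


@dataclass(frozen=True)
class CueEvent:
    """A user-facing cue: a vibration on any level change, or a message."""

    t: float
    kind: str  # "vibration" | "message"
    level: int
    text: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("vibration", "message"):
            raise ValueError(f"unknown cue kind {self.kind!r}")
        if self.kind == "message" and not self.text:
            raise ValueError("message cue requires non-empty text")


@dataclass(frozen=True)
class CueConfig:
    """Cue policy parameters.

    Exactly one of ``allowed_activities`` / ``blocked_activities`` may be
    given (or neither, meaning no gating): an allow-list pauses cueing
    outside the named activity profiles, a block-list pauses it inside them.
    """

    message_min_level: int = DEFAULT_MESSAGE_MIN_LEVEL
    message_text: str = DEFAULT_MESSAGE_TEXT
    personalized: bool = False
    allowed_activities: frozenset[str] | None = None
    blocked_activities: frozenset[str] | None = None
    vibrate_on_change: bool = True

    def __post_init__(self) -> None:
        if not LEVEL_MIN <= self.message_min_level <= LEVEL_MAX:
            raise CueConfigError(
                f"message_min_level must lie in [{LEVEL_MIN}, {LEVEL_MAX}]"
            )
        if self.allowed_activities is not None and self.blocked_activities is not None:
            raise CueConfigError(
                "specify allowed_activities or blocked_activities, not both"
            )
        for s in (self.allowed_activities, self.blocked_activities):
            if s is not None and not frozenset(s) <= ACTIVITY_LABELS:
                raise CueConfigError(f"unknown activity labels: {set(s) - ACTIVITY_LABELS}")
        if not self.message_text:
            raise CueConfigError("message_text must be non-empty")

    def permits(self, label: str) -> bool:
        if self.allowed_activities is not None:
            return label in self.allowed_activities
        if self.blocked_activities is not None:
            return label not in self.blocked_activities
        return True


def generate_cues(
    level_events: Sequence[LevelEvent],
    activity_intervals: Sequence[ActivityInterval] = (),
    config: CueConfig = CueConfig(),
) -> list[CueEvent]:
    """Turn level-change events into vibration and message cues.

    For every ``level_change`` whose timestamp falls in a permitted activity
    context: one vibration (if ``vibrate_on_change``) and, if the new level
    reaches ``message_min_level``, one message.  Gated changes produce no
    cues; the level stream itself is never filtered here.
    """
    cues: list[CueEvent] = []
    for e in level_events:
        if e.kind != "level_change":
            continue
        if not config.permits(activity_at(activity_intervals, e.t)):
            continue
        if config.vibrate_on_change:
            cues.append(CueEvent(t=e.t, kind="vibration", level=e.level))
        if e.level >= config.message_min_level:
            cues.append(
                CueEvent(t=e.t, kind="message", level=e.level,
                         text=config.message_text)
            )
    return cues


def write_cues(cues: Sequence[CueEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cues:
            fh.write(json.dumps(
                {"t": c.t, "kind": c.kind, "level": c.level, "text": c.text}
            ) + "\n")


def read_cues(path: str | Path) -> list[CueEvent]:
    cues = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            cues.append(CueEvent(t=d["t"], kind=d["kind"], level=d["level"],
                                 text=d.get("text", "")))
    return cues
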
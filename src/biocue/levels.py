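"""Arousal-level quantization and level-change event streams.

Heart rate is mapped to a discrete arousal level relative to the personal
baseline: with z = (bpm − mean)/SD, the level is ceil(z) clamped to the
integer range [−3, 5].  Interior bands are exactly one baseline SD wide and
closed on the right — z in (k−1, k] maps to level k — so level 3 begins
strictly above 2 SD, which is exactly the feedback-message condition the
cueing policy keys on.

:func:`process_stream` runs the quantizer statefully over a sample stream:
every reliable sample yields a ``measurement`` event, and a ``level_change``
event is emitted whenever the quantized level leaves the current state.
Unreliable samples are logged but never move the state, so sensor artifacts
cannot drive cues.  An optional hysteresis margin (in SD units) requires z
to travel beyond the current band's edge by that margin before a change
fires, for deployments where band-edge chatter produces too many cues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .baseline import BaselineModel
from .hrstream import HeartRateSample

LEVEL_MIN = -3
LEVEL_MAX = 5


@dataclass(frozen=True)
class LevelEvent:
    """A measurement or level-change entry in the engine's event stream."""

    t: float
    kind: str  # "measurement" | "level_change"
    bpm: float
    z: float
    level: int
    previous_level: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("measurement", "level_change"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "level_change" and self.level == self.previous_level:
            raise ValueError("level_change requires level != previous_level")


def quantize(bpm: float, baseline: BaselineModel) -> int:
    """Quantize a heart rate into an arousal level in [−3, 5].

    level = clamp(ceil((bpm − mean)/sd), −3, 5); boundary z = k maps to k.
    Monotone non-decreasing in bpm; level ≥ 3 iff z > 2.
    """
    if not baseline.sd_bpm > 0:
        raise ValueError("baseline SD must be positive")
    z = (bpm - baseline.mean_bpm) / baseline.sd_bpm
    return max(LEVEL_MIN, min(LEVEL_MAX, math.ceil(z)))


def _band_edges(level: int) -> tuple[float, float]:
    """The z-band (lower, upper] occupied by ``level``, with clamps open-ended."""
    lower = float("-inf") if level == LEVEL_MIN else float(level - 1)
    upper = float("inf") if level == LEVEL_MAX else float(level)
    return lower, upper


def process_stream(
    samples: Iterable[HeartRateSample],
    baseline: BaselineModel,
    hysteresis_sd: float = 0.0,
) -> list[LevelEvent]:
    """Quantize a stream statefully, emitting measurement and change events.

    The state initializes to the first reliable sample's level (logged as a
    measurement, not a change).  With ``hysteresis_sd`` h > 0 a change fires
    only once z has moved at least h beyond the current level's band edge;
    with h = 0 this is pure band-crossing, equivalent to per-sample
    re-quantization followed by adjacent change detection.
    """
    if hysteresis_sd < 0:
        raise ValueError("hysteresis_sd must be non-negative")
    if not baseline.sd_bpm > 0:
        raise ValueError("baseline is incomplete or degenerate (SD must be > 0)")

    events: list[LevelEvent] = []
    current: int | None = None
    for s in samples:
        z = (s.bpm - baseline.mean_bpm) / baseline.sd_bpm
        if not s.reliable:
            # logged for the timeline; never updates level state
            events.append(
                LevelEvent(t=s.t, kind="measurement", bpm=s.bpm, z=z,
                           level=current if current is not None else 0)
            )
            continue
        level = quantize(s.bpm, baseline)
        if current is None:
            current = level
            events.append(
                LevelEvent(t=s.t, kind="measurement", bpm=s.bpm, z=z, level=level)
            )
            continue
        lower, upper = _band_edges(current)
        crossed = z > upper + hysteresis_sd or z <= lower - hysteresis_sd
        events.append(
            LevelEvent(t=s.t, kind="measurement", bpm=s.bpm, z=z,
                       level=level if crossed else current)
        )
        if crossed and level != current:
            events.append(
                LevelEvent(t=s.t, kind="level_change", bpm=s.bpm, z=z,
                           level=level, previous_level=current)
            )
            current = level
    return events


def write_events(events: Sequence[LevelEvent], path: str | Path) -> None:
    """Append-friendly JSON-lines serialization of an event stream."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({
                "t": e.t, "kind": e.kind, "bpm": e.bpm, "z": e.z,
                "level": e.level, "prev": e.previous_level,
            }) + "\n")


def read_events(path: str | Path) -> list[LevelEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(LevelEvent(
                t=d["t"], kind=d["kind"], bpm=d["bpm"], z=d["z"],
                level=d["level"], previous_level=d.get("prev"),
            ))
    return events
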
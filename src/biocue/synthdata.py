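"""Seeded synthetic wearable heart-rate scenarios with ground truth.

The simulator emulates the statistical structure the biocueing engine
assumes of wrist PPG heart rate sampled at a fixed cadence:

    HR(t) = baseline_mean + circadian(t) + activity(t) + episode(t) + eps,
    eps ~ Normal(0, baseline_sd), i.i.d.

* ``circadian(t)`` is a flat reduction inside a local-clock night window
  (default 00:00–06:00), sized so night heart rate can drop below 50 bpm
  and exercise the adherence correction downstream.
* ``activity(t)`` adds a per-label elevation during scheduled activity
  intervals (walking, running, ...), which also feed the engine as the
  recognizer's label stream.
* ``episode(t)`` models transient arousal episodes as trapezoids: a linear
  ramp up over ``ramp_s``, a plateau at ``amplitude_sd`` baseline-SD units,
  and a symmetric ramp down — slow- versus fast-onset arousal differ only
  in the ramp.
* each sample is independently flagged unreliable with ``unreliable_prob``
  (a dropout, not a value perturbation: the engine must ignore it either
  way).

The same (seed, config) always yields the identical stream.  Ground truth
(episode windows and amplitudes, night intervals, per-sample components) is
returned alongside, and :func:`detection_metrics` scores message cues
against it as sensitivity and false alerts per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np

from .cueing import CueEvent
from .hrstream import ACTIVITY_LABELS, ActivityInterval, HeartRateSample, \
    validate_intervals

#: Scenarios start at 08:00 UTC so a 24 h run spans one full night window.
DEFAULT_START_EPOCH = datetime(2021, 6, 7, 8, 0, tzinfo=timezone.utc).timestamp()

DEFAULT_ACTIVITY_ELEVATION_BPM: Mapping[str, float] = {
    "still": 0.0,
    "walking": 15.0,
    "running": 45.0,
    "cycling": 30.0,
    "in_vehicle": 0.0,
    "unknown": 0.0,
}


class ScenarioConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EpisodeSpec:
    """A transient arousal episode: trapezoid in baseline-SD units.

    ``onset_s`` is relative to scenario start; the episode occupies
    [onset_s, onset_s + duration_s] with linear ramps of ``ramp_s`` at each
    end (triangular if 2*ramp_s exceeds the duration).
    """

    onset_s: float
    duration_s: float
    amplitude_sd: float
    ramp_s: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.ramp_s < 0:
            raise ScenarioConfigError("episode duration must be positive, ramp >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    duration_h: float = 24.0
    cadence_s: float = 20.0
    baseline_mean_bpm: float = 65.0
    baseline_sd_bpm: float = 5.0
    circadian_dip_bpm: float = 20.0
    night_window: tuple[float, float] = (0.0, 6.0)  # local clock hours
    tz_offset_min: int = 0
    start_epoch: float = DEFAULT_START_EPOCH
    activity_schedule: tuple[ActivityInterval, ...] = ()
    activity_elevation_bpm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_ELEVATION_BPM)
    )
    episodes: tuple[EpisodeSpec, ...] = ()
    unreliable_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.unreliable_prob <= 1:
            raise ScenarioConfigError("unreliable_prob must lie in [0, 1]")
        if self.duration_h <= 0 or self.cadence_s <= 0:
            raise ScenarioConfigError("duration and cadence must be positive")
        if self.baseline_sd_bpm < 0 or self.circadian_dip_bpm < 0:
            raise ScenarioConfigError("SD and dip amplitudes must be non-negative")
        if not set(self.activity_elevation_bpm) <= ACTIVITY_LABELS:
            raise ScenarioConfigError("unknown labels in activity_elevation_bpm")
        end = self.duration_h * 3600
        for ep in self.episodes:
            if ep.onset_s < 0 or ep.onset_s + ep.duration_s > end:
                raise ScenarioConfigError(
                    f"episode [{ep.onset_s}, {ep.onset_s + ep.duration_s}] s "
                    f"outside scenario duration {end} s"
                )
        validate_intervals(self.activity_schedule)


@dataclass(frozen=True)
class ScenarioGroundTruth:
    """Simulator truth: what a perfect detector would find."""

    episodes: tuple[tuple[float, float, float], ...]  # (onset, offset, peak_sd), epoch s
    night_intervals: tuple[tuple[float, float], ...]  # epoch s
    duration_s: float
    components: dict  # per-sample arrays: t, baseline, circadian, activity,
    #                   episode, noise, bpm, reliable


@dataclass(frozen=True)
class DetectionMetrics:
    sensitivity: float | None  # None when the scenario has no episodes
    false_alerts_per_hour: float
    n_episodes: int
    n_detected: int
    n_false_alerts: int


def _night_mask(t: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    local = t + config.tz_offset_min * 60.0
    hour = (local % 86400.0) / 3600.0
    lo, hi = config.night_window
    if lo <= hi:
        return (hour >= lo) & (hour < hi)
    return (hour >= lo) | (hour < hi)  # window wrapping midnight


def _night_intervals(config: ScenarioConfig) -> tuple[tuple[float, float], ...]:
    lo, hi = config.night_window
    start, end = config.start_epoch, config.start_epoch + config.duration_h * 3600
    off = config.tz_offset_min * 60.0
    day0 = np.floor((start + off) / 86400.0)
    out = []
    for day in np.arange(day0 - 1, (end + off) / 86400.0 + 1):
        a = day * 86400.0 + lo * 3600.0 - off
        b = day * 86400.0 + hi * 3600.0 - off
        a, b = max(a, start), min(b, end)
        if a < b:
            out.append((a, b))
    return tuple(out)


def _episode_profile(t_rel: np.ndarray, ep: EpisodeSpec) -> np.ndarray:
    """Trapezoid in [0, amplitude_sd] over [onset, onset + duration]."""
    ramp = min(ep.ramp_s, ep.duration_s / 2.0)
    x = t_rel - ep.onset_s
    up = np.clip(x / ramp, 0.0, 1.0) if ramp > 0 else (x >= 0).astype(float)
    down = (np.clip((ep.duration_s - x) / ramp, 0.0, 1.0) if ramp > 0
            else (x <= ep.duration_s).astype(float))
    inside = (x >= 0) & (x <= ep.duration_s)
    return ep.amplitude_sd * np.where(inside, np.minimum(up, down), 0.0)


def simulate(
    config: ScenarioConfig,
) -> tuple[list[HeartRateSample], list[ActivityInterval], ScenarioGroundTruth]:
    """Generate a heart-rate stream, activity intervals and ground truth.

    Deterministic: identical (seed, config) gives an identical stream.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_h * 3600.0 / config.cadence_s))
    t_rel = np.arange(n) * config.cadence_s
    t = config.start_epoch + t_rel

    circadian = np.where(_night_mask(t, config), -config.circadian_dip_bpm, 0.0)

    activity = np.zeros(n)
    for iv in config.activity_schedule:
        elev = config.activity_elevation_bpm.get(iv.label, 0.0)
        activity[(t >= iv.start) & (t < iv.end)] += elev

    episode_sd = np.zeros(n)
    for ep in config.episodes:
        episode_sd += _episode_profile(t_rel, ep)
    episode = episode_sd * config.baseline_sd_bpm

    noise = rng.normal(0.0, config.baseline_sd_bpm, n)
    bpm = np.maximum(
        config.baseline_mean_bpm + circadian + activity + episode + noise, 1.0
    )
    reliable = rng.random(n) >= config.unreliable_prob

    samples = [
        HeartRateSample(t=float(ti), bpm=float(b), reliable=bool(r))
        for ti, b, r in zip(t, bpm, reliable)
    ]
    truth = ScenarioGroundTruth(
        episodes=tuple(
            (config.start_epoch + ep.onset_s,
             config.start_epoch + ep.onset_s + ep.duration_s,
             ep.amplitude_sd)
            for ep in config.episodes
        ),
        night_intervals=_night_intervals(config),
        duration_s=config.duration_h * 3600.0,
        components={
            "t": t, "baseline": np.full(n, config.baseline_mean_bpm),
            "circadian": circadian, "activity": activity, "episode": episode,
            "noise": noise, "bpm": bpm, "reliable": reliable,
        },
    )
    return samples, list(config.activity_schedule), truth


def quiescent_mask(truth: ScenarioGroundTruth) -> np.ndarray:
    """Samples unaffected by night dip, activity or episodes (noise only)."""
    c = truth.components
    return (c["circadian"] == 0) & (c["activity"] == 0) & (c["episode"] == 0)


def detection_metrics(
    cue_events: Sequence[CueEvent],
    truth: ScenarioGroundTruth,
    match_window_s: float,
) -> DetectionMetrics:
    """Score message cues against true episodes by interval matching.

    An episode counts as detected if any message cue falls within
    [onset − w, offset + w]; a message cue matching no episode is a false
    alert, rated per simulated hour.  With zero true episodes sensitivity
    is undefined and reported as ``None``.
    """
    if match_window_s <= 0:
        raise ValueError("match_window_s must be positive")
    messages = [c.t for c in cue_events if c.kind == "message"]
    detected = 0
    for onset, offset, _amp in truth.episodes:
        if any(onset - match_window_s <= mt <= offset + match_window_s
               for mt in messages):
            detected += 1
    false = sum(
        1 for mt in messages
        if not any(onset - match_window_s <= mt <= offset + match_window_s
                   for onset, offset, _amp in truth.episodes)
    )
    hours = truth.duration_s / 3600.0
    return DetectionMetrics(
        sensitivity=None if not truth.episodes else detected / len(truth.episodes),
        false_alerts_per_hour=false / hours,
        n_episodes=len(truth.episodes),
        n_detected=detected,
        n_false_alerts=false,
    )
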
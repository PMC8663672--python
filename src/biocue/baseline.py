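"""Personal heart-rate baseline calibration.

The engine's reference frame is a personal baseline: the mean and standard
deviation of heart rate accumulated over a calibration window.  Calibration
walks the incoming stream in time order and *admits* a sample only if it is
reliable, falls outside any excluded-activity interval, and arrives at least
one nominal cadence after the previously admitted sample (faster-than-cadence
input is down-sampled).  It completes at the moment the required count of
admitted samples is reached; everything after that instant is ignored.

Two presets mirror the two study deployments of the engine: the evaluation
preset requires 200 admitted samples at 20 s spacing with running/cycling
excluded; the design preset requires 300 and imposes no activity exclusion
(its calibration instruction was purely behavioral).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .hrstream import ActivityInterval, HeartRateSample, activity_at

DEFAULT_REQUIRED_N = 200
DEFAULT_INTERVAL_S = 20.0
DEFAULT_EXCLUDED_ACTIVITIES = frozenset({"running", "cycling"})
#: Lower bound on the baseline SD, bpm.  A near-constant calibration stream
#: would otherwise make 1-SD level bands arbitrarily narrow.
DEFAULT_SD_FLOOR = 1.0


class IncompleteCalibrationError(RuntimeError):
    """Stream exhausted before the required sample count was admitted."""

    def __init__(self, admitted: int, required: int):
        super().__init__(
            f"calibration incomplete: {admitted} of {required} samples admitted"
        )
        self.admitted = admitted
        self.required = required


@dataclass(frozen=True)
class BaselineModel:
    """Calibrated personal baseline: the quantizer's reference frame.

    ``sd_bpm`` is the floored SD actually used for quantization;
    ``raw_sd_bpm`` keeps the pre-floor sample SD for provenance.
    """

    mean_bpm: float
    sd_bpm: float
    raw_sd_bpm: float
    n_samples: int
    interval_s: float
    started_at: float
    completed_at: float
    excluded_activities: frozenset[str] = field(default_factory=frozenset)

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["excluded_activities"] = sorted(self.excluded_activities)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BaselineModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["excluded_activities"] = frozenset(d["excluded_activities"])
        return cls(**d)


def calibrate(
    samples: Iterable[HeartRateSample],
    activity_intervals: Sequence[ActivityInterval] = (),
    required_n: int = DEFAULT_REQUIRED_N,
    interval_s: float = DEFAULT_INTERVAL_S,
    excluded_activities: Iterable[str] = DEFAULT_EXCLUDED_ACTIVITIES,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> BaselineModel:
    """Accumulate admitted samples until ``required_n`` is reached.

    Admission rule, applied in stream order: the sample is reliable, its
    activity label is not excluded, and its timestamp is at least
    ``interval_s`` after the previously admitted sample (the first candidate
    is always cadence-eligible).  Mean is the arithmetic mean and SD the
    sample (n−1) standard deviation of the admitted subset; ``sd_bpm`` is
    floored at ``sd_floor``.

    Raises
    ------
    IncompleteCalibrationError
        If the stream ends before ``required_n`` samples are admitted.
    """
    if required_n < 2:
        raise ValueError("required_n must be at least 2")
    if not interval_s > 0:
        raise ValueError("interval_s must be positive")
    if not sd_floor > 0:
        raise ValueError("sd_floor must be positive")
    excluded = frozenset(excluded_activities)

    admitted: list[HeartRateSample] = []
    last_t: float | None = None
    for s in samples:
        if not s.reliable:
            continue
        if excluded and activity_at(activity_intervals, s.t) in excluded:
            continue
        if last_t is not None and s.t - last_t < interval_s:
            continue
        admitted.append(s)
        last_t = s.t
        if len(admitted) == required_n:
            break
    if len(admitted) < required_n:
        raise IncompleteCalibrationError(len(admitted), required_n)

    values = [s.bpm for s in admitted]
    mean = math.fsum(values) / required_n
    raw_sd = math.sqrt(
        math.fsum((v - mean) ** 2 for v in values) / (required_n - 1)
    )
    return BaselineModel(
        mean_bpm=mean,
        sd_bpm=max(raw_sd, sd_floor),
        raw_sd_bpm=raw_sd,
        n_samples=required_n,
        interval_s=interval_s,
        started_at=admitted[0].t,
        completed_at=admitted[-1].t,
        excluded_activities=excluded,
    )


def calibrate_evaluation_preset(
    samples: Iterable[HeartRateSample],
    activity_intervals: Sequence[ActivityInterval] = (),
) -> BaselineModel:
    """200 admitted samples at 20 s cadence; running/cycling excluded."""
    return calibrate(samples, activity_intervals, required_n=200)


def calibrate_design_preset(
    samples: Iterable[HeartRateSample],
    activity_intervals: Sequence[ActivityInterval] = (),
) -> BaselineModel:
    """300 admitted samples at 20 s cadence; no activity exclusion (the
    design deployment placed no behavioral restrictions on calibration)."""
    return calibrate(
        samples, activity_intervals, required_n=300, excluded_activities=()
    )
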
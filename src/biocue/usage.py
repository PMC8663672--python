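"""Adherence (actual-use) metric from heart-rate sample counts.

A wearable's total number of heart-rate measurements, converted to hours
at the nominal cadence, indicates how long the system was actually in use.
Raw counts overstate use, because devices keep measuring overnight and
sometimes while not worn; the corrected metric therefore excludes samples
with implausibly low heart rate (< 50 bpm by default) and samples whose
local clock time falls in a night window (midnight–6 AM by default).

Hours are computed as retained_count x cadence / 3600 rather than from
inter-sample gaps: the indicator is a measurement count, and the cadence
is the device's fixed sampling period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .hrstream import HeartRateSample

DEFAULT_LOW_HR_THRESHOLD = 50.0
DEFAULT_NIGHT_WINDOW = (0.0, 6.0)  # local clock hours, half-open
DEFAULT_CADENCE_S = 20.0


@dataclass(frozen=True)
class UsageReport:
    """Raw and corrected usage hours with exclusion bookkeeping.

    A sample excluded for both reasons is counted once, as night
    (precedence night > low-HR), so the counts always reconcile:
    retained + n_excluded_night + n_excluded_low_hr = n_total.
    """

    raw_hours: float
    corrected_hours: float
    n_total: int
    n_retained: int
    n_excluded_low_hr: int
    n_excluded_night: int
    low_hr_threshold: float
    night_window: tuple[float, float]
    tz_offset_min: int
    cadence_s: float


def _is_night(t: float, night_window: tuple[float, float], tz_offset_min: int) -> bool:
    hour = ((t + tz_offset_min * 60.0) % 86400.0) / 3600.0
    lo, hi = night_window
    if lo <= hi:
        return lo <= hour < hi
    return hour >= lo or hour < hi


def usage_hours(
    samples: Sequence[HeartRateSample],
    low_hr_threshold: float = DEFAULT_LOW_HR_THRESHOLD,
    night_window: tuple[float, float] = DEFAULT_NIGHT_WINDOW,
    tz_offset_min: int = 0,
    cadence_s: float = DEFAULT_CADENCE_S,
) -> UsageReport:
    """Compute raw and corrected usage hours for a sample stream.

    A sample is retained iff bpm >= ``low_hr_threshold`` and its local
    clock time lies outside the (half-open) night window; the local clock
    is the sample's UTC timestamp shifted by ``tz_offset_min`` minutes.
    """
    if cadence_s <= 0:
        raise ValueError("cadence_s must be positive")
    n_total = len(samples)
    n_night = n_low = n_retained = 0
    for s in samples:
        if _is_night(s.t, night_window, tz_offset_min):
            n_night += 1
        elif s.bpm < low_hr_threshold:
            n_low += 1
        else:
            n_retained += 1
    return UsageReport(
        raw_hours=n_total * cadence_s / 3600.0,
        corrected_hours=n_retained * cadence_s / 3600.0,
        n_total=n_total,
        n_retained=n_retained,
        n_excluded_low_hr=n_low,
        n_excluded_night=n_night,
        low_hr_threshold=low_hr_threshold,
        night_window=night_window,
        tz_offset_min=tz_offset_min,
        cadence_s=cadence_s,
    )
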
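# Methods

## The biocueing model

The engine assumes a wearer whose heart rate, sampled every ~20 s by a
wrist PPG sensor, fluctuates around a stable personal mean with roughly
Gaussian short-term variability, and whose episodes of emotional arousal
manifest as transient elevations of that rate.  Arousal is therefore
expressed in *baseline-SD units*: after calibration of a personal mean
`μ` and SD `σ`, each sample's standardized deviation `z = (bpm − μ)/σ` is
quantized into an integer level

```
level = clamp(⌈z⌉, −3, 5)
```

Interior bands are exactly one SD wide and closed on the right: `z` in
`(k−1, k]` maps to level `k`.  This is the unique uniform 1-SD banding on
the −3…5 range under which level 3 begins strictly above `z = 2`, so the
policy "show the feedback message at levels 3, 4 and 5" coincides exactly
with the condition "more than 2 SD above baseline".  The clamps absorb
everything beyond: `z > 4` is level 5, `z ≤ −3` is level −3.

### Calibration

Calibration walks the stream in time order and admits a sample iff it is
(a) reliable, (b) outside every excluded-activity interval, and (c) at
least one nominal cadence after the previously admitted sample; it
completes at the instant the required count is admitted, and later input
can never alter the model.  Mean is the arithmetic mean and SD the
sample (n−1) standard deviation of the admitted subset — an unbiased
finite-window estimate.  Two presets exist: *evaluation* (200 admitted
samples, running/cycling excluded) and *design* (300 samples, no activity
exclusion, since that deployment placed no behavioral restrictions on the
calibration window).

The admit-then-space rule (reliability checked before cadence spacing)
is a convention: a device could equally space first.  The two orders
differ only on streams faster than the cadence.

### Cue policy

Every level change in a permitted activity context vibrates; a change
whose *new* level reaches the message threshold additionally shows the
message, once per qualifying transition — never per sample while
elevated, which would multiply an already high notification volume.
Decreases cue identically to increases.  Activity gating suppresses cues
only: measurement, quantization and the timeline continue, so data
utility is preserved whichever way "pausing" is configured.  Unreliable
samples are logged as measurements but never move the level state, so
sensor artifacts cannot drive cues.

An optional hysteresis margin `h` (SD units, default 0) requires `z` to
travel at least `h` beyond the current band's edge before a change fires.
At `h = 0` the state machine is exactly per-sample re-quantization plus
adjacent change detection (tests assert this equivalence).  The stream's
initial state is the first reliable sample's level, logged without a
change event, matching that reading.

## Tunable parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `required_n` | samples | 200 (eval) / 300 (design) | calibration counts of the two deployments |
| `interval_s` | s | 20 | the device's PPG sampling cadence |
| `sd_floor` | bpm | 1.0 | a constant stream would otherwise make bands degenerate; bounds sensitivity at 1 bpm/level |
| `excluded_activities` | — | {running, cycling} | proxy for "intense physical activity" during calibration; configurable, off in the design preset |
| reliability window | bpm | [30, 220] | plausibility bounds for wrist HR; the sensor flag alone misses motion artifacts |
| `message_min_level` | level | 3 | the >2 SD message condition |
| `hysteresis_sd` | SD | 0 | pure band crossing; raise to damp band-edge chatter |
| usage `low_hr_threshold` | bpm | 50 | below-plausible readings counted as non-wear |
| usage `night_window` | local clock | [00:00, 06:00) | nighttime correction window; half-open to avoid double counting at the edges |

## The scenario simulator

Synthetic scenarios follow

```
HR(t) = μ + circadian(t) + activity(t) + episode(t) + ε,   ε ~ N(0, σ) i.i.d.
```

with defaults μ = 65 bpm and σ = 5 bpm (typical resting wrist HR and
short-term variability for an adult), a flat −20 bpm dip inside the night
window (putting night HR near 45 bpm, below the 50-bpm usage threshold,
so the adherence correction is exercised), per-label activity elevations
(walking +15, cycling +30, running +45 bpm), and trapezoidal arousal
episodes — linear ramps of configurable duration into a plateau at a
configurable amplitude in SD units, so slow- and fast-onset arousal
differ only in the ramp.  Each sample is independently flagged unreliable
with a configurable probability.  Scenarios start at 08:00 by default so
a 24-h run spans one full night.  Identical (seed, config) yields a
byte-identical stream (`numpy` PCG64 generator).

What the simulator deliberately does **not** emulate: autocorrelated
heart-rate variability (RSA, baroreflex), gradual circadian ramps,
correlated dropout bursts, or accelerometer signals (activity labels are
generated as truth, not inferred).  The engine uses only mean and SD, so
richer structure would add nothing the tests could distinguish — but it
also means passing tests bound the engine's behavior on *this* noise
model, not the false-alert rate to expect on real, autocorrelated wrist
data (real PPG noise is burstier; real arousal is not trapezoidal).

Detection quality is scored by interval matching: an episode counts as
detected if any message cue lands within `[onset − w, offset + w]`; cues
matching no episode are false alerts, rated per simulated hour.  With no
true episodes sensitivity is undefined and reported as `None`.

## Instrument scoring and statistics

SUS: `score = (Σ_odd (r−1) + Σ_even (5−r)) × 2.5`, range 0–100, no
proration (a missing item is an error).  Other instruments score as item
*means* on the native response scale — a 1–5 instrument scores in 1–5 —
with reverse-keyed items reflected (`r → max+min−r`) and proration by the
mean of answered items when at least 80 % of a (sub)scale's items are
answered (a common psychometric convention); below that the score is a
missing marker, never a number.  The bundled AQ-SF/STAXI-2/ABSQ configs
carry **synthetic placeholder item mappings** (correct item counts,
ranges and subscale names; invented assignments): the real mappings are
licensed content and must be supplied as YAML/JSON by the user.

Wilcoxon matched pairs: differences post − pre; zeros dropped by default
(Pratt's zero-rank method by flag); |d| ranked with average ties;
`W = min(W+, W−)`.  The two-sided p is exact — full enumeration of all
2^n sign assignments — for effective n ≤ 15, since with ties the exact
distribution is not available from standard library routines; beyond
that, a normal approximation with `Var = Σr²/4` (which with average ranks
*is* the tie correction) and a 0.5 continuity correction.  Z carries the
sign of `W+ − W−`.  Correlations are Pearson by default (Spearman by
flag) with df = n − 2 and the t-transform p.  Two-sided throughout; no
multiple-testing correction is applied.

## Numerical conventions and degenerate inputs

- Band boundaries: `z` exactly integer `k` maps to level `k` (ceil).
- `mean`/SD use compensated summation (`math.fsum`); tests pin agreement
  with an independent two-pass computation to 1e−9.
- SD floor 1.0 bpm prevents division by zero for constant calibration
  streams (the floored model reports `raw_sd_bpm` separately).
- Empty streams: `process_stream` returns an empty sequence; `usage_hours`
  returns 0 h; neither is an error.
- All-zero Wilcoxon differences: degenerate result (W = 0, p = 1,
  n_effective = 0), flagged, not an error.
- Usage exclusion precedence is night-then-low-HR, so a nighttime
  bradycardic sample is counted once and the report always reconciles:
  retained + night + low = total.
- Simulated bpm is floored at 1.0 so extreme noise cannot produce
  non-physical non-positive rates.

## Test problem sizes

The suites run on deliberately small scenarios: calibration streams of a
few hundred samples, 1.5–6 h simulated scenarios, 20–50 seeds for the
stochastic properties (parameter recovery within `3σ/√200` in ≥ 95 % of
50 runs; detection sensitivity averaged over 20 seeds per episode
amplitude).  These sizes give the properties sharp expected outcomes
while keeping the whole suite in seconds.

## Known limitations

- The reliability criterion (sensor flag AND 30–220 bpm) is this
  package's convention; deployed devices define confidence differently.
- The engine is single-signal: no skin conductance, respiration or HRV
  features, and no adaptive/rolling baseline — a baseline drifts with
  fitness, medication and season, which a fixed calibration ignores.
- False-alert rates measured on the simulator's i.i.d. noise are not
  predictions for real wrist data.
- Usage correction cannot distinguish genuine daytime wear from a device
  left measuring on a nightstand when readings stay plausible.
- Participant-level study outcomes (group SUS means, usage-hour
  distributions, clinical pre/post medians) require item- and
  participant-level data that were never published; the package scores
  such data when supplied but ships none.
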
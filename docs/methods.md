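# Methods

This note documents the detection procedure, its parameters, the synthetic
data it is validated on, and the numerical choices made where the design
was genuinely open.

## Signals and conventions

Airflow is a uniformly sampled series in arbitrary device units (typically
200 Hz from a PSG export); SpO₂ is stored internally as a saturation
*fraction* in [0, 1] (files in percent are auto-converted when the values
exceed 1.5). All times are seconds from recording start and all events are
half-open intervals `[start, end)`, which avoids double counting at shared
boundaries. The hypnogram is a sequence of 30-s epochs labelled W, N1, N2,
N3 or R.

## Apnea detection (local range)

`LR(t) = max − min` of the airflow over `[t, t + Δt)`, evaluated every
0.5 s with Δt = 10 s — the clinical minimum duration of a breathing event,
so a window fully inside an apnea sees no normal breath. LR is positively
homogeneous in the signal and invariant to offsets, hence insensitive to
baseline drift but *scale-dependent*: the thresholds below apply to 1/LR in
inverse device units and must be recalibrated for hardware with different
gain (`optimize_thresholds` automates this).

The implementation assembles window extrema from per-step block extrema
when the window is a whole multiple of the step (the default: 2000-sample
windows, 100-sample steps), and reduces a strided view otherwise. Both
paths are contractually bit-identical to the naive per-window loop, which
the tests enforce against a brute-force oracle.

Event rule: maximal runs of grid points with 1/LR > Tₐ are candidates;
each run is extended by Δt (detection lags the window start by up to one
window, and the extension restores the clinical minimum duration:
`duration = super-Tₐ dwell + Δt`); runs whose extended intervals overlap
are *joined into one candidate* — dense super-Tₐ peaks separated by less
than one window belong to one physiological event. A candidate becomes an
apnea iff it contains at least one point with 1/LR > T꜀. Joining before
confirmation is the only ordering that keeps three desired properties
simultaneously: detected events are disjoint, every event lasts ≥ Δt, and
raising T꜀ can only remove events (monotonicity). Strict `>` is used at
both thresholds. LR is clamped to `lr_floor = 1e-9` before inversion so a
flat-lined sensor (LR = 0) reads as a confirmed apnea — complete cessation
of airflow is the definition of the event.

Threshold search: the default grid is Tₐ ∈ {5, 10, 15, 20} ×
T꜀ ∈ {15, 20, 25, 30, 35}; pairs violating Tₐ < T꜀ are skipped. For each
pair the detector runs on every recording and is scored event-by-event
against the annotations; both the overcheck (FP) and miss (FN) rates use
the annotated total as denominator, and the pair minimizing their sum
wins, ties broken toward smaller Tₐ then smaller T꜀ (deterministic
output). The sum is typically flat in Tₐ — Tₐ shapes durations, T꜀ decides
existence — so the tie-break matters and tends to return the smallest
equivalent Tₐ.

## SpO₂ sudden-drop detection

A drop runs from onset t₁ (last sample at the pre-drop plateau) to nadir
t₂ and is accepted iff `Q(t₁) − Q(t₂) ≥ min_drop` (default 0.03) **and**
`(Q(t₁) − Q(t₂))/(t₂ − t₁) > k₀` (default 0.001 fraction/s, i.e. 0.1
percentage points per second: a minimal 3% drop must complete within 30 s,
matching the lookback horizon used downstream). The event duration is
`(t₂ − t₁) + t₀`, where t₀ — the valley dwell — ends when the signal first
rises `valley_recovery` (default 0.01) above the nadir.

The scan is a single forward pass: advance to a descent start, track the
falling signal while tolerating counter-rises ≤ `valley_recovery`
(oximeter noise), record the nadir, then re-anchor t₁ as the last pre-nadir
sample within `onset_tol` (default 0.0025) of the pre-nadir maximum, walked
back up any monotone descent. The re-anchoring matters with noise: without
it a long noisy plateau preceding the drop dilutes the measured slope and a
genuine desaturation fails the slope rule; on noiseless traces it reduces
exactly to "last plateau sample", which the worked-example tests pin down.
A second dip beginning before the signal recovered `min_drop / 2` above the
previous nadir extends the previous candidate instead of opening a new one
(one physiological desaturation, not two). An optional 1-s median filter
(`spo2_median_filter_s`, default off) is available for noisier inputs.

## Merging and the report

Desaturations lag their cause by a patient-specific delay, observed to lie
between the event onset and its end plus ~30 s. Each drop is therefore
attributed to an apnea — and discarded — when its descent `[t₁, t₂]`
intersects `[apnea start, apnea end + lookback_s)` (default 30 s);
surviving drops are hypopneas. Testing the whole descent rather than only
the onset makes the rule robust to an onset anchored a second or two
before the apnea begins; a surviving drop whose recovery tail reaches into
a neighbouring event is clipped so the merged list stays disjoint. A drop
overlapping two apneas is discarded once.

`AHI = (nA + nH) / T` with T the total sleep time in hours (epochs not
labelled W, times 30 s). Severity: AHI < 5 normal, [5, 15) mild, [15, 30)
moderate, ≥ 30 severe (boundaries inclusive on the left). The report also
carries per-type event rates and the percentage of sleep time occupied by
events (using detector durations), a cumulative-burden statistic that
correlates strongly with the AHI. Degraded modes: without SpO₂ the report
is apnea-only with hypopnea fields null; without a hypnogram the recording
span stands in for sleep time, loudly flagged (`sleep_time_assumed`).

## Evaluation

Detected and reference events are matched one-to-one greedily by greatest
temporal overlap (> 0 s required; ties → earlier reference, then earlier
detection); unmatched references are misses, unmatched detections
overchecks. Matching ignores the apnea/hypopnea label by default since
both count equally toward the AHI; `by_type=True` and a minimum-overlap
fraction are available. Miss and overcheck rates are both relative to the
reference total; PPV to the detected total. Cohort agreement on AHI,
apnea/h, hypopnea/h and duration percentage uses
`RMSE = sqrt(mean((X_auto − X_manual)²))` over patients, with both columns
produced by the same report arithmetic.

## Synthetic nights

The generator emulates exactly the features the detector consumes:

* **Breathing**: a sinusoid with per-breath period jitter (±20 % around
  0.25 Hz) and amplitude jitter (±15 % around a 0.2-unit peak-to-peak),
  multiplied by an event envelope — residual amplitude fraction 0.1 in
  apneas, 0.4 in hypopneas — plus Gaussian sensor noise with sd 1 % of the
  normal peak-to-peak (0.002 units). The calibration puts normal breathing
  at 1/LR ≈ 5 (below Tₐ = 10), hypopneas at ≈ 11 (above Tₐ but safely
  below T꜀, so airflow alone must not flag them) and apneas at ≈ 30–33
  once noise is included (above T꜀ = 25).
* **Flow artifacts**: shallow-breathing spells of 12–25 s with residual
  amplitude 0.18–0.25 and *no* desaturation, excluded from ground truth —
  the synthetic analogue of sighs, position changes and sub-criterion flow
  reductions in real airflow. They land at 1/LR ≈ 16–22, between the
  confirmation candidates: a grid search with T꜀ ≤ 20 overchecks on them
  while T꜀ = 25 does not, and T꜀ = 35 starts missing true apneas, giving
  the threshold optimization a genuine interior optimum. Without any such
  structure every T꜀ below the apnea level scores identically and the
  optimum is degenerate.
* **SpO₂**: baseline 0.97 minus one trapezoidal desaturation per event
  (depth U[0.03, 0.08]; fall U[10, 20] s so the slope rule holds by
  construction; valley U[5, 20] s; recovery U[20, 40] s — resaturation is
  slower than desaturation), onset delayed U[5, 25] s after the event
  start, clipped to 0.8× the event duration so the drop begins while its
  event is ongoing; overlapping depressions combine by maximum. Sensor
  noise sd 0.001 — oximeters average internally, so SpO₂ noise is far
  smaller than the 3 % criterion.
* **Hypnogram**: 10 % wake epochs placed as a sleep-onset block, a final
  awakening and brief mid-night arousals; stages sampled N1/N2/N3/R with
  probabilities 0.1/0.5/0.2/0.2. Events and artifacts are placed only
  inside sleep, at least 75 s apart (enforced ≥ 60 s), by rejection
  sampling; impossible requests raise a `GenerationError`.

Default event load is 20 apneas + 10 hypopneas per 8-h night, durations
U[12, 60] s — a mild-range night that still exercises every code path;
`generate_cohort` jitters counts (±25 %) and breathing amplitude (±10 %)
per patient from spawned seeds. All randomness derives from one master
seed via `numpy.random.SeedSequence`; no global state is touched.

**What passing on these nights does and does not show.** The generator
makes the detector's assumptions true by construction: amplitude collapse
is instantaneous and uniform, desaturations are clean trapezoids, the
SpO₂ baseline is stationary and there is no body-position or
sensor-displacement drift, no central/obstructive morphology, and no
ambiguous boundary events. Near-perfect recovery here validates the
implementation and the internal consistency of the rules — not clinical
performance, which depends on exactly the confounds the generator omits.

## Known limitations

* Thresholds are global, not patient-adaptive; device gain changes require
  recalibration of (Tₐ, T꜀).
* Hypopneas are recognized only through desaturation; arousal-terminated
  hypopneas without a 3 % drop are invisible to the method.
* No central-vs-obstructive subtype classification (no effort channels).
* The valley-dwell definition (`valley_recovery`) is a convention; the
  event-duration tail is sensitive to it, the event counts are not.
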
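# Methods

## Background and scope

The mobile approach–avoidance task (mAAT) shows food images on a phone and
asks the participant to pull the phone toward their face (approach) or push
it away (avoidance) depending on the image category. The phone's inertial
sensors record each response. `mobileaat` turns those raw traces into the
task's two behavioral measures — motion-onset reaction time and movement
distance — applies the task's validity rules, and runs the planned
statistics (2×2 repeated-measures ANOVAs, Wilcoxon signed-rank tests,
Pearson correlations). A minimum-jerk simulator generates whole cohorts
with known ground truth so every stage is testable without human data.

The stimulus-presentation app, participant recruitment, and rating-scale
administration are out of scope; explicit ratings (valence, arousal,
wanting on 0–100 scales) and food-neophobia totals are accepted as inputs.

## Signal model and preprocessing

A trial's trace is timestamped 3-axis acceleration in the device frame
(optionally with rotational rate, carried through but unused). The device
axis convention is `+z_toward_face`: positive z displacement is a pull.

Because the phone is at rest before the stimulus (the task only advances
once it is), gravity plus accelerometer bias is estimated as the per-axis
mean over a **rest window** (default 0.3 s) before stimulus onset and
subtracted as a constant. No orientation tracking is attempted: responses
last well under a second, so rotation-induced error in the constant-gravity
assumption is second order, and the onset criterion operates on the
rotation-invariant magnitude anyway. Devices that expose a linear
accelerometer skip the subtraction.

Phone sampling is irregular, so traces are linearly interpolated onto a
uniform grid (default **100 Hz**; linear, not spline, to avoid overshoot at
the movement edge), then low-pass filtered with a zero-phase 4th-order
Butterworth at **20 Hz** (configurable off). The zero-phase (forward–
backward) filter suppresses tremor and sensor noise that would otherwise
trip the fixed component of the onset threshold, without shifting the
onset. Whether the original processing chain filters before thresholding
is not documented; the filter is this package's choice and `lowpass_hz:
null` disables it for comparisons.

## Reaction time

Motion onset is the first sample of the response window whose gravity-free
acceleration magnitude strictly exceeds

    threshold = max(0.8, 0.3 · a_max)   [m/s²]

where `a_max` is the maximum magnitude within the current trial's response
window (default 2 s; the image disappears after 2 s and the trial counts as
a "no reaction"). The adaptive term scales the criterion to the vigor of
this particular response; the 0.8 m/s² floor keeps noise from triggering on
feeble ones. `a_max` is per-trial, not per-block: the trial is the task's
unit and the criterion must adapt per response. RT is the time from
stimulus onset to motion onset in milliseconds. First-sample-strictly-above
is the tie-break; on noiseless simulated movements the detected onset is
never earlier than the true onset minus one sample, and systematically late
by one to two samples (the magnitude must *rise* to the threshold), i.e. a
+10–20 ms bias at 100 Hz that is identical across conditions and therefore
cancels from all within-design contrasts.

## Movement distance

The distance measure is defined here as the double time-integral of the
movement-axis (z) acceleration over the outward stroke:

* velocity = cumulative trapezoid of a_z from onset, with v(onset) = 0
  (the phone starts at rest);
* the stroke ends at the first sample after the outward velocity peak where
  the signed velocity falls to ≤1% of that peak, capped at 1 s (flagged when
  capped);
* distance = |cumulative trapezoid of velocity| at the stroke end.

Two numerical details matter. The outward velocity peak is located after
latching the *initial* movement direction, because with a return stroke the
global |v| extremum can fall in the return phase and would otherwise drag
the segment end past it, cancelling the displacement. And the 1%-of-peak
zero tolerance absorbs residual baseline bias, whose integral keeps the
velocity a hair off zero at the true stroke end; at 100 Hz this moves the
detected end by at most one sample on clean strokes.

The published description of the distance measure ("derived using the
magnitude and the duration of the acceleration") does not print a formula;
this double-integration definition is a declared interpretation, chosen
because it has closed-form oracles (constant-acceleration and minimum-jerk
profiles) and because truncating at the outward-phase end is forced by the
task: the participant immediately returns the phone, so whole-trial
displacement is ≈0 by design and "distance" must mean peak excursion.
Sub-second single-axis integration keeps drift second order; no further
drift correction is applied. Because integration starts at the *detected*
(slightly late) onset with v=0, distances carry a small negative bias
(≈5–7% for typical strokes), again common to all conditions.

Observed direction is the sign of the net z displacement over the segment
(positive pull, negative push); |displacement| < 1 cm is `undetermined`.

## Validity rules

Per trial: RT < 200 ms → `too_fast` (whole trial discarded — "discarded"
is read as trial-level, so the distance is excluded too); RT > 2000 ms or
no threshold crossing → `no_reaction`; unprocessable trace (no usable rest
baseline, empty window) → `no_onset`. Statuses partition trials. Per
participant: less than 75% valid trials → excluded as incomplete; exactly
75% is included. Trials whose observed direction contradicts the
instruction stay valid but are flagged — no direction-error exclusion is
applied, the flag supports sensitivity analyses. Only experimental trials
enter the 75% accounting (practice trials are never represented here).

## Aggregation and statistics

Cell means (participant × category × direction, valid trials only) are the
unit of analysis. RT score = push − pull (positive = approach motivation);
distance score = mean of pull and push (distance effects in this task are
direction-independent).

The 2×2 repeated-measures ANOVA is computed from explicit sums of squares,
each effect tested against its own effect-by-subject interaction with df
(1, n−1). With two-level factors sphericity holds trivially and each F
equals the squared paired t on the corresponding within-participant
contrast — used as an independent oracle in the tests, alongside pingouin.
Participants missing any cell are dropped listwise (logged); the paper's
handling is unstated and complete cells are what classical RM-ANOVA
requires. F, df, p and partial η² are reported (the original report gives
only p).

Wilcoxon signed-rank: zero differences dropped, mid-ranks for ties,
W = min(W+, W−); exact two-sided p by convolution over the (possibly
half-integer) rank lattice for n ≤ 15, continuity-corrected normal
approximation with tie correction above. Exact-vs-approximate choice and
tie handling are declared defaults, not inferred from the original
report. Pearson correlations use the product-moment r with p from the t
distribution (scipy). All tests are two-sided at α = 0.05; no
multiple-testing correction is applied, matching the analysis plan.

## Simulator

Movements are minimum-jerk strokes x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵) along z —
the standard smooth point-to-point reaching model, with analytic velocity
and acceleration (peak |a| = (10/√3)·D/T²) giving exact oracles. A trial
is: 0.5 s pre-stimulus rest (the fixation interval), stimulus onset, the
planted latency, the outward stroke, a 0.15 s hold, a mirrored return
stroke, tail rest; traces always cover the full 2 s response window.
Gravity is a constant vector; sensor imperfection is i.i.d. Gaussian noise
per axis (default sd 0.05 m/s²) plus Gaussian clock jitter (default sd
1 ms, clipped below half a sample step so timestamps stay monotone).

Experiment defaults mirror the task design: 71 participants, 4 categories ×
2 directions × 20 trials (10 unique images per category, two presentations
per direction), base RT 650 ms with 60 ms between-participant and 100 ms
within-participant sd, a 30 ms congruency effect split ±effect/2 (congruent
pairings: pull-palatable, push-unpalatable, pull-dutch, push-asian) so the
direction and category margins stay flat and the interaction carries the
effect, displacement ≈0.25 m scaled by a category arousal gain, stroke
duration U(0.3, 0.5) s. Planted rating means follow the expected ordering
(valence/wanting high for palatable and own-culture food; arousal high for
unpalatable and own-culture food). Realistic distributions of phone-AAT
peak accelerations are not published; D ≈ 0.2–0.3 m and T ≈ 0.3–0.5 s are
declared assumptions.

`simulate_experiment(emit="metrics")` emits the planted per-trial RT and
distance directly as a metrics table, skipping trace synthesis. The
power/type-I replication studies (hundreds of cohorts) use this path
through the QC + statistics layers: trace processing contributes ~10 ms
quantization noise against the 100 ms planted RT noise, so its effect on
the interaction test is negligible, and trace-level recovery is validated
separately. What the simulator does *not* emulate: phone-specific noise
spectra, rotational dynamics, grip variability, attention lapses and
anticipations — so passing recovery tests demonstrate correctness of the
processing chain under the stated signal model, not robustness to every
real-world artifact.

## Problem sizes and numerical choices

Default analyses in the test suite and acceptance script use: 500 single
trials for RT recovery (clean 100 Hz sampling — with the default 1 ms clock
jitter a 10 ms-grid-aligned latency makes the ±20 ms bound a knife edge by
construction; jittered sampling is covered by the resampling oracle and the
cohort recovery report); a 12-participant trace-level cohort (1920 trials)
for the end-to-end run; 200 effect and 500 null metric-level replicates at
40 participants for power and type-I calibration. Uniform-grid checks use
relative tolerance 1e-6; the trapezoid integration error is O(Δt²)
(verified by grid halving). Degenerate inputs — impulse-only traces, empty
response windows, all-zero differences, zero-variance correlates — return
flagged results or raise typed errors rather than propagating NaNs.

## Known limitations

* The distance definition is an interpretation of an unpublished formula;
  absolute distances carry a small systematic underestimate (detection-delay
  bias), though condition contrasts are unaffected.
* Constant-baseline gravity removal ignores in-movement rotation; strongly
  rotating responses misattribute some gravity to linear acceleration.
  Gyroscope data is parsed and stored but unused.
* The RM-ANOVA is specialized to 2×2 within designs (the study's design);
  larger factorial layouts are out of scope.
* Sessions are processed independently; no hierarchical/trial-level
  modeling is offered.
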
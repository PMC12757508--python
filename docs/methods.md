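# Methods

## The task and the measurement problem

In the olfactory habituation/dishabituation (OHD) task a rodent is presented
with each odor stimulus in a block of repeated trials. Investigation of a
repeated odor declines (habituation); switching to a novel odor restores it
(dishabituation). An automated olfactometer variant of the task presents each
stimulus by opening its odorant valve for 60 s and then flushing with clean
air for 60 s, so a trial is a 2 min window anchored at a valve onset. A
session comprises a 5 min chamber habituation, a 6-trial clean-valve noise
habituation phase (12 min), and 12 testing trials — three consecutive
presentations of each of four stimuli: clean-air control (CLN), two nonsocial
odors (NSA, NSB), and a same-sex urine social odor (SOC) — for 24 min of
testing.

`ohdkit` implements the full downstream analysis: schedule and valve-log
handling, telemetry/tracking ingestion, automatic investigation scoring,
and effect estimation, plus a synthetic-session generator that produces
valve logs, VOC telemetry, and centroid trajectories with known ground truth.

## Valve scheduling and trial windows

The apparatus feeds air through exactly one valve at a time: the
normally-open clean-air valve (id 0) or one of four odorant valves (ids 1–4).
`schedule_to_valve_events` realizes a schedule under this exclusivity rule
(close-then-open pairs at each switch) and `validate_valve_events` replays
any log, reporting instants with zero or multiple open valves.

Trial windows span valve onset to the next trial onset (ON + OFF, nominally
120 s). Whether investigation should be tallied over the full 2 min window
or the 60 s ON phase only is genuinely open; the default is the full window,
matching the 2 min presentations of the classic hand-run task, and the window
bounds are explicit in every API so an ON-only analysis is a one-line change.
Clean-control "trials" produce no valve transitions, so they are invisible in
a log; `trial_windows` infers them by dividing inter-onset gaps of roughly
*k* trial periods into *k* equal windows (and `windows_from_schedule` is the
preferred, unambiguous path whenever the schedule is known). Segmentation
between consecutive onsets absorbs sub-second onset jitter.

## Telemetry

tVOC telemetry is sampled at ~260 ms at both chamber inlets; raw readings
span 0–32,768 ppb and saturate near 29,000 ppb. Parsing enforces the sensor
range and strictly increasing timestamps, naming the offending row.
Per-second summaries average readings in left-closed buckets [k, k+1);
empty buckets are reported missing, never interpolated. Per-trial summaries
average the per-second values of buckets fully inside the window and take
the peak raw reading in the window. Bottle screening passes a bottle iff
the median of its readings (relative to baseline air) lies in the inclusive
30–70 ppb band; the median is robust to the occasional transient spike in
short screening runs.

## Automatic investigation scoring

Scoring operates on centroid pixel coordinates calibrated at
`mm_per_pixel` (0.458 in the reference setup). Distance from the primary
(odor) end is the signed projection onto the tube axis, clipped at zero.
A frame counts as investigation iff:

1. the centroid lies between `inner_cm` (2 cm) and `outer_cm` (6 cm) from
   the primary end — at 0.458 mm/pixel these are the 44 px and 132 px
   boundaries, obtained with a ceiling conversion (the unique simple rule
   reproducing both printed thresholds); and
2. the motion state is *toward* the primary end, during or after the motion:
   direction is the sign of the distance displacement over a centered window
   (default ≈ 0.25 s of frames, threshold `motion_epsilon_mm` = 2 mm), and
   stationary frames inherit the most recent non-stationary direction, so a
   pause after an approach still counts. A leading stationary run counts as
   no direction. A frame closer than the inner boundary is treated as the
   subject turning away and never counts; a bout therefore ends at the first
   *away* frame or on leaving the zone.

Maximal runs of investigating frames become bouts; an n-frame bout lasts
n/avg_fps seconds. Bouts are intersected with trial windows (straddling
bouts are split) to give per-trial durations. Manually scored intervals
import through the same path; overlapping annotation rows are merged to
their union first. The direction window length and threshold are not
dictated by any published value; both are configurable, and the brute-force
per-frame oracle in the test suite pins the semantics exactly.

## Effect statistics

Only presentations 1 and 3 (first and final) enter the analysis. For each
analysis unit (a subject–session pair by default, pooling sessions as
independent replicates; configurable via `unit_keys`):

- habituation effect per stimulus: duration(p3) − duration(p1), negative
  under habituation;
- dishabituation effect per adjacent stimulus pair: duration(next, p1) −
  duration(prev, p3), positive under dishabituation.

Each effect is summarized by the mean per-unit difference with a percentile
bootstrap CI (units resampled with replacement; default B = 10,000, 95%
level, deterministic given a seed). The bootstrap-distribution median is
reported alongside the mean. The percentile method is the simplest scheme
consistent with a plain "bootstrapped 95% CI" and is first-order accurate:
at n ≈ 100 its empirical coverage is 94–96%, while at n = 24 it covers
≈ 93% for Normal data (P(|t₂₃| ≤ 1.96·√(23/24)) ≈ 0.932) — a known
small-sample property of the method, worth keeping in mind when reading CIs
from small cohorts. BCa or t-intervals would tighten this but add machinery
the analysis does not otherwise need.

Significance uses a two-sided sign-flip permutation test on the per-unit
differences: exact enumeration of all 2ⁿ sign assignments when 2ⁿ ≤ n_perm
(p = #{|mean*| ≥ |mean|}/2ⁿ), Monte-Carlo with the add-one correction
otherwise. Holm's step-down correction is applied across the whole family
of effects. Mixed-effects models are deliberately not fitted here: the
pipeline exports the model-ready long-format table (presentations {1,3},
plus a full variant) for lme4/statsmodels or any other tool.

## The synthetic-session generator

The generator exists so every stage can be validated end to end with known
ground truth; it emulates the statistical structure the analysis assumes,
not the physics of a real chamber.

**VOC kinetics.** First-order rise/decay: during ON the primary-inlet
concentration relaxes toward the stimulus plateau with τ_rise (default
10 s); during OFF it decays toward baseline with τ_decay (default 20 s).
Defaults anchor to the apparatus' operating points: baseline 50 ppb, odor
plateaus 11,500 ppb (stimuli are diluted to peak in the 10,000–13,000 ppb
band), readings rounded, floored at 0, capped at 29,000 ppb inside the
0–32,768 ppb sensor range, sampled every 260 ms. Gaussian sensor noise
(default SD 5 ppb) is added before capping; the secondary (positive
pressure) inlet stays at baseline plus noise. The noiseless trajectory
matches the closed-form exponential to 1 ppb (rounding included).

**Behavior.** The subject's axial position follows a discrete-time
mean-reverting (Ornstein–Uhlenbeck) walk at the video frame rate, reflected
into the 152.4 mm tube. Each second the walk's target is redrawn: the
attraction point (30 mm, inside the 20–60 mm investigation zone) with
probability `attract_gain × salience_s × r^(p−1)` (clipped at 1), else a
rest point at 90 mm. Defaults: salience CLN:NSA:NSB:SOC = 0.05:1:1:2.5,
habituation ratio r = 0.6, attract_gain = 0.3 — so SOC draws the subject
75% of seconds on its first presentation and 27% on its third, producing
first-presentation investigation times of tens of seconds and strong decay
across presentations, in the range typical of OHD sessions. The
per-presentation decay applies to odorant stimuli only: the clean-air
control elicits odor-independent baseline exploration, which does not
habituate — this is what lets the control act as a negative control in the
effect analysis. θ = 1.5 s⁻¹ and σ = 10 mm/√s give a stationary spread of
≈ 6 mm, fast enough to reach a new target within ~2 s and tight enough that
a resting subject essentially never drifts into the investigation zone
(the zone boundary sits > 5 SD from the rest point), which is the
generator's null-agent contract: zero salience ⇒ zero ground-truth bouts.

**Ground truth.** Truth bouts are obtained by applying the *same* zone and
direction rule to the exact (un-quantized) trajectory; the exported trace
is rounded to integer pixels with small lateral jitter. Scorer validation
therefore measures only what the pipeline can control — pixel quantization
at the zone and motion thresholds — and end-to-end recovery is within two
frames per bout boundary. Component streams (VOC, agent, per-subject)
derive from the master seed by fixed offsets, so fixtures are byte-identical
given a seed.

**What the generator does not emulate.** Airflow and plume dynamics, sensor
warm-up and drift, body posture (the centroid stands in for the animal; the
snout-based manual rule is reachable only through imported annotations),
grooming bouts, tracking dropouts, and any coupling between VOC level and
behavior. Passing tests show the *analysis* is correct under the assumed
behavioral structure; they are not evidence about real mice.

## Problem sizes in the test and acceptance runs

The suite validates the bout detector against a brute-force per-frame
classifier on 1,000+ random traces (10–250 frames each), end-to-end
ground-truth recovery on 20 full 24-minute sessions at 30 fps, bootstrap
coverage on 1,000 simulated Normal cohorts (n = 100, B = 1,000),
permutation-null uniformity by exact enumeration at n = 10, and the
qualitative effect pattern on a full 24-subject simulated cohort
(B = 4,000). The whole suite runs in well under a minute on one core.

## Known limitations

- The investigation rule scores the centroid, not the snout; automatic and
  manual scores are kept distinct (`method` column) and never mixed.
- Clean-trial inference from a bare valve log assumes trial periods are
  near-nominal; heavily irregular logs should be paired with their schedule.
- The percentile bootstrap's small-n undercoverage (above).
- Effect estimates pool subject–session replicates without modeling the
  within-subject correlation across sessions; the long-format export exists
  precisely so a mixed model can account for it.
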
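# ohdkit

Analysis pipeline for automated **olfactory habituation/dishabituation
(OHD)** sessions run on an olfactometer, written for behavioral
neuroscientists who score rodent odor investigation from valve logs, VOC
telemetry, and video tracking.

In the OHD task each odor is presented in a block of repeated trials;
investigation declines across repeats (**habituation**) and rebounds when a
novel odor appears (**dishabituation**). An olfactometer variant presents a
stimulus by opening its odorant valve for 60 s then flushing with clean air
for 60 s, so trials are 2 min windows anchored at valve onsets. A standard
testing session is 12 trials — three consecutive presentations of each of
clean-air control (CLN), two nonsocial odors (NSA, NSB), and a same-sex
urine social odor (SOC) — for 24 min.

The package covers the full path from raw session files to effect estimates:

- **`ohdkit.paradigm`** — build stimulus schedules, emit/validate valve event
  logs (exactly one valve open at any instant), and segment logs into trial
  windows.
- **`ohdkit.telemetry`** — read/write telemetry CSVs (tVOC in ppb at both
  chamber inlets, 0–32,768 ppb sensor range, ~260 ms sampling) and tracking
  CSVs; per-second and per-trial VOC summaries; odorant-bottle screening
  (median in the 30–70 ppb band).
- **`ohdkit.scoring`** — automatic investigation scoring: a frame counts iff
  the centroid is 2–6 cm from the primary (odor) end (44–132 px at
  0.458 mm/pixel) during or after motion toward that end; frames < 2 cm are
  treated as turning away. Bouts are aligned to trial windows; manual
  annotations import through the same path.
- **`ohdkit.stats`** — habituation effects (presentation 3 − presentation 1,
  negative under habituation) and dishabituation effects (next stimulus
  p1 − previous stimulus p3, positive under dishabituation), each with a
  seeded percentile-bootstrap 95% CI, a sign-flip permutation p-value
  (exact when 2ⁿ ≤ n_perm), Holm correction across the family, and a
  long-format export for external mixed-model fitting.
- **`ohdkit.simulate`** — synthetic sessions with ground truth: first-order
  VOC rise/decay kinetics with sensor saturation, and a mean-reverting-walk
  subject whose attraction to the odor end scales with stimulus salience and
  decays geometrically across presentations.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a default 24-min session, score it, then estimate effects on a
24-subject simulated cohort:

```python
from ohdkit.paradigm import windows_from_schedule
from ohdkit.scoring import ZoneRule, detect_bouts, score_trials, scores_to_frame
from ohdkit.simulate import generate_session, simulate_cohort
from ohdkit.stats import compute_effects

fx = generate_session(seed=7, outdir="demo")          # events/telemetry/trace + truth
zone = ZoneRule.for_fps(30)
windows = windows_from_schedule(fx.schedule)
scores = score_trials(detect_bouts(fx.trace, zone), windows, subject="M01")
print(scores_to_frame(scores))

cohort = simulate_cohort(n_subjects=24, seed=7)       # full pipeline per subject
effects = compute_effects(cohort, stimulus_order=["CLN", "NSA", "NSB", "SOC"],
                          n_boot=4000, n_perm=2000, seed=7)
print(effects.round(2))
```

The single-session scores show the expected within-subject pattern
(investigation of NSA falling 20.6 s → 7.4 s across its three presentations,
SOC 50.4 s → 16.5 s, clean air flat at ~1 s), and the cohort effect table:

```
          kind stimulus  point_s  boot_median_s  ci_low_s  ci_high_s  n  p_perm  p_holm
   habituation      CLN     0.07           0.08     -0.20       0.35 24    0.63    0.63
   habituation      NSA   -12.43         -12.41    -13.73     -11.08 24    0.00    0.00
   habituation      NSB   -13.65         -13.65    -14.81     -12.46 24    0.00    0.00
   habituation      SOC   -31.57         -31.61    -33.09     -29.93 24    0.00    0.00
dishabituation CLN->NSA    18.84          18.85     17.60      20.13 24    0.00    0.00
dishabituation NSA->NSB    13.78          13.76     12.22      15.30 24    0.00    0.00
dishabituation NSB->SOC    42.76          42.77     41.60      43.81 24    0.00    0.00
```

Negative habituation effects with CIs excluding zero for every odor (but not
for clean air), and positive dishabituation — largest into the social
stimulus — is the signature OHD pattern.

The same workflow is available from the shell:

```sh
ohdkit simulate --seed 7 --outdir demo/
ohdkit schedule --out events.csv
ohdkit voc-summary --telemetry demo/telemetry.csv --events demo/events.csv --out voc.csv
ohdkit score --trace demo/trace.csv --events demo/events.csv --subject M01 --out scores.csv
ohdkit stats --scores scores.csv --seed 7 --out effects.csv --long-out long.csv
```

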
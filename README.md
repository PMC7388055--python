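# lapskill

A headless assessment engine for basic psychomotor skills in minimally
invasive surgery (MIS).  Contactless gesture-tracked box trainers record the
3D motion of two laparoscopic instrument tips while a trainee performs
abstract skill tasks; turning those motion logs into objective scores is the
computational core of such a simulator, and that core is what this package
implements — without any rendering, device driver, or GUI.

`lapskill` is aimed at surgical-education researchers and simulator builders
who need a reproducible, scriptable scoring pipeline: it defines six classic
trainer tasks (grip and placement, object transfer, bimanual traversal,
instrument withdrawal/reinsertion, diathermy, and combined manipulation with
diathermy), detects interaction events in instrument-tip trajectories,
computes the standard motion metrics, and produces per-attempt (immediate)
and across-attempt (terminal) feedback reports.  A seeded synthetic-
trajectory simulator stands in for the tracking hardware so every part of
the pipeline can be exercised, validated, and benchmarked without human
data.

## The metrics and the score

Performance on a task is summarised by five parameters:

* **Time** `T` — task duration (s).
* **Efficiency of movement** per hand — the excess of the actual tip-path
  length over the ideal path length, `E = max(0, L_actual − L_ideal)` (mm),
  together with the time the tip spent outside a corridor of radius 10 mm
  around the ideal path (s).
* **Economy of diathermy** `D` — excess burn time: for each on-target
  electrocautery activation of duration `d`, the excess is
  `max(0, d − 2 s)`; only activations strictly longer than 2 s are
  penalised.
* **Errors** — nine weighted error classes (shaft-rather-than-tip contact
  with a target, hitting the workspace limits, undue target contacts,
  container-margin contacts, instrument clashes, excess oval contacts,
  off-path time, off-target diathermy, excess burn time), each applicable to
  a fixed subset of the six tasks.
* **Final score**

  ```
  S = 100 − Σᵢ nᵢ · vᵢ
  ```

  where `nᵢ` is the number of errors of class *i* and `vᵢ ∈ [1, 5]` its
  weight (1 least, 5 most important; off-target diathermy carries the
  maximum weight 5).  Continuous quantities enter the sum through their own
  error classes, discretised as ceil-of-seconds.  Higher is better; the
  score is not clamped below zero unless asked.

Instrument kinematics honour the fulcrum effect: the rigid shaft always
passes through a fixed trocar pivot at the body-wall entry point, and
withdrawal/reinsertion is detected as the tip crossing a depth threshold
along the insertion axis.

## Worked example

Simulate one novice session of Task 5 (diathermy: cauterise five targets on
a fixed sphere) and score it:

```
$ lapskill simulate --task 5 --profile novice --seed 42 --out sim
wrote task5_novice_seed42.csv (9640 samples, 160.7 s)

$ lapskill score --task 5 --trajectory sim/task5_novice_seed42.csv --out scored
final score 42 (completed)
```

`scored/result.json` holds the full metric set.  For this session:

```
final_score            42.0
time_s                 160.7
completed              true
economy_excess_burn_s  4.32
tally                  WORKSPACE_BOUNDARY: 9, DIATHERMY_OFF_TARGET: 4,
                       EXCESS_BURN_TIME: 5
```

Reading: the simulated novice completed the task but took 160.7 s, hit the
workspace limits 9 times (weight 2 → 18 points), activated diathermy away
from a designated target 4 times (weight 5 → 20 points), and over-held
on-target burns for 4.32 s in total (ceil → 5 counts, weight 4 → 20
points), so `S = 100 − 58 = 42`.  An expert profile under the same seed
scores at or near 100.  `scored/events.jsonl` lists every detected episode
with sub-sample interval bounds; `lapskill report` aggregates attempts into
a terminal-feedback series (score, time and error count per attempt, plus
the first-to-last score trend).

The same pipeline is available as a library (`lapskill.simulate_trajectory`,
`lapskill.detect_events`, `lapskill.score_session`,
`lapskill.generate_cohort`), and the scene geometry, error weights and
detection thresholds are all overridable via JSON configs.

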
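# Methods

This note documents the models, conventions and numerical choices behind
`lapskill`: what is computed, under which assumptions, and which defaults
were genuinely open design decisions.

## Coordinate frame and scene

All geometry lives in a right-handed frame in millimetres: origin at the
centre of the sensor pad, +y up, +z toward the user.  The default workspace
is a 200 mm cube centred 150 mm above the pad (inside the usable volume of a
consumer optical hand/instrument tracker, roughly 20–600 mm above the
device).  The two trocar pivots sit at (±60, 40, 60) mm — below and in front
of the workspace, like body-wall ports.  None of these dimensions is
canonical; all are overridable through scene JSON, and the defaults were
chosen once so that the six task layouts fit comfortably with clearance
between scene objects, instrument shafts and workspace walls.

Shapes (spheres, finite cylinders, axis-aligned boxes) are closed sets:
boundary contact counts as contact, a conservative choice for error
detection.  A *hollow* cylinder is a container whose contact surface is the
cylindrical wall only — entering through the open end is not a contact.

Each task's *ideal path* is an open polyline per hand.  Paths begin at a
per-hand rest position, pass through the task's working waypoints, and (for
the withdrawal task) include the return leg, so that a perfect execution
has zero excess path length by construction.

## Tasks and completion criteria

| # | Task | Completion |
|---|------|------------|
| 1 | Grip and placement | sphere released while inside the goal container |
| 2 | Transfer and placement | grasped by two distinct hands, then released inside the hollow cylinder |
| 3 | Bimanual traversal ("cross") | ≥ 95 % of each hand's path arc length visited within the 10 mm corridor |
| 4 | Withdrawal and reinsertion | required number of reinsertions by the configured hand (default 1) |
| 5 | Diathermy | every designated target has at least one on-target burn |
| 6 | Manipulation + diathermy | sphere placed in the cube *and* all targets burned |

Task 3 is bimanual (no dominant-hand option); all other tasks mirror their
scene across the x = 0 plane when the dominant hand is switched.  The
number of cautery targets (default 5) and the permitted oval contacts in
task 4 (default 2) are configurable; neither has a canonical value.  The
cautery targets sit on a horizontal arc of the base sphere: with the
targets at one height, the shaft — which descends steeply toward the
pivot — clears the neighbouring targets while one is being burned, so a
clean execution commits no shaft-contact errors.

## Event detection

Contact events are maximal intervals of a thresholded distance signal.
Interval bounds are linearly interpolated on the signal at threshold
crossings (sub-sample precision); where a bound is forced by a state change
rather than a crossing (e.g. the object becomes held), it pins to the
sample time.  Detection never assumes uniform sampling.

Defaults (all `DetectionParams` fields):

* **contact tolerance** ε = 1 mm beyond a surface;
* **debounce** 100 ms — contact episodes separated by a shorter gap merge.
  Burn episodes (a sampled binary pedal state) and off-path intervals (a
  continuous time integral; merging across a gap would count on-path time
  as off-path) are *not* debounced;
* **tip zone** 5 mm — the distal shaft length that counts as "tip".
  Off-tip contact requires the truncated shaft within ε of the target
  *while the tip is farther than one tip-zone length from contact*: a
  contact that close to the tip is tip approach, not shaft contact
  (without this the shaft-start point trails through the contact band on
  every tip-first approach);
* **grasp radius** 10 mm — a jaw closing within this of the object grasps
  it; a closing jaw of the non-holding hand takes the object over
  (hand-off);
* **corridor** 10 mm around the ideal path for off-path classification and
  traversal credit;
* **clash distance** 2 mm between the two full shafts;
* **withdrawal** is the tip's depth along the insertion axis (pivot →
  workspace centre) dropping below 60 mm, reinsertion is rising above
  70 mm — 10 mm hysteresis against chatter.

Error-counting rules that were genuinely open:

* *Undue target contacts* (tasks 1–2): a tip-target contact episode is
  **exempt** when the hand grasps the object during it (the grasp is the
  task, not an error) or when it is the disengagement immediately after
  that hand released or handed over the object.  A re-touch after clean
  disengagement counts.
* A released, resting ("parked") object is out of play for off-tip contact
  until re-grasped; the depositing instrument's shaft otherwise
  unavoidably grazes the just-released sphere on the way out.
* Oval contacts count only beyond the permitted number.
* Burn episodes are attributed on/off-target by the tip position at
  activation; the nearest designated target within ε wins.

## Metrics and the score

The five parameters are time, per-hand efficiency of movement, economy of
diathermy, the error tally, and the final score `S = 100 − Σ nᵢvᵢ`.
Efficiency of movement is described in the source material by two
non-equivalent phrasings — time outside the ideal path and
actual-minus-ideal path length — so both are computed and reported.  Only
the printed score formula exists, so the continuous quantities reach the
score exclusively through their own error classes, discretised as
ceil-of-seconds (OFF_PATH_TIME, weight 1/s-class; EXCESS_BURN_TIME,
weight 4).  This keeps the printed formula exact rather than inventing a
second one.

Only one weight is fixed by the source (off-target diathermy = 5).  The
other eight defaults (off-tip 3, oval excess 3, excess burn 4, the contact
and boundary counts 2, off-path 1) respect the stated 1–5 importance
ordering and are fully user-configurable; they are declared defaults, not
reconstructions.  The score is not clamped below 0 by default (information
would be destroyed); a clamp option exists for display parity.

`S = 100` if and only if the tally is empty, and `S` strictly decreases
with every added error — both are tested invariants.

## The synthetic-trajectory simulator

The simulator emulates a two-handed operator, not a sensor: for each task
it scripts waypoints that execute the completion criterion, interpolates
between them with minimum-jerk profiles (the standard smooth-reach model),
and adds two Ornstein–Uhlenbeck noise processes per hand — fast tremor
(correlation time 0.15 s) and slow lateral path deviation (correlation
time 0.8 s).  Noise amplitude is modulated by planned tip speed between
0.3× (dwelling on a precision action) and 1× (mid-transport), a
speed–accuracy trade-off without which a novice-level tremor would defeat
every grasp and burn.  Long reaches split into 30 mm sub-moves with a
per-waypoint hesitation pause.  Sampling is 60 Hz (a typical optical
tracker rate); the detection layer never relies on that rate.

Errors are injected explicitly at profile-dependent rates and logged:
boundary excursions (12 mm beyond a wall, 0.35 s dwell), instrument-clash
sweeps (the tips sweep through each other so the shafts must cross),
open-jaw target pokes, container-wall drags, off-tip shaft placements
(tip parked 25 mm beyond the target along the pivot ray), off-target burns
(≥ 25 mm from any target) and on-target over-holds.  Deep injections
(boundary, off-target burn, poke-to-centre, off-tip) are geometrically
guaranteed to be detectable; thin-surface injections (container wall,
clash) are implemented as sweeps *through* the surface, which makes
detection robust to tremor but means the episode count is a consequence of
the actual noisy trajectory rather than a fixed per-injection number.  For
that reason the manifest carries, besides the injected-event list, the
**ground-truth tally of the final trajectory**, annotated by an
independent per-sample reference classifier (`lapskill.reference`) at
debounce 0.  The reference classifier is a plain-loop restatement of the
detection conventions that shares only the scalar geometry primitives with
the production detector; the production detector is held to exact
agreement with it in the tests, and the geometry primitives are checked
separately against dense-sampling brute force.

Default skill profiles (chosen once as plausible for a first-time novice,
a trainee with some box-trainer hours, and an experienced MIS surgeon):

| parameter | novice | intermediate | expert |
|---|---|---|---|
| speed (mm/s) | 25 | 60 | 110 |
| tremor SD (mm) | 3.0 | 1.8 | 0.8 |
| path deviation SD (mm) | 8.0 | 4.0 | 2.0 |
| overshoot / blunder prob. | 0.5 | 0.25 | 0.05 |
| boundary hits (/min/hand) | 8 | 2.5 | 0.2 |
| clashes (/min) | 4 | 1.5 | 0.1 |
| off-target burn prob./target | 0.5 | 0.2 | 0.02 |
| burn over-hold SD (s) | 1.2 | 0.6 | 0.2 |
| hesitation per waypoint (s) | 2.0 | 0.8 | 0.2 |
| wanders (/min/hand) | 6 | 2 | 0 |

These yield median final scores near 100 for the expert on every task and
novice medians tens of points lower, with novice sessions 5–15× longer —
the pattern classically reported for box-trainer metrics.  Determinism is
strict: one named RNG (`numpy` PCG64) seeded from the user's seed, no
global state; identical (task, profile, seed) give bitwise-identical
trajectory files.

**What the simulator does not emulate:** sensor noise and dropouts of the
optical tracker (its ~0.7 mm accuracy informs nothing here; the "operator"
is noisy, the "sensor" is perfect), occlusion artefacts, instrument
rotation about its own axis, jaw kinematics beyond a binary state,
gravity/physics on the released object (it rests where released), fatigue
or learning within a session, and genuinely human error patterns —
injections are independent events at fixed rates.  Passing tests therefore
show that the *pipeline* is correct and discriminates the simulated skill
construct; they are not evidence about real surgeons.

## Numerical choices and degenerate inputs

* Interval boundaries interpolate linearly on the distance signal; ties at
  exactly the threshold resolve to "contact" (closed sets).
* `ceil` discretisation applies only to strictly positive totals (0 s off
  path → 0 errors).
* Segment–segment distance uses the clamped closed-form minimisation with
  a parallel-case fallback; degenerate (zero-length) query segments are
  handled as points.  Instrument shafts are validated non-degenerate (a
  tip exactly at the pivot is an error).
* Trajectories require ≥ 2 samples and strictly increasing timestamps;
  files may omit one hand entirely, which is reconstructed as parked at
  its pivot with the jaw open.
* CSV output prints floats with 17 significant digits (exact double
  round-trip); reading uses correctly-rounded float parsing.
* Seeds for cohort generation derive from the base seed by counter modulo
  2³¹ − 1.

## Problem sizes in the shipped tests

Oracle-equivalence suites use ≥ 100 randomised instances per query type
and ~100 random short trajectories (2–2.5 s, 60 Hz) across the six tasks;
manifest recovery runs 6 tasks × 10 seeded novice sessions; the skill-
separation check runs 50 seeds per (task, profile) cell with annotation
disabled.  These sizes keep the full suite around three minutes on one CPU
while leaving each statistical margin wide (the smallest observed
expert–novice median gap is several times the required 10 points).

## Known limitations

* The stored-data schema of the original embedded database is not public;
  the CSV/JSON-Lines trajectory dialect and the per-subject JSON session
  store are declared replacements, not reconstructions.
* Eight of the nine error weights are package defaults, not published
  values.
* The traversal-completion rule (≥ 95 % arc-length coverage) and all
  detection thresholds are engine conventions; different front-ends could
  reasonably choose others, which is why every one of them is a parameter.
* Off-tip contact in task 3 has no applicable target object in the default
  scene (the traversal tube is the working surface, not a protected
  target), so that class, while formally applicable, stays zero there.
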
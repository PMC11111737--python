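# Methods

## The estimation problem

A 2D regression gaze tracker maps an *eye feature* vector
`e = (e1, e2, e3, e4)` — two gaze-direction components built from the pupil
centre and two head components built from the eye corner, all in
video-image pixels — to a screen point `g = (gx, gy)` through a quadratic
polynomial

```
g = v · c,   v = (1, e1, e2, e1·e2, e1², e2², e3, e4)
```

with one 8-coefficient vector per axis (`cx = a0…a7`, `cy = b0…b7`).  Given
fixation samples `(e_i, t_i)` with per-sample weights `w_i` (the diagonal of
`W`), the coefficients minimise `‖W(Vc − T)‖²`, i.e. the weighted
normal-equation solution `c = (VᵀWᵀWV)⁻¹VᵀWᵀWT` when the design has full
rank.  Weights enter the objective squared, so duplicating a sample equals
multiplying its weight by √2.  The solve is an SVD-based least squares on
the weighted rows; a rank-deficient design returns the minimum-norm
solution, so a session is well-defined from its very first sample.  No
column scaling or other conditioning is applied before the solve (the
feature and target magnitudes involved — tens of pixels and hundreds of
screen pixels — keep the normal matrix comfortably conditioned); an
optional ridge penalty exists but defaults to 0.

## Coordinate spaces

Six feature constructions are supported, differing in the origins the pupil
`(x, y)` and corner `(m, n)` are referenced to (global image origin, the
subject's first recorded corner, or each point's own first recorded
position).  The local-relative space

```
e = (dx, dy, m − m0, n − n0),   dx = (x − x0) − (m − m0)
```

expresses pupil pose relative to the eye corner with both indexed to their
first recorded positions.  It is translation-invariant (adding a constant
to all pupil and corner coordinates changes nothing) and maps the
origin-defining fixation to the zero feature.  This removes per-subject
anatomy and common-mode head shifts from the representation, which is what
lets a model pooled from *other* subjects (a **prior model**) replace
per-user calibration.

## Session lifecycle

A session holds a prior model, an immutable origin captured from the first
fixation, and the current user's accumulated samples.  The origin
convention ties the zero feature to a gaze at the screen centre:

* **Centre start** — the first fixation is on a centre target; the origin
  is that fixation.
* **Arbitrary start** — the first fixation is on any target `t_a`; the
  centre-gaze pupil position is reconstructed by inverting the prior model,
  `(x0, y0) = (x, y) − f⁻¹(t_a)`, with the head components pinned at zero.
  The inverse is solved by damped least squares (termination tolerance
  1e−8) multi-started from the window centre and the four quadrant
  midpoints; because the model is quadratic, only roots inside a
  200 × 200 px window centred on the measured pupil are admissible (the
  window matches the extent of the eye region in the camera image), and the
  root nearest the measured pupil is chosen.  Reconstruction requires a
  local-space prior: only there does the pupil origin enter the feature
  definition.  Both the reconstructed sample (zero feature → centre) and
  the measured sample (first-fixation feature → `t_a`) are absorbed; when
  `t_a` *is* the centre they coincide and are stored once, making the two
  start paths identical.

**Adaptive vs static.**  In adaptive mode every confirmed fixation
(including the starting one) is appended with a weight much larger than the
prior samples' — default ratio 100:1, configurable — and the model is refit
from scratch after each append, so the result is independent of update
order and the current user's data rapidly dominates.  A static session
keeps the bare prior fit and absorbs nothing: absorbing a current sample is
by definition an adaptive act, and letting a "static" model ingest even one
high-weight sample would amount to a one-point recalibration and would
confound the comparison between representations with the comparison between
update policies.

## Interaction and error metric

Targets are discs: a visible object (default radius 10% of the screen
width, subtending ≈3.3° at the default geometry) inside an invisible
collider (default 1.25× the visual radius; a collider strictly containing
the visual object is required, the exact ratio is a free choice).  Holding
the gaze inside the collider accumulates dwell time and shrinks the visible
disc linearly to 50% as feedback; at 1.8 s the target's event triggers and
the state resets.  Leaving the collider resets the timer fully — partial
dwell retention would invite accidental triggers.  Gaze error is the
distance from the estimate to the *visual boundary* divided by the screen
width (`max(0, ‖g − centre‖ − R_visual)/W`): a gaze anywhere on the visible
object is legitimately on-target and scores zero.  A helper converts the
fraction to visual degrees via `atan(f·W_phys/D)`.

## The synthetic cohort

No measured human data ships with the package; the simulator generates
cohorts with the statistical structure the method assumes:

| parameter | default | meaning |
|---|---|---|
| base_corner | N((0,0), (40,25)) px | subject's corner rest position in the image |
| anat offset | N((30,−5), (12,8)) px | pupil−corner anatomical vector |
| gain_x / gain_y | N(0.09, 0.008) / N(0.10, 0.010) | px pupil per screen px (eye region ≈160×100 px for an 800×372 display) |
| curvature | N(0.10, 0.02) | quadratic response fraction at the 400 px half-width |
| rot_gain | N(0.10, 0.02) | pupil−corner coupling per px of head shift |
| noise_sd | 0.5 px | per-coordinate measurement noise |
| head_step_sd | 4 px/fixation | head random-walk step (4 px ≡ 1 mm) |
| head_limit | 120 px | excursion bound ≡ 30 mm around the start posture |
| posture_sd | 40 px | initial head posture per session (≡ 10 mm) |

Each subject's displacement→target response is an exact quadratic
`t = d/gain + quad·d²`, and the forward pupil displacement is its exact
inverse.  Two properties follow.  First, a single subject's noiseless,
head-still data lies *exactly* inside the estimator's model family in every
coordinate space (a shifted parabola is still a parabola), so
identifiability tests close at machine precision.  Second, across subjects
the parabolas are shifted by anatomy and posture; one global quadratic
cannot fit several shifted parabolas (the correction would need an `e1·e3`
cross term the design row lacks), so absolute-space priors transfer poorly
while locally-aligned features expose the shared response — the effect the
local-relative representation exists to exploit.  An optional cubic term is
available as a deliberate misspecification switch and defaults to 0.

Session scripts mirror the study protocol: a 9-point calibration pattern
(centre first, so the origin convention holds by construction), a 4 × 7
grid of interaction targets, free-play target sequences generated as a
seeded neighbour walk on that grid, and session lengths drawn uniformly
from 40–107 fixations.  Everything is reproducible from explicit seeds.

**What the simulator does not model:** pupil/corner detection failures and
blinks, head *rotation* as distinct from translation, camera lens
distortion, saccade dynamics and attention lapses (fixations are assumed
exactly on-target), and the idiosyncratic nonlinearities of real eye
images.  Passing tests therefore demonstrate the estimator's behaviour
under its own assumptions — transfer, adaptation, bootstrap and metric
logic — not field accuracy on human data.

## Experiment harness

Replays score prequentially: the error at each fixation is recorded
*before* the adaptive update absorbs that fixation, so adaptive mode is
never graded on data it has already seen.  Error series split into halves
by fixation count and are summarised by the 95th-percentile
(linear-interpolation order statistic).  The prior-size sweep draws random
subject subsets per size (20 draws by default — enumerating all subsets is
infeasible beyond small cohorts); the space-ranking summary pools held-out
first-half static errors across priors of 2, 3, 5 and 7 subjects, comparing
whole prior-size curves rather than one operating point.  The
arbitrary-target experiment takes rolling 8-target windows over the
free-play sequence (a session with `T` targets yields `T − 8 + 1` windows;
no wrap-around) and pairs each arbitrary-start replay with a centre-start
replay of the same window.  Distribution comparisons use the two-sided
Mann–Whitney U test.

With the default cohort and the boundary-distance metric, local-relative
errors are almost entirely inside the visual disc, so medians and even
95th percentiles can be exactly zero — in particular the prior-size plateau
comparison (7 vs 11 subjects) closes at 0 ≡ 0.  That flooring is a property
of the metric's definition, not an artefact: any gaze on the visible target
is error-free.

## Problem sizes and numerical choices

Simulated experiments use 12-subject cohorts (24 for the adaptive-vs-static
comparison), 6 subset draws per prior size for rankings and 20 for sweeps,
8 rolling windows per subject for the arbitrary-target parity check, and
50 instances for the inverse-solver cross-check against a 0.1 px exhaustive
grid oracle — sizes chosen so the full battery runs in a couple of minutes
while every comparison retains a clear margin.  Inverse-solver roots are
accepted at residual ≤ 1e−8 (scaled by target magnitude), deduplicated at
1e−5 px, and a prior whose linear gaze sensitivity is singular (smallest
singular value < 1e−6, or condition number > 1e8) is rejected as
non-invertible.  Ties in dwell timing resolve in favour of triggering
(`elapsed ≥ threshold`).

## Known limitations

* One eye, one camera stream; dual-eye fusion is out of scope.
* The tracked corner is a single point; medial vs lateral is not
  distinguished.
* No forgetting or windowing of old samples and no outlier rejection in the
  adaptive loop; a mislabelled confirmed fixation stays in the model.
* Prior-sample weights do not decay as current samples accumulate; the
  current user's dominance comes entirely from the weight ratio.
* The arbitrary-start solve inverts the prior *before* the measured sample
  is absorbed (matching the order in which the quantities become
  available).
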
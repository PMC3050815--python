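# Methods

This note documents the models, defaults and numerical choices behind
`shimmer3d`, and what the synthetic-scene tests do and do not establish
about real recordings.

## Stereo geometry

The rig model is two frame-locked cameras at working distance *d* (default
2 m) subtending a stereo angle *α* (default 30°), giving a baseline
*b* = 2·d·tan(α/2) ≈ 1.07 m.  World coordinates are metric (mm) in the nest
frame — *x* horizontal (right-positive), *y* vertical (up), *z* away from
the comb towards the cameras — with the origin at the comb-plane centre.
Image coordinates are 0-based, origin top-left, *u* = column, *v* = row;
all px↔mm conversions go through the magnification *m* (default
0.3 mm/px).  The expected depth error under a matching error of *e_img*
pixels is e_z = m·e_img·cos(α/2)/sin(α); at the defaults, 0.58 mm
(≈ 0.6 mm).

Two rig constructors are provided:

- `make_parallel_rig` builds the projection matrices directly in rectified
  (parallel-camera) geometry: both cameras share their orientation, the
  stereo angle enters through the baseline, and per-view principal-point
  offsets put zero disparity at the comb plane.  Homographies are identity
  and the epipolar row constraint holds exactly.  This is the default for
  synthetic scenes, whose "footage" is then already rectified — matching
  the pipeline's assumption that rectification happened upstream.
- `make_verged_rig` builds physically converging cameras plus the
  rectifying homographies H = K·R_rect·Rᵀ·K⁻¹ that align both image planes
  with the baseline.  `rectify_pair` (and the row-alignment tests) exercise
  this path.  `rig.rectified()` folds H into P, which is exactly the
  matrix a rectified image obeys.

Triangulation stacks the two cross-product constraints [t]×P·T = 0 into a
6×4 homogeneous system, normalizes its rows, and takes the smallest right
singular vector.  The smallest singular value is reported as a residual;
no residual threshold is imposed by default — degenerate geometry
(coincident camera centres) raises instead.  Triangulation is exact on
noiseless projections (< 1e-6 mm round trip) and its z-noise under ±1 px
jitter scales linearly with *m*, matching the e_z budget.

## Segmentation

Detection is NCC template matching.  The NCC surface is computed with an
FFT numerator and integral-image window statistics; windows (or templates)
of zero variance score 0, and the surface is invariant to affine luminance
changes of the image.  The base template is synthesized — a bright thorax
ellipse above a longer banded abdomen ellipse, Gaussian-smoothed — so the
package is self-contained; a cropped template from real footage can be
substituted.  The head is omitted from both template and sprite: on real
nests it is usually concealed by neighbouring bees.  The bank spans
orientations ±11.5° in 2.86° steps (9 grid points; the span matches the
orientation scatter of quiescent curtain regions) and three scales spanning
±13.7% (9 px at the 65.63 px reference body length).

Non-maximum suppression is greedy in descending score with ties broken by
row then column; weaker maxima within 20 px of an accepted one are
discarded.  The score threshold `min_score` defaults to **0.6**: on dense
synthetic curtains, true bees score ≳ 0.69 while weak composite maxima
between bees score ≲ 0.56, and 0.6 separates them cleanly (recall ≥ 0.95,
false positives ≈ 0 at default settings).  A lower threshold admits
between-bee composites whose suppression radius can then shadow true
detections.  Bees in turbulent regions are simply those below threshold —
no special-case logic.

## Stereo matching

Left detections choose among M = 3 disparity slots (equal subdivisions of
the admissible disparity range, derived from the ±75 mm measurement-volume
depth via the rig geometry) or an occlusion label.  Candidates must share
the rectified row within `row_tol` = 2 px; each slot keeps its lowest-cost
candidate, with data cost 1 − NCC of the 20×20 thorax patches.  The energy

    E = Σ_p θ_p(label_p) + λ · Σ_(p,q) |label_p − label_q|

uses θ = data cost (or the occlusion penalty Ct0 = 0.6 for the occlusion
label and empty slots) and λ = 0.3 over a neighbour graph (Delaunay
triangulation of the left thoraces pruned at 3× the median edge length).
The exact capacity formulas of the original construction are not public;
these forms are declared defaults, all configurable, and the test oracle
(exhaustive enumeration over labellings) is defined on whatever capacities
are configured, so the min-cut's optimality is verified independently of
them.  The graph is a standard layered construction: one source→slots→sink
chain per left detection, infinite reverse arcs so every finite cut severs
each chain exactly once (cut position = label), and capacity-λ arcs between
neighbouring chains at each level realizing the linear smoothness cost.
The cut is computed with networkx's preflow-push; the cut value equals the
labelling energy exactly.  One-to-one use of right detections is enforced
afterwards: a right candidate claimed by several chains stays with the
lowest data cost and the losers become occluded.

## Tracking

Per frame and view, the 20×20 px thorax template is correlated over a
40×40 px search region centred on the previous position; the global NCC
maximum wins, with ties broken by smallest displacement, then row, column
and most recent template.  Tracking is integer-pixel (a parabolic subpixel
mode exists behind `subpixel`, default off).  Each track stores the
templates of the 15 preceding frames per view; scoring against the whole
memory gives the time-symmetry behaviour — appearances from the upward
thrust recur during the downward phase, and matching an older template
re-anchors the position.  On a time-symmetric flip fixture the symmetric
tracker returns to its starting pixel (±1 px per axis; an integer-pixel
tracker cannot do better), while a single rolling template drifts > 2 px.
A step whose best score falls below `track_min_score` = 0.4 marks the
track lost.

Left/right tracks are fused by replacing both rows with their mean
(columns untouched), which restores exact row consistency before
triangulation.  After a wave has passed — global sROI activity below 5%
for 30 consecutive frames — lost tracks are replaced by re-running
segmentation and matching; survivors keep their ids, replacements get
fresh monotonically increasing ids and make no identity claim.

## Wave detection and episodes

ΔL_a(i) is the mean absolute difference of frames (i−1, i) over the
60×60 px sROI (18×18 mm; 3600 px) centred on the agent's fused left-view
position — the sensor follows the track, keeping it centred under curtain
drift.  Arrival is declared two frames before the first run of three
values above ΔL_th = 10 (series values ≤ 5 are sensor noise); RS is the
series maximum within 12 frames (≈ 200 ms) of arrival, a declared default
since the underlying peak time is descriptive; rRS divides by the
population maximum.  Detection re-arms after 12 consecutive sub-threshold
frames, so multiple waves per agent are resolved.  Episodes are 30+60
frames around arrival; offset correction subtracts the per-axis mean of
pre-frames 1–6 (idempotent by construction).  rRS levels are ten
equal-width bins on [0.3, 0.8] (values outside clipped into the end bins),
grouped (3, 4, 3) into low/middle/high to mirror the three-way shading of
the pooled-course figures; the split is configurable since no canonical
value exists.  Pooling uses plain arithmetic means and s.e.m. = sd/√n per
relative frame; weighted variants are not implemented.

A known measurement caveat is reproduced as a test: with agents closer
than ~10 mm, an inactive agent inside a flipping patch can be falsely
detected through sROI overlap; shrinking the sROI removes the false
positive on that fixture.

## Synthetic curtain

The generator defines the study conditions: 60 Hz, 900 frames (15 s),
0.3 mm/px, a 700×500 mm field at 12.67 mm grid spacing with 0.9 mm
positional jitter, orientations within ±11.5°, body lengths 19.7 ± 0.5 mm,
and a gentle 10 mm surface dome inside the ±75 mm measurement depth.
`reduced_scene_config` keeps all of that and shrinks only the field
(190×170 mm, ~180 agents) and duration (300 frames, two waves) so the full
pipeline runs in minutes on one CPU; this reduced scene is what the
end-to-end tests use.

Waves are straight fronts sweeping the curtain at 500 mm/s (right→left by
default; within the speed range of dummy-wasp-elicited waves).  Per-agent
participation strength s ∈ [0, 1] is drawn from a *spatially correlated*
Gaussian field (mean 0.55, sd 0.15, correlation length 25 mm, 20%
non-participants selected by a second correlated field): shimmering
participation is locally synchronized, and without spatial correlation the
sROI — which integrates several neighbours — could not reflect the focal
agent's strength.  Marginal strengths remain approximately Gaussian.

Flip kinematics, all scaled by s: the thorax moves 1 mm towards the comb
over 100 ms, is pushed away at 6× the phase-1 mean velocity to a +1 mm
overshoot, and relaxes with a 2.5 s time constant; the body lifts 0.5 mm
in *y* (a free parameter — no measured value exists — flagged in the scene
manifest) and *x* follows *z* with coupling 0.3 (shear towards the
oncoming wave).  The abdomen elevation follows |sin(πt/200 ms)|: up within
100 ms, down within 200 ms (12 frames at 60 Hz), with maximal angular
velocity at onset, as in a whip-like thrust.  Passive curtain motion is an
isotropic exponential coupling kernel (15 mm length, gain 0.15) driven by
the neighbours' active z/y motion; it produces sub-0.2 mm pre-arrival
drift and begins before the local front arrival, as the front excites
neighbours first.

Rendering draws each agent far-to-near as two anti-aliased ellipses; the
projected abdomen length is foreshortened by cos(flip angle) (with a 10%
floor for the curved stub of a fully raised abdomen).  Abdomens carry
three high-contrast transverse bands — *A. dorsata* abdomens are strongly
banded — and brighten by up to 50% with elevation as the paler ventral
surface rotates into view.  Both choices exist because frame-difference
detection responds to *luminance change*: a flat sprite changes only at
its silhouette, which underestimates the motion signal of a textured,
glossy abdomen by an order of magnitude.  Additive Gaussian noise
(sd 3) is clipped to 8 bits, putting the quiescent ΔL_a noise floor near
3.5, consistent with "motionless" ≤ 5.

### What the synthetic tests do and do not show

The simulator shares the pipeline's geometric model (its projections are
exact), its bees are rigid two-ellipse sprites without legs, wings, pose
variation beyond one orientation angle, occlusion by flying bees, motion
blur, or illumination gradients, and its waves are single contiguous
fronts (no jumping between distant patches).  Passing the recovery tests
therefore establishes the *internal* correctness of the chain — detection,
optimal matching, drift-free tracking, metric triangulation within the e_z
budget, arrival timing, RS ordering and episode statistics under realistic
packing, kinematics and noise — not performance under field appearance
variation, which only real calibrated footage can establish.

## Problem sizes and tolerances

End-to-end tests run on the reduced scene (~180 agents × 300 frames,
667×733 px), chosen so the full chain, including two reseeds, completes in
a few minutes on one CPU.  Matching optimality is verified exactly
(enumeration over ≤ 4⁸ labellings, 50 random instances); NCC against a
brute-force double loop at 1e-10; triangulation round trips at 1e-6 mm;
arrival timing at ±2 frames for flips ≥ 45°; wave speed at ±10%; RS
monotonicity as Spearman ρ > 0.8 across all tracked agents with RS
measured at each agent's known front-crossing frame (conditioning on
detected events only would range-restrict the sample and deflate rank
correlation).  Zero-variance NCC windows score 0; NCC ties in tracking
break towards the smaller displacement; all randomness flows from explicit
seeds and reruns are byte-identical.

## Known limitations

- Integer-pixel tracking quantizes trajectories to ~0.3 mm in x/y; the
  depth budget absorbs this in z, but sub-pixel refinement would be needed
  below that.
- Identity is not maintained across reseeds by design.
- Only the row coordinate is fused between views; columns are trusted to
  the per-view trackers.
- The flip-angle estimate from projected foreshortening assumes rotation
  in a plane containing the optical axis.
- Dense (per-pixel) disparity, multi-view (> 2 camera) matching and wave
  front geometry reconstruction are out of scope.
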
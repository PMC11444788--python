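# Methods

This note documents the models and numerical choices behind `mosquitrack`:
what each stage assumes, which parameters matter, what the synthetic data
does and does not emulate, and where the known limitations are.

## Detection

The built-in detector targets infrared-style laboratory footage: small dark
bodies on a light background. A frame is binarized at an intensity
threshold (default 128 of 255), connected components outside a pixel-area
window (default 4–2000 px²) are discarded, and each component yields a
tight bounding box. Confidence is the component's mean contrast against the
background median, normalized to (0, 1] — a monotone proxy that lets the
confidence threshold (default 0.05, deliberately lenient for small targets)
behave like a learned detector's score cutoff. The image-size parameter is
snapped **up** to the next multiple of the backbone stride 32 (1040 → 1056):
of the two nearest acceptable values the larger one preserves resolution.

**Component splitting.** Two mosquitoes whose images touch merge into one
connected component, whereas a learned detector usually still reports two
boxes while the overlap is partial. The pipeline therefore estimates the
typical single-body pixel area online (running median of component areas —
valid because singles dominate) and splits any component larger than 1.6×
that median by a deterministic 2-means clustering of its pixels. A split is
accepted only if the two cluster centroids are at least 1.5·√(median area)
apart (≈ three-quarters of a body length): more deeply overlapping bodies
form a compact blob whose halves do not correspond to the individuals, and
splitting such a blob would invent positions. Split-sibling boxes are
trimmed disjoint along their dominant separation axis so the deliberately
lenient NMS threshold (0.05) cannot collapse them back into one.

## Motion model and gating

Each identity carries a constant-velocity Kalman filter on
(cx, cy, a, h, ẋ, ẏ, ȧ, ḣ), where a is the box aspect ratio and h its
height. Process and measurement standard deviations scale with box height
(h/20 for positions, h/160 for velocities — the convention that keeps
uncertainty proportional to apparent size), but with absolute floors of
2 px (position), 0.6 px/frame (velocity) and 2 px (size), and a fixed 1.0
for aspect. The floors matter: at mosquito scale (h ≈ 8 px) the raw
h-scaled values are sub-pixel, far tighter than real detector jitter, and
— more importantly — far tighter than the per-frame velocity changes of a
maneuvering insect, so without floors the gate rejects nearly every true
continuation. The generous aspect/size stds reflect that the axis-aligned
box of a small elongated body changes shape rapidly as it turns; shape is
nearly uninformative for these targets and the gate should discriminate on
position.

Candidate pairs are gated by the squared Mahalanobis distance of the
measurement from the predicted measurement distribution at the 0.95
chi-square quantile with 4 degrees of freedom (9.4877). For gating only,
the positional innovation variance is capped at (10× the position std)²: a
track coasting for many frames would otherwise accumulate an arbitrarily
large capture basin and swallow unrelated targets passing its last known
neighbourhood. The measurement update uses the consistent, uncapped
covariance.

## Association

The assignment cost is `d²/gate + 0.5·appearance + bias`, where
appearance is the minimum cosine distance between the detection's
L2-normalized intensity-histogram descriptor and the track's gallery (50
most recent descriptors), and the bias (0.01 per coasted frame, +0.02 for
tentative tracks) deterministically favours established, recently updated
tracks on ties. The Hungarian algorithm solves the assignment against a
finite unmatched cost (1.3) instead of an infinite one. The finite cost is
load-bearing: with hard infeasibility, the solver always prefers a
complete matching, so a coasting track whose own detection momentarily
falls outside its gate is forced onto the *other* target's detection —
the classic identity swap at occlusion exit. With a finite unmatched cost,
leaving that track to coast is cheaper than a bad double-match.

Two occlusion-specific rules use an absolute proximity test (within two
box heights of a track's predicted position — deliberately not the
covariance gate, so a long-coasting track's inflated uncertainty cannot
trigger them):

- a matched detection that is also in the proximity of an *unmatched*
  confirmed track is treated as a merged measurement of two overlapping
  bodies and left unmatched — both tracks coast through the overlap on
  clean constant-velocity predictions instead of one of them chasing the
  merged blob's centroid (whose motion is the pair average and corrupts
  the velocity estimate);
- an unmatched detection in the proximity of any track does not spawn a
  new identity (it is a plausible measurement of an existing one); and a
  detection left over whose proximity contains exactly one unmatched,
  unambiguous track is re-associated directly — a plain gate miss from a
  sharp turn, not an ambiguity.

Lifecycle follows the standard pattern: a new detection spawns a tentative
track, confirmed after 3 consecutive hits (a miss while tentative deletes
it); a confirmed track is deleted after Max Age (default 30 frames = 0.5 s
at 60 frames/s) consecutive misses. Identities are positive integers,
unique per run, never reused.

## Filtration and interpolation

Filtration removes identities observed (not counting interpolated points)
in strictly fewer than `min_presence_pct`% (default 5) of the video's
frames — the mechanism that eliminates reflections and other short-lived
spurious objects. It runs before interpolation.

Interpolation fills every missing frame strictly between a trajectory's
first and last observed frames, fitting x(f) and y(f) independently with a
cubic spline using not-a-knot boundary conditions (reproduces cubic
polynomials exactly and is the common numerical default). With three
observed points the interpolant degrades to the unique quadratic, with two
to linear; leading/trailing gaps are never extrapolated. A configurable
maximum gap length is exposed (`max_gap`), unlimited by default.
Percentages are reported at two decimals, rounded half away from zero.

## Evaluation

MAE sums absolute x and y deviations per frame and averages over frames;
tolerance accuracy counts frames with both |Δx| and |Δy| strictly below
the tolerance (default 6 px — half an average body length, and
`derive_tolerance(body_lengths)` recomputes mean/2 from user-measured
lengths, conventionally sampled over ~20 random frames). Estimated
trajectories are matched one-to-one to ground-truth agents by minimal mean
centroid distance (Hungarian). Occlusion events are maximal runs of
consecutive frames where an identity pair's boxes overlap with IoU
strictly above 0.25; overlap exactly at the threshold does not count.

Identity preservation through an event is scored geometrically: each
involved agent is paired with its nearest *observed* estimated trajectory
at the last well-defined frame before the event, and each of those
estimated identities maps back to its nearest agent at the first frame
after the event where both are observed again. The event is correct iff
both round trips return the original agents; events where a mapping is
undefined are excluded as undetermined. Interpolated points are excluded
from the mapping because the junction frames of an occlusion place the
agents a few pixels apart, where spline-filled positions are
ill-conditioned for a nearest-neighbour decision.

## Synthetic data

The generator emulates the target recording regime — 1040×1024 px frames
at 60 frames/s, up to five agents, 12 px mean body length (so the
half-body-length tolerance recipe yields 6 px), light background (230)
with dark (contrast 190) anti-aliased oriented ellipses and Gaussian pixel
noise (std 2). Kinematics are a mean-reverting velocity random walk with
one-frame autocorrelation 0.95 (direction-change timescale ≈ 0.3 s),
stationary RMS speed 3 px/frame (≈ 0.05–0.2 m/s at plausible mm-per-pixel
scales — cage flight, not pursuit), a top speed of twice the RMS, and
smooth wall avoidance (steering inside a margin band; mosquitoes turn near
walls rather than bounce, and an instantaneous velocity reversal would
also be unlearnable for any motion model). All randomness flows from one
seed through named independent streams (motion, noise, dropout,
reflections), so every component is separately reproducible.

Structured scenarios:

- `min_separation` confines agents to disjoint arena cells (guaranteeing
  the stated minimum distance) for clean-tracking baselines;
- `n_forced_crossings` rigidly translates whole agent paths so scheduled
  pairs meet within a quarter body length — a rigid translation leaves
  each path's kinematics untouched, so the encounter is a natural
  transversal flyby rather than an artificial swerve. A realized encounter
  is accepted only if it is a genuine crossing with disjoint entry/exit
  paths: relative speed at least 0.8× the RMS speed throughout, duration
  at most 12 frames, the agents swap sides, and neither reverses heading.
  Rebounds, hairpins and joint travel are redrawn (deterministically, by
  an attempt-indexed seed). At most n_agents − 1 crossings are feasible;
  more is an error.
- `dropout_rate` hides an agent in a given frame with i.i.d. probability
  (default study condition ≈ 0.002, matching a ~0.2% missed-detection
  rate); the mask is recomputable from the config so tests know exactly
  which frames were dropped.
- `n_reflections` adds static dark disks of sub-filtration duration,
  placed at least four body lengths from every agent position during
  their active window: they emulate specular spots on the cage wall,
  which are spatially distinct from the flying animals (a spot coincident
  with a body never registers as a separate identity).

What the generator does **not** emulate: wing/leg articulation, motion
blur, photometric variation between individuals, resting behaviour,
background clutter, and camera artifacts. Passing the end-to-end tests
therefore demonstrates the pipeline's logic — association, occlusion
handling, filtration, interpolation, evaluation — under controlled
geometry and noise, not detector robustness on real footage; for real
videos the external-detections route with a trained detector is the
intended path.

## Problem sizes in the test suite

The default suite runs the full pipeline on reduced arenas (256–360 px,
1.5–8 s at 60 frames/s) rather than full 1040×1024 scenes; the pipeline is
resolution-independent and the reduced scenes preserve the body size,
frame rate, speeds and densities that drive tracking difficulty, while
keeping the suite fast. The crossing benchmark accumulates 50+ scored
occlusion events over ~55 seeded two-agent scenes.

## Known limitations

- With visually identical targets, identity through an occlusion rests
  entirely on motion extrapolation; encounters where an agent turns
  sharply *during* the overlap are genuinely ambiguous and occasionally
  resolved wrongly (the measured preservation rate on transversal
  crossings is ~90–93%, and would be lower for lingering encounters). A
  discriminative appearance model (the deep re-identification embedding
  this design anticipates via its descriptor gallery) is the remedy on
  real footage, where individuals differ.
- The blob detector assumes dark-on-light contrast and a single class; it
  is a stand-in for a trained detector, not a substitute on real footage.
- The constant-velocity model has no acceleration state; at 60 frames/s
  the process noise absorbs maneuvering, but much lower frame rates would
  degrade both gating and occlusion coasts.
- Box centers are quantized by the pixel grid; the ≈1 px MAE floor on
  synthetic scenes reflects box quantization, not association error.
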
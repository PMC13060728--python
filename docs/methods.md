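# Methods

This note documents the models, parameter choices and numerical decisions
behind `swgaze`, and states what the synthetic-data generator does and does
not emulate.

## Coordinate conventions and scene

Right-handed coordinates with y up: x is lateral (midline at x = 0,
positive toward the right gate), z is depth from the start platform (0) to
the far wall (6 m).  All lengths are metres, times seconds.  The default
scene encodes the study geometry: a 5 x 6 m room, walker rows at
z = 1.4 m and 4.7 m, the gate-indicator sign at z = 1.7 m, standers at
z = 3 m, exit gates on the far wall at x = ±1.25 m.  Bench geometry is
only qualitatively specified in the source design ("centre of the room",
back-to-back pairs), so the default is a single 1.2 m x 2.4 m block
centred at (0, 3.05) with seated-agent colliders flanking its lateral
edges — deep enough (0.8 m) to cover extended legs, which is what forces
the left/right route choice.  Every object carries an axis-aligned box
collider; walkers get a 0.4 x 1.8 x 0.3 m box.  Box colliders keep all
ray and containment tests exact and deterministic.

Gate-side, walker-direction and bench-occupancy (or deadline) factors form
the 12-cell factorial designs of the two experiments; a seeded permutation
yields the 84-trial session order.

## Synthetic-data generator

The generator stands in for the study's undeposited raw streams.  Its
defaults are the study conditions: 80 Hz frame clock, walkers at 1.3 m/s
spaced 2.5 m, gate cue at t = 2 s, 12-s deadline (experiment 1).  Values
the study does not print are set once to field-plausible figures:

| parameter | default | rationale |
|---|---|---|
| participant base speed | 1.3 m/s | preferred human walking speed |
| velocity-dip depth / centre / width | 0.4 / 3.05 m / 0.8 m | the observed mid-room slow-down between the rows |
| hook probability | 0.06 | observed hooked-trial rate under a lax deadline |
| gap offset bias | 0.0 (mid-gap) | unpressured crossings are near gap centre |
| reaction delay after cue | 0.3 s | simple reaction time to a visual cue |
| inter-pupillary distance | 63 mm | adult mean |
| gaze noise | 0.5° s.d., AR(1) ρ = 0.995 | 0.5° accuracy with ~0.05°/frame precision, typical consumer-HMD eye-tracker figures |
| fixation / pursuit durations | lognormal, mean 0.30 s / 0.45 s | standard scene-viewing and pursuit-episode scales |
| saccade main sequence | 21 ms + 2.2 ms/deg | classic duration-amplitude law |
| PSO | 1° damped 18 Hz oscillation, ~50 ms | post-saccadic oscillation signature |
| eye height | 1.6 m | average standing eye level |

**Locomotion.** The participant waits until cue + reaction delay, then
follows a lateral spline x(z) (monotone PCHIP through a handful of control
points) around the bench block to the target gate, at path speed
v(z) = v₀ · (1 − dip·exp(−(z − z₀)²/2w²)).  Hooked trials use a
mirror-image spline that crosses the midline after the bench zone.  The
kinematic ODE dz/dt = v(z)/√(1 + x′(z)²) is integrated by Euler steps at
800 Hz and sampled at frame times.

**Walkers and gap geometry.** Each row is an infinite single file moving
strictly linearly; the file's lateral placement (mod spacing) is chosen
*after* the participant trajectory so that at each row crossing the
rear-facing agent sits fraction·spacing downstream and the front-facing
agent (1 − fraction)·spacing upstream, where fraction =
0.5 + bias + noise, clipped so the crossing clearance is at least
`clearance_m` (0.3 m).  This backward construction is a deliberate
synthetic-data device: it makes the crossing geometry an exactly
controllable ground truth while keeping every logged walker trajectory
exactly linear (speed and spacing recover to 1e-6 from the logs).  The
generator does not model collision-avoidance dynamics beyond this: the
0.3 m bound is the guaranteed centre-to-centre minimum under default
settings, a shoulder-brushing pass rather than proxemically comfortable
distance.

**Gaze.** Events alternate: a saccade toward a target drawn from the
current phase's pool (minimum-jerk angular profile, main-sequence
duration), an optional damped post-saccadic oscillation, then a fixation
(static target) or pursuit (walker target, gain 0.98).  Events truncate at
phase boundaries so gaze stays phase-appropriate.  Both eye rays converge
on the gazed point from origins ±half-IPD; each eye gets independent AR(1)
angular noise.  The drift-dominated noise model (ρ = 0.995) matters: white
0.5° noise at 80 Hz would imply 20–50 deg/s frame-to-frame velocity
jitter, which no real tracker exhibits and which would erase the
fixation/pursuit velocity separation the classifier relies on.

**Pupil.** diameter = baseline (4 mm) + 0.15 mm hippus-like oscillation at
0.9 Hz + a train of Hann-windowed 3.5 Hz bursts (0.12 mm, 0.35 s) emitted
at 0.5 bursts/s per unit load, placed deterministically via the integrated
load intensity, + white noise (0.02 mm).  Burst count, and hence
high-frequency band power, scales linearly with load, and each burst is a
distinct oscillatory event — the two properties the load analyses need.

**What the generator does not emulate.** Bodily sway and gait
oscillations; head orientation distinct from gaze; blinks and tracker
dropouts (validity is always true; the analysis side handles missing
samples anyway); sitter-occupancy effects on the path (the condition is
encoded, but the default policy does not widen its berth when sitters are
present); luminance-driven pupil responses.  Passing tests therefore
demonstrate correctness of the measurement and metric chain under
controlled conditions, not behavioural realism of any particular effect
size.

## Gaze reconstruction and attribution

The vergence point is the midpoint of the shortest segment between the two
eye rays, with ray parameters clamped to be non-negative (the constrained
optimum is found on an edge of the quadrant when the unconstrained one is
infeasible); the segment length is kept as a quality figure.  Pairs with
cross-product norm below 1e-9 are flagged for collider fallback.
Attribution: the object whose collider contains or comes within
`snap_radius` = 0.1 m of the vergence point wins (ties at equal distance
go to the smaller collider, so a sitter beats its bench); otherwise the
cyclopean ray (mean origin, renormalized mean direction) is cast against
all colliders.  Boxes containing the ray origin are not hit candidates —
the participant stands on the boundary-wall collider at trial start and
cannot gaze at an object from inside it.  At realistic noise levels the
vergence depth error at 3–6 m viewing distance exceeds the snap radius, so
distant attributions are mostly decided by the ray cast; this mirrors the
original instrumentation, where collider intersections served as the
cross-check on vergence estimates.

Occlusion is physical: a ray to the gate can legitimately hit a seated
agent first.  Attribution accuracy against generator truth is ~94% at
default noise and ≥97% on steady (fixation/pursuit) frames at zero noise;
residual zero-noise misses are genuine occlusions.

## Event classification

Angular kinematics are world-referenced (the headset's own orientation is
not in the logs), computed from unwrapped azimuth/elevation of the
cyclopean direction with `np.gradient` (central differences, one-sided at
the ends).  Consequences: fixating a static object while walking produces
translation-induced gaze rotation that overlaps slow pursuit, so the HMM
is validated on head-fixed streams; head-free accuracy is lower (~0.7)
for reasons intrinsic to the available signals, not the implementation.

The I-VT classifier thresholds Savitzky-Golay velocity at 100 deg/s
(head-free VR is noisier than desktop tracking) and merges sub-60 ms
interior fixations.  The HMM is a 4-state Gaussian HMM on
(log speed, log |acceleration|) with sticky transitions and structural
zeros that make the PSO state enterable only from the saccade state
(EM preserves exact zeros); states are relabeled post hoc by fitted
kinematics — lowest speed = fixation, highest = saccade, and of the middle
two the higher-acceleration one = PSO.  For classification features the
derivative window is 5 frames, order 2: at 80 Hz a saccade lasts 3–4
frames, and an 11-frame window smears its velocity into up to ±5
neighbours, capping frame accuracy near 0.87 even at zero noise.  (The
11-frame, order-3 default of `sg_smooth_velocity` remains appropriate for
smoothing displays and the I-VT view.)  Frame-exact accuracy at default
noise is ≥0.8; the ±2 frames flanking each event boundary are intrinsically
ambiguous under any finite differentiation window, so the "accuracy → 1 as
noise → 0" property is asserted on interior frames (≥0.95 at zero noise),
with overall accuracy monotone in noise.

Segments are maximal label runs; each ends where the next begins (the last
extends one frame period), so segments exactly tile the trial.  Segment
amplitude is the great-circle angle between run-start and run-end
directions.

## Metrics

**Attention taxonomy.** The phase x object-kind map follows the task's
goal hierarchy; the timer is task-related in every phase where it is
listed at all (precedence task-related > local > global), because
information sources do not stop being information sources while also being
look-ahead targets.  Unlisted kinds and unattributed frames are
miscellaneous.

**GTE.** First-order transition probabilities are estimated among the
states *observed within each 80-frame window* (stride 1), and the
conditional entropy is normalized by log2 of the number of observed
states — normalizing by log2(216) would make short windows incapable of
approaching 1.  Windows with fewer than two distinct states or fewer than
two transitions are missing, never zero.  Missing gaze samples (state −1)
are skipped.

**K-coefficient.** Pairs are fixations immediately followed by a saccade;
fixations followed by pursuit are excluded (the pairing is undefined for
them).  Standardization is per trial, so the grand mean is zero by
construction and phases with a single event still get a value; per-phase
means assign each pair by its fixation midpoint.  Zero variance in either
component flags the trial degenerate rather than emitting infinities.

**Gap crossing.** Distances are measured along the row's travel axis at
the first frame at or past the row's z line; the rear-facing agent is the
nearest one downstream in the walking direction.  Euclidean distance would
conflate the lateral gap with the participant's depth offset at the
crossing frame.

**Alignment.** Signed angle in the horizontal plane between the gaze
direction and the heading (smoothed finite differences of head position,
edge-replicated 0.25 s boxcar); positive = right.  Frames below
0.2 m/s are flagged stationary but reported — slow-motion frames are
where large misalignments legitimately occur.

**LHIPA.** The pupil series (NaN gaps ≤ 0.2 s linearly interpolated,
longer gaps reject the window) is decomposed with a periodized symlet-16
DWT.  The high band aggregates the detail levels spanning ≈1.25–5 Hz
(levels 4–5 at 80 Hz), the low band sits one octave below (≈0.6–1.25 Hz).
A deeper low band (below 0.6 Hz) would need ≥6 s windows, which
phase-length segments (1–4 s) cannot supply; this octave placement keeps
the index defined on phase windows of ≥2.4 s while preserving the
low/high contrast.  Modulus maxima are local maxima of |coefficients|
surviving a universal threshold σ√(2 ln N), with σ estimated once from
the finest detail level (median absolute deviation / 0.6745 — the
standard wavelet noise estimate; the orthonormal periodized DWT keeps
white noise at the same scale at every level, so raw coefficients are
thresholded directly).  The index is the low-band maxima rate over the
high-band rate; no suprathreshold high-band maxima flags the window
degenerate.  Higher load → more high-frequency pupil events → larger
denominator → lower index.

**Density maps.** 0.1 m bins smoothed with a 0.3 m Gaussian kernel,
normalized to unit mass.

## Trial bookkeeping

Phases follow the time/depth rules with half-open intervals (a frame
exactly on a row line belongs to the later phase) and a monotone-label
rule: once a phase closes, brief backward z dips do not reopen it.  Gate
arrival is entry into a 0.9 m x 0.3 m box at the far wall; a foil-box
visit shorter than 0.25 s followed by target arrival counts as a
pass-through, which hooked paths need.  Success is target arrival within
deadline + 1 s grace.  Filtering is two-stage in the original order:
durations > 16 s are dropped before any statistics; wrong-gate trials are
kept for success/duration statistics and dropped before gaze analyses.
Hooked-trial exclusion applies only to path-shape analyses, as a mask,
not a global drop.  The hooked rule — mean lateral position over the
bench zone (2.0–4.1 m) on the wrong side *and* a midline crossing beyond
it — is a reconstruction; the source describes the shape only
qualitatively.

## Problem sizes and determinism

Everything is seeded: a session seed spawns per-trial seeds
(SeedSequence), and each trial seed drives locomotion, gaze and pupil
draws, so (config, seed) determines every output byte.  The test suite
uses cohorts of 100 trajectory-only trials for parameter recovery
(gap-fraction bias within ±0.05, hooked prevalence within binomial error),
30 s head-fixed streams for classifier validation, 60 s pupil windows for
load monotonicity, and a 12-trial full-pipeline cohort for the qualitative
phase-pattern checks — sizes at which the asserted tolerances have
comfortable statistical headroom while the whole suite runs in about a
minute.

## Known limitations

- World-referenced angular features cannot fully separate
  fixation-during-locomotion from smooth pursuit; head-free event labels
  are approximations (as they are for any system without reliable head
  orientation).
- Per-phase LHIPA is undefined for phases shorter than ~2.4 s at 80 Hz;
  the bookend phases often fall below this, so cohort-level pooling is
  recommended.
- The locomotion policy does not react to sitter occupancy or deadline
  pressure; condition effects on path shape and gap bias must be injected
  through the policy parameters, not expected to emerge.
- Box colliders overestimate body volume at corners; attribution near
  adjacent objects (timer embedded in the far wall, sitters against the
  bench) relies on the smaller-volume tie-break.
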
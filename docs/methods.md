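# Methods

This note documents the models implemented in `fincrawl`, the choices made
where the biology under-determines the mathematics, and what the synthetic
data can and cannot show.

## The crawling gait model

The fish is reduced to two rigid suckers joined by an inextensible spine
chord of length `spine_length` (17 mm for the default 50 mm animal). Each
sucker has two lateral fin pivots at `pivot_offset` (9 mm) either side of
its centre. Friction under a sucker is anisotropic: the abducted-fin side
grips (`mu_abducted`, default 1.99), the adducted side slides
(`mu_adducted`, 1.11). Because the quasi-static model never integrates
forces, these coefficients enter only through the kinematic rule they
justify: **the abducted side is the anchor**.

One displacement phase proceeds as:

1. the actively pulled sucker rotates by `rotation_per_stage` (θ, default
   0.47 rad) about its abducted-side pivot, moving its centre along a chord
   of 2·R·sin(θ/2);
2. the passive sucker mirror-rotates (−θ) about its own abducted-side
   pivot, and its adducted side slips along the substrate until the centre
   distance is again exactly `spine_length` (a radial projection; the slip
   is ≈0.2 mm at defaults).

Step 2 is deliberately *not* "solve the passive rotation alone so the spine
length is preserved": that one-unknown solve is structurally non-periodic —
the solved angle overshoots the active angle every stage, heading and
lateral position drift secularly, and the constraint becomes unsatisfiable
within a few cycles at default geometry. The rotate-then-slip rule is the
behaviour actually described for the animal (the adducted side moves first,
then the sucker rotates about the abducted side) and yields an exactly
periodic gait with spine conservation at machine precision.

Forward crawling is two mirror-image stages per cycle, fin states swapping
sides *during* each rotation; backward crawling is four quarters: fin-swap
(no motion), rotation, fin-swap, rotation. In both gaits there are exactly
two sucker rotations per cycle, the girdle muscles act in anti-phase, and
both suckers stay in contact in every frame. Swapping the protocol and
nothing else reverses the sign of net displacement. Rotation amplitude is
scaled by `muscle_contraction_amplitude / 3.5 mm`, so a zero girdle stroke
produces zero displacement: the muscles are the motor.

Within a phase, motion follows a cosine easing after an initial dwell
(`dwell_fraction` = 0.3 of the phase), reproducing the observed
pause-accelerate-decelerate pattern (two accelerations per cycle) and
making every landmark momentarily stationary — minimum axial and lateral
velocities are zero.

### Landmark synthesis

The midline is built per frame by integrating a unit-tangent direction
field over arc length (so total arc length is exact by construction):
straight chord between the sucker centres, a head section whose bend
relative to the chord tapers from the anterior sucker heading to nearly
straight at the snout (`head_taper` = 1.3), and a tail section whose bend
is the posterior sucker's heading relative to the chord amplified by
1 + `tail_gain`·u^`tail_power` (u = tail fraction; 1.8 and 0.7). Twenty
points at equal arc spacing are emitted, plus five-vertex fin polygons
whose area is linear in an abduction factor eased along the phase waveform,
girdle-muscle endpoint pairs placed at exactly the model muscle length, and
head/sucker reference points. Gaussian landmark jitter (`noise_sigma`, one
seeded generator) models digitisation error.

### Calibration of the defaults

The geometry and actuation defaults are the study conditions, fixed once:

- body length 50 mm — the value implied by the reported mm/s ↔ BL/s
  conversions (65/1.3 = 50; 800/16 = 50), although the reported standard
  length is 60.3 ± 3.9 mm; the inconsistency (103 mm/s ≈ 2.3 BL/s implies
  ≈45 mm) is left unresolved and 50 mm used throughout;
- `rotation_per_stage` = 0.47 rad and `pivot_offset` = 9 mm give
  8.38 mm/cycle, so a maximal 16-cycle bout covers 134 mm (> 130 mm);
- `tail_gain`/`tail_power`/`head_taper` are calibrated so that the
  *pipeline-measured* peak lateral velocity at the landmark 80% of body
  length from the head is 7.8 BL/s and the amplitude envelope grows
  monotonically tailward with a tail/head ratio above 7;
- cycle frequency 7.70 Hz, frame rate 500 Hz.

Landmark indexing: reported landmark numbers are 1-based (points 1–11), so
"point 9" = 80% BL = index 8 of the package's 0-based arrays.

What the generator does *not* emulate: out-of-plane motion, sucker
deformation and pressure fields, tail-fin propulsion (the escape launch),
fluid loading, inertial dynamics, and observer digitisation bias beyond
isotropic jitter. The velocity profile along the body is therefore smoother
than in the animal (e.g. the simulated lateral-velocity envelope keeps
rising to the tail tip rather than peaking at 80% BL), and passing tests on
synthetic data validate the pipeline's measurement chain, not the animal's
full dynamics.

## The ratcheting friction model

A pulling test is a slider (the fish) dragged through a spring
(`spring_stiffness`, 25 mN/mm — gauge plus tether compliance) whose far end
moves at `pull_speed` (0.1 mm/s). The slider sticks while spring force
F < μ_static·N and otherwise slides, quasi-statically tracking
F = μ_sliding·N. The normal load N is the applied adhesion (gram-force
levels converted at 9.80665 mN/gf) plus an angle-dependent term: once F has
reached `angle_threshold_force` (65 mN), every `slip_quantum` (0.2 mm) of
slip raises all four fin-ray angles by `angle_per_slip`·quantum and N by
`angle_gain` per degree. Each discrete angle increment lifts the sliding
limit above the current force, re-sticking the slider — the force trace is
a rising stick-slip sawtooth. Below the threshold the trace is a single
static peak followed by a flat sliding plateau, which is what makes the
extracted "stable post-onset force" equal μ_sliding·N.

The intrinsic suction load of the euthanised fish in the fin-ray-angle test
is not measurable; it is inferred as `angle_threshold_force`/μ_static
(≈3.33 gf), i.e. the first slip is also the first ratchet event. Two
independent observations support this: with the default stiffness and pull
speed it puts first movement at 65/(25·0.1) = 26 s, the reported onset
time, and it makes the detected angle-rise force ≈65 mN.

Estimators:

- movement onset = first sample with displacement > 0.05 mm (small against
  the ~10 mm total excursion); static force = max force before onset;
  sliding force = median force from 10% past onset to the first angle rise
  (else trace end);
- coefficients = through-origin OLS slopes of static/sliding force against
  adhesion load, all 12 trace points per fit (the expected relation is
  proportional and the reference line is drawn from zero); an intercept
  option exists but is off by default;
- the angle-rise threshold is the *largest force reached up to* the first
  2° rise of the smoothed mean angle series — the force at the crossing
  sample itself sits in a post-slip trough of the sawtooth and does not
  represent the triggering load.

Measurement noise is additive Gaussian on force (`noise_sigma_force`,
0.05 mN); no noise model was reported, and the simulated traces are far
cleaner than gauge data.

## The kinematics pipeline

- Interpolation: natural cubic spline through the 20 points parameterised
  by cumulative chord length; arc length accumulated over a 20 001-point
  subdivision and inverted to place 101 points at equal arc increments
  (gap equality ~1e-6 relative; verified against a 10^5-subdivision
  polyline oracle in the tests).
- Landmarks: every 10th resampled point; 10 segments of 10% BL.
- Travel direction: principal axis of the anterior head point's path,
  oriented by net displacement; below 0.1 mm net displacement the head-axis
  direction is used; all-coincident positions are an error.
- Segment angles: unsigned, folded to [0°, 90°] (reported maxima are
  positive without sign).
- Amplitudes: signed perpendicular distance to the travel-direction line
  through the mean head position ("straight body midline" is otherwise
  undefined); per-cycle maxima are reported unsigned.
- Velocities: Savitzky-Golay smoothing (window 11 samples, order 3 — the
  reported smoother with unreported parameters; both exposed in config)
  followed by central differences; axial/lateral are projections on the
  travel direction and its left normal, resultant their hypotenuse.

## Cycle analysis

Fin areas are shoelace areas (self-intersecting outlines rejected via a
geometric validity check; collinear outlines degenerate to zero). States
use min-max normalisation over the whole series with cut-offs at 70%/30%
of the range (configurable); normalisation is global rather than per-cycle
because cycles are themselves derived from the states. A constant series is
labelled single-state with a warning. Cycles run between successive entries
of the right pectoral fin into abduction; frequency is cycles over elapsed
boundary-to-boundary time. Cycle normalisation linearly interpolates 20
phase samples including both endpoints (reported as 0–100% in 5% steps);
aggregation is pointwise mean and sample SD (ddof = 1). Correlations are
Pearson (the coupled waveforms are near-linear); zero-variance series yield
NaN sentinels.

## Numerical and testing notes

- Problem sizes: simulations in tests and in the acceptance script use 5–16
  cycles at 500 Hz (325–1040 frames) and pulling traces of 40–111 s at
  50 Hz; a full acceptance run takes a few seconds on one core.
- Determinism: one seeded `numpy` generator per simulation; identical
  config + seed reproduce byte-identical outputs (hashed in the pipeline
  manifest).
- Degenerate inputs (duplicate midline points, zero-length segments,
  coincident muscle endpoints, stationary head, single adhesion level,
  traces without movement or without angle rise) raise typed errors or
  return documented sentinels rather than propagating NaNs.

## Known limitations

- Quasi-static and purely kinematic: no force balance, no prediction of
  failure loads or of gait changes under external flow.
- The fin-ray-angle ratchet is macroscopic and phenomenological; it does
  not model the unculi microstructure or substrate roughness.
- The backward gait reproduces the phase structure (fin swaps before
  rotations, two low-displacement quarters) but quarter displacements are
  exactly zero rather than "< 0.5 mm".
- Live-animal magnitudes that depend on un-deposited raw video (total
  excursion 9.86 mm at 111 s, per-segment angle ranges, the 800 mm/s
  launch) are treated as qualitative anchors only.
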
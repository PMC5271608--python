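# Methods

`gridframe` analyzes how the hexagonal firing lattices of grid cells anchor
to competing spatial reference frames when a square foraging platform is
rotated or translated inside a cue-rich room.  This note documents the
models, the numerical choices, and what the synthetic data can and cannot
establish.

## Coordinate and angle conventions

All coordinates are in cm.  The origin is the platform center in the
standard (STD) configuration, x rightward, y upward.  Rotations are
reported **clockwise-positive** (matching the direction of the experimental
platform rotations); internally, axis directions from `atan2` are
CCW-positive, and the conversion happens once, in `frames.grid_rotation`.
Because the lattice is 60-degree-symmetric, grid rotations live on a circle
[-30, +30) deg with the endpoints identified; all rotation arithmetic wraps
into this range (`angles.wrap_grid_angle`).

Three reference frames are considered for each manipulated session:

- **room** — the frame of the distal cues (rotation 0);
- **platform** — the physical apparatus (rotation = the full manipulation
  angle, e.g. 70 CW ≡ +10 in grid space);
- **geometry** — the square platform's symmetry class: the congruent
  rotation of minimal magnitude modulo 90 deg (70 CW → 20 CCW; 45 CW is an
  exact tie, resolved toward the sign opposite the physical rotation, → 15
  CW in grid space).

## Rate maps

Running speed is estimated on a path smoothed with a clipped temporal
Gaussian.  The source text gives "variance = 300 ms"; a literal variance of
300 ms² would be σ ≈ 17 ms — under one camera frame, incapable of
smoothing — so we read it as σ = 300 ms (config-exposed), clipped at ±2σ
with edge renormalization.  Epochs strictly longer than 500 ms with speed
strictly below 3 cm/s are expunged from the *unsmoothed* trajectory and
from the spike train.  Positions are binned at 3 × 3 cm; bins with < 50 ms
dwell are missing (NaN).  Spatial smoothing uses a clipped 5 × 5 Gaussian
mask with variance 2 bin² (taken literally: σ ≈ 1.41 bins is plausible for
a 5 × 5 clipped mask), renormalized over occupied bins at each step; an
output bin is missing when fewer than five occupied bins fall inside the
mask.  Bootstrap maps resample the spike train with replacement at its
original size and repeat the whole pipeline; the implementation reuses the
replicate-invariant occupancy side and is exactly equivalent to rerunning
it (verified by a single-spike identity test).

Bin edges are anchored to a symmetric extent about the platform center so
that map rotations about the array center coincide with rotations about
the room origin; a day's sessions share one extent covering every session.

## Correlograms and grid geometry

The crosscorrelogram is the map of Pearson correlations between two rate
maps at every discrete displacement, restricted to displacements whose
overlap holds at least 100 co-occupied bins.  It is computed from six
masked convolution sums (`scipy.signal.correlate`); a brute-force
nested-loop oracle pins the implementation to 1e-9.  Windows whose
variance cancels to rounding noise (near-constant overlap) are invalidated
with a scale-aware tolerance.  A field at displacement v means translating
the first map by +v aligns it with the second.

Correlation fields are 8-connected components of at least 20 bins with
r > 0.1 (8-connectivity tolerates single-bin diagonal bridges at 3 cm
resolution); centers of mass are correlation-weighted — the unweighted
variant differs by well under a bin on ideal lattices.  The central field
is the one nearest (0,0), ties to the larger area.  Canonical semi-axes:
AX0 nearest the +x direction (an exact ±30 deg tie resolves CCW), AX1/AX2
the first semi-axes CCW/CW of it.  Orientation is the circular mean of the
semi-axis directions taken in the 60-degree-periodic space (multiply by 6,
average, divide), which avoids ±60 wraparound artifacts.  Scale is the
mean center-of-mass distance of the three axis fields.  The ellipse is a
direct least-squares conic fit (`skimage.measure.EllipseModel`) to the six
inner fields; the elliptical index is 1 − B/A.

## Gridness and classification

If the elliptical index exceeds 0.05, the rate map is stretched by A/B
along the short-axis direction before scoring.  The stretch is applied as
a NaN-aware affine resampling of the map image (bilinear, with any output
bin touching a missing input bin marked missing); re-binning the raw
trajectory under rescaled coordinates would require re-running the
upstream pipeline inside every bootstrap replicate for an effect below the
bin scale, so image resampling was chosen and iterated (≤ 3 times) until
the residual index falls below 0.05.

The annulus containing the six inner autocorrelogram fields has radii
D ± 1.2·cR, with D their mean distance from the center and cR the radius
of the circle whose area equals the central field's.  The annulus is
correlated with copies of itself rotated by 30/60/90/120/150 deg
(bilinear interpolation, correlating over bins valid in both); the
gridness score is min(r60, r120) − max(r30, r90, r150).  The sentence
describing the score in the source text lists 30 deg on both sides of the
subtraction; that version scores ideal hexagonal grids strongly negative,
contradicting the reported statistics of accepted maps, so the standard
definition above is implemented, with both offset sets config-exposed.

A rate map is classified as a grid cell iff all seven criteria hold:
gridness ≥ 0.1; all six annulus fields identified; adjacent semi-axis
separations strictly between 30 and 90 deg; elliptical index < 0.5; every
inner field within 20% of its center distance from the fitted ellipse
(radial point-to-ellipse distance); scale < 125 cm; and gridness ≥ 0.1 in
at least 95 of 100 bootstrap maps.  Criteria are evaluated lazily in this
order; ones unreachable after an earlier failure are reported as
not-evaluated.

## Reference-frame responses

The grid rotation is the wrapped difference of grid direction between a
manipulated session and its reference — the most recent preceding session
in the standard platform configuration.  The residual rotation in a frame
subtracts the frame's rotation (in grid space); positive residuals are
over-rotations.  The phase shift in a frame is the displacement of the
most central correlation field of the crosscorrelogram computed after
rotating the STD map by the frame's full physical rotation plus the
measured residual (room frame: by the measured room rotation alone).

For SHIFT (platform translated by half its side, 68.5 cm, along +x) both
cameras are platform-centered, so the directly measured shift is the
platform-frame phase.  The room-frame x component follows the circular
algebra α = 2π·68.5/(scale·cos(orientation)), β from the observed platform
shift, γ = β − α, each wrapped to (−π, π], and room shift =
γ·scale·cos(orientation)/(2π).  Two conventions are bridged explicitly:
the measured shift is "where the grid pattern moved", while the α/β
formulas count shifts so that a perfectly room-bound grid satisfies β = α;
the sign flips on the way in and out (`frames.shift_responses`).  The
y component (orthogonal to the translation; the formulas are
one-dimensional) is taken from the platform frame.  The projected period
uses scale·cos(orientation) exactly as written; reducing the orientation
to the axis nearest the translation first is available for sensitivity
analysis by passing that angle.  Note that α is sensitive to the scale
estimate (dα/dscale ≈ −2π·68.5/scale²), so a 2% scale error moves the
room-frame phase by ~2 cm at scale 60 — phase-recovery tolerances account
for this.

An optional diagnostic evaluates the hypothesis of re-anchoring to an
arbitrary platform side: the minimal phase shift over the four
90-degree-congruent alignments.

## Pair coupling

Pairs of simultaneously recorded grids are formed when both pass
classification in the STD and manipulated sessions and their STD maps
correlate below 0.5.  Coupling is (1) the wrapped absolute rotation
difference and (2) the joint correlation: both STD maps are rotated by the
pair's average rotation (circular mean in the 60-expanded space) and
translated by the average phase-shift vector — each grid's own measured
shift enters the average even across scales — then each map is
mean-centered and unit-normalized over its occupied bins, the pairs are
stacked, and the cosine is taken over entries defined in both stacks.
Controls rotate each STD map by U(−30, 30) deg and shift each manipulated
map by a uniform direction and a distance U(0, grid scale), independently
per map per replicate (10 by default), and re-run the full measurement on
the perturbed maps rather than perturbing measured parameters — more
faithful to the stacked-map definition.  Scale-ratio classes: SR1 ≤ 1.3,
SR2 ≤ 1.9, SR3 above.

## Circular statistics

Grid angles are linearly expanded onto the full circle (×6), statistics are
computed there, and descriptive angles are mapped back (÷6).  Rao's
spacing test uses U = ½ Σ|T_i − 360/n| against the Russell & Levitin
(1995) critical-value table (the table used by the circstat family of
toolboxes), linearly interpolated between tabulated sample sizes; its
empirical size at n = 20 is verified to sit in [0.02, 0.09] at nominal
0.05.  Tests against a hypothesized angle build 95/99/99.9/99.99%
mean-direction confidence intervals per Zar's formulation (chi-square form
for mean resultant length ≤ 0.9, exponential approximation above) and
report the largest interval excluding the hypothesis.  All circular tests
require n > 7.

Thinning removes putative duplicates: within (rat, tetrode, manipulation),
no two retained units from different days may lie within 150 µm along the
tetrode track.  Among conflicting units the earliest day (then the lowest
cluster id) is kept — the procedure only needs to be automatic and
deterministic — making thinning idempotent.  Units without recorded depth
are excluded with a warning.

## Synthetic sessions

The generator emulates the study conditions: a 137 cm square platform in a
355 × 280 cm room, 30 Hz tracking, manipulations STD/ROT20/ROT30/ROT45/
ROT70/SHIFT/STD2, 20-minute sessions.

**Trajectory.**  A smoothed random walk with per-epoch target speeds,
velocity relaxation, heading diffusion, reflective walls, and explicit
pause states.  The foraging task (continuous pellet chasing) produces
brisk, ballistic-dominated running, modeled with a mean target speed of
32 cm/s, σ 3 cm/s, heading diffusion 0.7 rad/√s, and ~3 pauses/min of
~1 s.  A mildly noisy billiard has a near-uniform stationary distribution
and mixes within a few platform crossings; after 20 min, ≥ 95% of 3-cm
bins accumulate ≥ 50 ms of dwell and the dwell CV over fully interior bins
is below 0.5 (the CV floor is set by visit-count statistics, ≈ 1/√visits;
bins clipped by the wall are excluded from the CV because their smaller
reachable area lowers their dwell deterministically).  No speed or pause
distributions are prescribed by the source; these are free, exposed
parameters.  An optional waypoint-steering term is available.

**Grid cells.**  The firing rate is a rectified, sharpened sum of three
plane-wave cosines at 60-degree separations (exact lattice periodicity,
analytic control of scale/orientation/phase; peak rate exactly at the
vertices), with a Gaussian-bumps-on-lattice alternative selectable for
robustness checks.  Elliptical distortion is injected by an affine shear
of position before rate evaluation, giving a closed-form target index.
Spikes are inhomogeneous Poisson by thinning of a homogeneous process at
the peak rate, validated against a 1-ms Bernoulli oracle.

**Anchoring.**  Each cell carries an anchoring policy.  Under a
manipulation the lattice follows its anchor frame's rotation/translation
minus a configured under-rotation and phase lag — deterministic offsets,
not per-session noise, matching the day-to-day reproducibility of the
measured responses.  Room-anchored lattices are unchanged in room
coordinates; geometry-anchored lattices follow the minimal congruent
square configuration.  Boundary cells fire along one platform wall in
platform coordinates (plateau within the field width, Gaussian falloff)
and therefore track the geometric boundary through manipulations.

**What the synthetic data do not show.**  Ideal lattices have no
out-of-field firing, no rate remapping, no theta modulation, no tracking
noise, and anchoring responses are noiseless per session; passing
parameter-recovery tests therefore bounds algorithmic bias, not robustness
to biological variability.  Camera-frame errors are injected only as rigid
offsets with known inverses; camera-correction *estimation* (done by eye
in the experimental workflow) is deliberately out of scope — corrections
are manifest inputs.

## Problem sizes and determinism

Calibration checks run 100 ideal grids and 100 uniform-rate cells on
20-minute sessions sharing ten trajectories (simultaneously recorded cells
share a path), with 100 bootstrap maps per cell; coupling checks use an
eight-cell coherent population (≥ 10 eligible pairs) with 10 control
perturbations per pair; the Rao size check uses 2,000 uniform samples at
n = 20.  Every stochastic stage draws from a generator seeded by stable
derivation from one master seed (`synthetic.derive_seed`), so reruns are
bit-identical.

## Known limitations

- Scale estimates carry a ~1–3% outward bias from thresholded
  correlation-weighted centers of mass on broad cosine fields; this
  propagates into α-based SHIFT phase predictions (see above).
- The ROT70 "degraded grid" preset scrambles the lattice into jittered
  bumps; it reproduces the classifier-level phenomenon (loss of
  hexagonality with preserved multi-field firing), not its biophysics.
- `geometric_frame_angle` is defined for square platforms only; the scene
  model cannot express non-square platforms.
- Rate maps use fixed binning; adaptive or kernel-density maps and polar
  (directional) maps are out of scope.
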
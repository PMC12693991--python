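# Methods

This note records the model, the numerical choices and the limits of what
the simulated studies can show.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate frames and kinematics

The laboratory (acetabular) frame has its origin at the joint centre of
rotation — the centre of the seated femoral head — with +Z from the origin
toward the magnetometer at the shell pole.  The build does not dimension
this frame explicitly, so it is a package convention; everything else is
expressed in it.

A state (θ, ψ) tilts the stem-neck axis by θ about the in-plane axis
(−sin ψ, cos ψ, 0): `R = Rz(ψ)·Ry(θ)·Rz(−ψ)`.  Two consequences are load
bearing:

* at θ = 0 the pose is the identity for *every* ψ — the azimuth is
  genuinely undefined at neutral, and the 360 tilt-0 grid states are exact
  duplicates;
* the stem does not spin about its own axis during an azimuth sweep.  For
  the axisymmetric build magnet the spin is unobservable either way; for
  the diametrally magnetised catalogue candidates it decides their
  state-separation scores, and the no-spin convention is the one that
  reproduces the expected candidate ordering (it is also how a
  ball-and-socket joystick moves).

The magnetometer is mounted yawed 180° about +Z relative to the joint
frame (`GeometryConfig.sensor_yaw_deg`).  This is forced by the physics:
with the magnet tilted toward +X the in-plane field at the sensor points
toward −X, so only a flipped sensor makes the azimuth convention
"ψ = 0 ⇒ in-plane field along sensor +X" hold, which the arctangent
tracker relies on.  All `FieldVector` values in the package are in the
sensor frame.

## Magnet field models

Units are mm / mT / µT throughout; conversions are centralised in
`magnetostatics`.

* **Axially magnetised cylinder** — exact elliptic-integral solution,
  evaluated through Carlson symmetric integrals (`scipy.special.elliprf`,
  `elliprj`), valid outside the body.  The on-axis limit reduces to the
  elementary two-face expression used as a hand-check.
* **Cuboid** — exact superposition of uniformly charged rectangular pole
  plates (arctan solid-angle term for the normal component, log terms
  in-plane); an arbitrary remanence vector superposes the three
  axis-aligned solutions.
* **Diametral (transverse) cylinder** — surface-charge quadrature:
  σ = Br·cos φ on the curved face, integrated with a uniform (spectrally
  convergent, periodic) rule in φ (64 nodes) and Gauss–Legendre axially
  (24 nodes).  Node-doubling changes the result by < 1e-10 relative at the
  working distances, so the rule is converged far beyond the sensor
  quantisation.  The same engine doubles as an independent numerical
  cross-check of the two closed forms (agreement < 1e-8 relative in the
  tests) and the point dipole `m = Br·V/µ0` is the far-field oracle for
  all three (< 2% at 5 characteristic lengths, < 0.5% at 10).

Evaluation points landing exactly on a formula singularity (the cylinder
rim circle, a cuboid face plane) are nudged by a relative 1e-9 before
evaluation; points inside the magnet body raise an error.

## Build geometry and calibration

The sensor distance is fixed at `d_s = 24 mm` (between the 18 mm liner
bearing radius and the 28 mm shell outer radius, the sensor being potted in
the introducer hole).  The magnet offset `a` along the neck axis is not
measurable on the build, so it is solved by 1-D root finding (Brent) so the
neutral-state field magnitude equals the measured 1996.8 µT; this gives
`a = 2.50 mm`, and the neutral state is then verified to carry the
grid-wide maximum of |B|.  The solved offset and a configuration hash are
written into every report for provenance.

## State separation and magnet ranking

For the 66 × 360 grid (tilt 0–65°, azimuth 0–359°, 1° steps, tilt-major
order, 23 760 states) the per-state nearest-distinct-neighbour distance in
(Bx, By, Bz)-space is computed with `scipy.spatial.cKDTree` (verified
against an O(n²) oracle on small instances).  meanSS is the mean over all
states.  Because the tilt-0 states are exact duplicates, the raw minimum
is exactly 0 for every magnet; the headline minSS therefore excludes
exact-duplicate distances, and both values are reported.  Candidates are
ranked in the one calibrated build geometry (calibrated once, on the
reference disc) by meanSS, ties by minSS; the reference 8 × 2 mm axial
disc wins both metrics with meanSS ≈ 9.8 µT.

## Trackers

* **Look-up** — Euclidean nearest neighbour over the reference dataset via
  the k-d tree; exact ties resolve to the lowest dataset index, so a
  degenerate neutral reading returns state (0, 0) deterministically.
* **Responsivity** — the in-plane fraction R of the field is tabulated
  noiselessly at 1° steps over tilt 0–66° (strict monotonicity is asserted
  at build; it holds on the reference geometry) and inverted by linear
  interpolation with end clamping.  Azimuth is `atan2(By, Bx)` wrapped to
  [0, 360); an exactly zero in-plane reading is flagged with a warning and
  reports the arctangent convention value 0 so streaming inversion stays
  total.
* **Neural network** — 3 → 12 → 12 → 12 → 2 tanh/linear net, min-max
  normalisation of inputs and outputs to [−1, 1], trained full-batch by
  Levenberg–Marquardt with an analytic Jacobian (damping start 1e-3, ×10 /
  ×0.1 schedule) and early stopping on validation error with patience 6;
  70/15/15 random split from one seed; training is bit-reproducible.
  Azimuth is regressed in raw degrees, so predictions near the 0°/360°
  wrap are intrinsically poor for this tracker — the pooled azimuth RMSE
  (~6°) is dominated by wrap samples while tilt stays sub-degree.  A
  sin/cos output encoding would remove the wrap failure but is deliberately
  not the default, to keep the tracker faithful to the raw-angle fitting
  recipe the other trackers are compared against.

## Sensor model and protocols

The magnetometer model quantises to 6.01/6.01/9.68 µT per axis at 49 Hz
after adding zero-mean Gaussian noise, one LSB per axis by default (no
noise figure is available for the physical part; one LSB is the
conservative conventional choice).  Commanded motion is piecewise-linear
at 30°/s (the bench rate is not documented; 30°/s is a realistic manual
articulation speed and is configurable):

* **two-DoF protocol** — from neutral to each tilt of the 5–60° (5° step)
  ladder, sweeping azimuth across 0–355° at each level with alternating
  direction; three repeats, with repeat-to-repeat variation entering
  through the sensor noise seed.  Ground truth is the commanded state at
  125 Hz; streams pair by closest timestamp keyed to the sensor (one row
  per sensor sample, pairing error ≤ 4 ms).
* **subluxation protocol** — an impingement-only excursion to the 64°
  onset and back, then lever-outs to 70°, 72° and 74° (rest tilt 40°,
  ψ = 0).  The continuity-switch channel is true whenever the commanded
  tilt reaches the onset.  Ground truth (head separation) is sampled at
  the 25 Hz camera rate and keys the alignment.

The lever model is a single rigid rotation of the head–stem body about
the rim point the neck contacts (radius 18 mm, opposite the tilt
direction), with no axial load — matching a robot articulation rather
than a physiological subluxation.  The head-centre displacement magnitude
is the chord 2·r_l·sin(δ/2); its direction is out of the liner opening,
away from the sensor.  The tracked scalar ("Z displacement") is this
chord; in the joint frame the actual Z component differs from it by
cos(δ/2) < 0.4% over the protocol range.  The 25-entry look-up is sampled
uniformly in δ (the bench sampling was camera-frame driven and slightly
non-uniform; that detail is not reproduced).  The inversion pipeline gates
on the continuity switch — separation is reported as 0 while the switch is
open — which is also what makes the impingement-without-separation event a
guaranteed true negative.

## Error statistics

Angular error is `asin(sin(observed)) − asin(sin(expected))` in degrees,
which removes the 0°/360° azimuth wrap; note it also folds angles beyond
±90° (170° reads as 10°).  That folding is kept for parity with the bench
statistics; a conventional wrapped signed difference is available via
`fold=False`.  RMSE carries the square root; the quoted SD is of the
signed error.  Summaries pool all repeats and can stratify by tilt band
(< 20°, 20–45°, > 45°) to expose the low-tilt azimuth degradation.

## Calibration module

Hard/soft-iron correction fits the general 10-parameter quadric to raw
readings by linear least squares, recentres it, takes the SPD square root
of the ellipsoid matrix as the soft-iron correction W and fixes the
expected magnitude β to the geometric-mean semi-axis, so an undistorted
spherical cloud maps to itself.  Identifiability (enough spread, a true
ellipsoid) is checked and degenerate inputs raise.  The synthetic fixture
distorts 500 Fibonacci-sphere directions at the ~1000 µT field scale of
this system; recovery restores the radius coefficient of variation to
< 1% for SPD distortions of condition ≤ 3, offsets ≤ 200 µT and 2 µT
noise.  Simulated pipelines are undistorted by default; calibration is for
real streams or explicitly distorted fixtures.

## What the simulations do and do not show

The synthetic studies share the exact forward model with the trackers'
reference data: they demonstrate algorithmic correctness, noise/quantisation
robustness and internal consistency, and they bound from below the error a
physical build would see.  They do not contain robot compliance, component
seating shifts, field-model mismatch, ambient-field drift or camera
measurement error, which is why the simulated tracking errors (e.g. ~0.3°
tilt RMSE for the look-up method) sit well below the bench figures they are
compared against as ceilings.  Problem sizes used by the reproduction
script: 23 760-state grid, ~21 000 pooled sensor samples over three
repeats, 6 000 training draws for the network, 234 camera-rate subluxation
samples.

## Known limitations

* Two DoF only; stem axial rotation is unobservable with this axisymmetric
  magnet by construction.
* Single magnet and single sensor; no temporal filtering or fusion.
* The lever model ignores axial load and liner deformation.
* Soft-magnetic effects, demagnetisation and temperature drift are out of
  scope; the calibration model is strictly linear.
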
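# Methods

`weplrange` estimates the probability distribution of *random* (inter-
fraction) proton range error that remains after daily image-guided setup
correction, using serial volumetric CT of previously treated patients —
or, for development and validation, ground-truthed digital phantom
courses.  The output is a site- and centre-specific prior (overall mean,
systematic Σ, random σ, and per-fraction histograms) for robust treatment
planning.  No dose is computed.

## Stopping-power calibration

CT numbers are mapped to proton stopping power relative to water in two
stages.

**Electron density → relative stopping power.**  For a material of
relative electron density ρ_e/ρ_ew and mean excitation energy I,

S_rel = (ρ_e/ρ_ew) · [ln(2 m_e c² β² / (I(1−β²))) − β²]
                    / [ln(2 m_e c² β² / (I_w(1−β²))) − β²],

with I_w = 75 eV, m_e c² = 0.511 MeV, and β² obtained from the proton
kinetic energy via γ = 1 + E/(938.272 MeV).  The ratio is treated as
energy independent: for the worst-case calibration insert (cortical-bone
substitute, ρ_e = 1.69, I = 87 eV) the package computes a 0.238 %
difference between 90 and 310 MeV, inside the 0.6 % margin usually quoted
for a single-curve calibration.  When a curve is built from inserts the
reference energy defaults to 150 MeV (mid treatment range); by the same
independence the choice is immaterial at the quoted margin, but it is
fixed for reproducibility.

**HU → stopping power.**  The (measured HU, S_rel) knots form a
piecewise-linear curve (`hu_to_sp`): exact at every knot, clamped to 0
below the lowest knot, linearly extrapolated from the last segment above
the highest (metal-bright pixels), and never negative.  The shipped
default curve is an 8-knot megavoltage-CT calibration spanning air
(−970 HU) to cortical bone (673 HU, SP 1.622).

**Insert I-values.**  Manufacturers do not publish the mean excitation
energies of their density plugs.  The shipped insert file therefore
stores I-values obtained by inverting the ratio above at 150 MeV against
the measured stopping-power column of the default curve, so that
`build_calibration` on the shipped inserts reproduces that curve to
better than 0.1 %.  These are fitted effective values, not measured ones;
the file documents this and is editable.  The separate constant
`CORTICAL_BONE_I_EV = 87 eV` (a manufacturer-typical literature value) is
what the energy-independence margin is evaluated with.

A power-law range–energy relation R = α·E^p (defaults α = 0.0022 cm,
p = 1.77, configurable) is provided as a utility for converting WEPL
changes to energy terms; nothing downstream depends on it.

## WEPL ray tracing

The effective depth at a pixel is WEPL = Σᵢ spᵢ·ℓᵢ over the pixels the
ray crosses between the grid boundary and the *target pixel centre*,
with ℓᵢ the geometric intersection length.  Conventions, fixed
package-wide and pinned by tests:

- In-plane axes: +y anterior, +x patient left; pixel (0,0) top-left;
  row index runs anterior→posterior.
- Gantry 0° places the source anterior (parallel ray direction (0,−1));
  90° at patient left.  Divergent beams use a configurable
  source–axis distance (default 2000 mm); `None`/`inf` selects a
  parallel beam.
- Tracing is strictly in-plane (coplanar beams only); 3D tracing is out
  of scope.

The traversal is exact, not sampled: every crossing of a pixel edge is
located analytically (a Siddon-style grid walk), and each inter-crossing
segment is attributed to the pixel containing its midpoint.  A ray
through a pixel corner therefore contributes zero length to the diagonal
neighbours.  Integration starts at the grid boundary rather than the
body surface; outside-body pixels carry near-zero stopping power, so the
difference is immaterial and the kernel needs no body segmentation.  For
parallel beams at cardinal angles `wepl_map` uses an algebraically
identical cumulative-sum evaluation (full upstream pixels plus half the
target pixel); the generic walk covers everything else, and the two
paths are cross-checked in the tests.  A fixed-step sampling integrator
exists only as a test oracle (agreement within 0.05 mm on random
geometries).

Note on rotation invariance: the WEPL of a *pixelized* phantom is not
exactly rotation invariant — rasterizing a hard-edged disc introduces
~spacing-scale anisotropy at oblique angles regardless of the traversal.
The rotation-consistency test therefore uses a radially smooth phantom,
where all gantry angles agree to <0.01 mm.

## Per-fraction pipeline

For each usable fraction and beam angle: HU→SP conversion; rigid
registration into the reference frame by resampling the *stopping-power*
image (bilinear, zero fill) with the recorded couch shift (and optional
rotation about the isocenter) — interpolating after conversion keeps the
calibration's clamping semantics; optional field-of-view truncation
correction; WEPL maps; per-CTV-pixel differences to the reference
fraction.

- **Reference fraction**: the first usable fraction by default,
  overridable.  Pixel correspondence is by grid index after rigid
  registration; deformable matching is out of scope.  A through-plane
  shift component is resolved by nearest-slice matching.
- **Truncation correction**: pixels inside the scanning circle (default
  diameter 386 mm) keep their measured value; outside the circle but
  inside the (planning) body contour they are filled with a uniform
  stopping power (default 1.0, water, as a conservative soft-tissue
  surrogate); outside both they are 0.
- **Sign convention**: Δ > 0 means the WEPL increased relative to the
  reference (undershoot risk); Δ < 0 means it decreased (overshoot risk,
  e.g. weight loss).
- **Summaries**: per-fraction mean, sample (n−1) SD, and a percent-volume
  histogram with configurable bin width (default 1 mm) covering the full
  data range.  Heat-map figures truncate the display at ±15 mm, but
  statistics always use all data.

## Population statistics

- Overall mean: unweighted mean of per-fraction means over all analysed
  images — image-count weighting, not patient-count weighting.
- Systematic Σ: sample SD of the per-fraction means pooled across
  patients (and across angles for the overall row; per angle for angle
  rows).
- Random σ: spread of the individual per-pixel deltas, weighting by data
  points.  Two definitions are implemented because the pooling semantics
  are genuinely ambiguous: `pooled` (default) is the SD of all deltas
  about the grand mean and so includes between-fraction mean variation;
  `within` removes each fraction's mean first and estimates the purely
  within-fraction spread.  Both are exposed; outputs label which was
  used.

No outlier rejection or systematic-error correction is applied.  The
population table carries one row per gantry angle plus a pooled `All`
row; a group with too few fractions or pixels is reported with NaN and
an error note without invalidating the other rows.

## Synthetic courses and their ground truth

`simulate_course` turns a phantom spec (elliptical body, disc/slab
inserts, disc CTV, pixel-centre rasterization) and a Gaussian motion
model into a course of stopping-power images plus the shift table the
pipeline expects.  Mechanisms, each per fraction:

- **Setup displacement** (SD `setup_sd` per axis) of the whole anatomy,
  with a recorded IGRT correction chosen so the residual after applying
  it has SD `residual_after_igrt_sd`.
- **Relative insert motion** (SD `relative_insert_motion_sd`):
  femoral-head-like structures move independently of the CTV.
- **Body-contour erosion** (`erosion_rate` mm/fraction): weight loss;
  shortens the entry path, driving the mean ΔWEPL negative
  (overshoot) and monotonically with fraction.
- **Density fluctuations** in slab regions: a scalar N(mean, sd) offset
  per fraction (filling-type change; shifts all downstream pixels
  equally) or i.i.d. per-pixel offsets (local heterogeneity).

All randomness is Gaussian so the recovery targets stay analytic; a
course is a pure function of the seed.  `ground_truth_stats` returns the
model's (m*, Σ*, σ_w*) for density-driven mechanisms (scalar/per-pixel
fluctuations, erosion trend) at cardinal parallel angles; displacement
mechanisms have geometry-dependent distributions with no closed form and
deliberately raise instead of returning an approximation.

The parameter-recovery configuration (`recovery_course_inputs`) places a
~500-pixel CTV behind a 20 mm scalar-fluctuation slab (per-fraction mean
exactly N(−1.8, 3.4²) mm) and a 30-layer per-pixel-noise slab on a dense
(SP 3) base so the noise cannot clip at zero, calibrated so each CTV
pixel's marginal noise SD is exactly 3.3 mm.  Because any upstream noise
is shared by all CTV pixels in the same beam column, per-pixel noise is
column-correlated; the pooled σ target is unaffected (law of total
variance) while the `within` estimator is mildly biased low — a real
property of 2D ray geometry, not an implementation artifact.

What the phantoms do *not* emulate: CT texture and imaging noise,
deformable anatomy, 3D geometry, realistic HU distributions (synthetic
courses are generated directly in stopping power).  Passing the recovery
tests shows the pipeline arithmetic and statistics are correct under the
stated motion model; it does not validate the model against real
anatomy.

On the pelvis-like phantom, lateral femoral-insert motion inflates Σ for
the 90° beam while the 0° beam — whose rays never cross the lateral
discs — is untouched, reproducing the clinically reported
angle-dependence as a strict ordering.  If an isotropic ~1 mm setup
residual is added, both beams acquire a comparable contour-entry noise
floor and the ordering is only resolvable with many more fractions than
a quick simulation uses; the shipped ordering test therefore isolates
the insert-motion mechanism.

## Numerical choices and sizes

- Sample (n−1) SD everywhere; NaN (not an error) for single-pixel SDs.
- CSV outputs: fixed headers, 4-decimal mm precision → byte-identical
  re-runs; the replay test re-executes an analysis from its own run log.
- Bilinear resampling for rigid shifts; zero shift short-circuits to the
  identity (reference self-comparison is exactly zero).
- NaN voxels convert to stopping power 0 via the calibration clamp and
  are counted in the run log.
- Default problem sizes: phantom grids of 95–190 px at 1–2 mm spacing,
  courses of 15–40 fractions in the examples and 201 fractions for the
  parameter-recovery check; these keep the whole test suite under a few
  seconds on one CPU while leaving the recovery tolerances tight.

## Known limitations

- 2D in-plane tracing only; divergence is modelled in-plane.
- Rigid registration only; the "equivalent pixel" correspondence ignores
  deformation, as does the source method.
- The systematic range error of the HU calibration itself is out of
  scope; only inter-fraction *changes* are quantified.
- The shipped insert I-values are effective fitted values (see above),
  appropriate for reproducing the default curve, not for materials
  research.
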
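# Methods

This note documents the models, conventions, numerical choices and
known limitations of `spinalign`.

## Coordinate conventions

All 3D quantities live in the radiographic (biplanar) frame: y
vertical and increasing cranially, x lateral (frontal-plane
deviation), z antero-posterior and increasing posteriorly
(sagittal-plane deviation).  The frontal radiograph images the (x, y)
plane, the lateral the (z, y) plane.  Image rows run downward in pixel
space, so pixel-to-mm conversion flips rows:
`y = origin_y + spacing_row · (rows − 1 − row)`; the stored image
origin is therefore the *bottom-left* pixel's 3D position.  The
conversion is affine and exactly invertible, which the phantom uses to
synthesize pixel annotations.

## Biplanar reconstruction

The projection model is purely orthogonal: frontal = (x, y),
lateral = (z, y).  (The real slot-scanner geometry is near-parallel in
the scan direction; the orthogonal model is the standard working
approximation for annotation-level work and makes triangulation the
exact inverse of projection.)  A marker observed in both views is
reconstructed with x from the frontal pick, z from the lateral pick,
and y as the arithmetic mean of the two vertical observations —
the two views constrain y redundantly, and no physical argument
privileges either, so the mean is used and the discrepancy
`|y_f − y_l|` is reported as a per-marker quality metric (flagged,
never fatal, above a configurable 15 mm).

Drawn polylines may backtrack vertically.  Preprocessing sorts by y
and averages duplicate y values; a drawing in which more than 5% of
points had to be reordered (relative to the better of the two drawing
directions) is rejected rather than silently repaired.  Two planar
polylines are fused by parameterising both by y over the intersection
of their y ranges and sampling x(y) and z(y) by linear interpolation
at `n_samples` (default 100) regular intervals.

## Rigid registration

The scanner→radiograph transform is the closed-form least-squares
proper rigid fit (Kabsch): centre both marker sets, SVD of the
cross-covariance, and flip the smallest singular direction when the
unconstrained optimum is a reflection.  Weights are uniform.  Sources
with fewer than 3 points, or whose centred matrix has a second
singular value below 1e-6 of the largest (collinear geometry), are
rejected.  Marker RMSE is the root mean square of the per-marker
Euclidean residuals; with K markers carrying isotropic noise σ the
6-dof fit leaves E[RMSE] ≈ σ·√((3K−6)/(3K))·√3, so RMSE grows
linearly in σ — a property the acceptance checks verify empirically.

The default registration set is the four clinical markers (C7, L5,
both posterior superior iliac spines), mirroring the manual workflow
where each pick costs operator time.  Automated phantom batches use
all nine placed markers: picking is free there, and the wider lever
arm roughly halves the rotation error under marker noise (Monte
Carlo: median 1.3° with 4 markers vs 0.5° with 9 at σ = 2 mm).

## Curve smoothing and shape correlation

Each line is modelled as independent penalized cubic smoothing
splines x(y), z(y).  The roughness penalty is selected per coordinate
by generalized cross-validation by default, with an explicit numeric
override in the pipeline config; straight lines lie in the penalty's
null space and are reproduced exactly at any penalty.  Inputs of 4
distinct y values (the documented minimum) fall back to an exact
cubic interpolating spline, the zero-penalty limit.  Curves are
resampled at regular y intervals (default 100 samples); paired curves
are restricted to the intersection of their y ranges first, since the
skin line and the internal line span different landmarks.

Superimposition is rotation+translation-only Procrustes: the proper
3D rotation minimising summed squared distances, scale fixed at 1, so
the centroid size of the moving curve is preserved exactly and the
statistic is invariant to any rigid postural offset.  The internal
line is the moving set, the skin line the reference.  The per-plane
correlation is computed on the aligned coordinate sequences (not
derivatives), each sequence centred by its own mean and scaled by its
own N−1 sample standard deviation.  Exactly identical or exactly
negated sequences return ±1.0 exactly.  A zero-variance sequence
makes the correlation undefined and raises; the batch pipeline maps
the one degenerate-but-meaningful case — *both* sequences flat to
within 1e-9 mm — to 1.0, since two straight lines agree perfectly in
shape.

Note one genuine property of no-scaling 3D Procrustes: when the two
curves differ in amplitude (the skin deviation is a damped copy of
the spinal deviation), the least-squares rotation tilts part of the
larger deviation out of its plane, so per-plane correlations sit
below the same-plane correlation of the raw construction.  This is
inherent to the method, not an artifact.

## Cobb angles

Curvature inflections of the in-plane coordinate are located as sign
changes of the spline's second derivative on the sample grid, refined
by bisection, with second-derivative magnitudes below 1e-7 of the
curve-wide maximum treated as zero (a numerically straight curve
yields no inflections).  Inflections closer than 20 mm to each other
are merged to their midpoint; inflections within 20 mm of an endpoint
are dropped (no meaningful segment fits there).  Curve endpoints
anchor the outer segments so single (C-shaped) and double (S-shaped)
curves both yield angles — a single curve has its most-tilted
tangents at its ends.

Tangent slopes are estimated by local regression over a 20 mm window
(about one vertebral height), widened in 50% steps until it holds at
least 5 samples and falling back to a global fit, with a warning,
if it outgrows the curve.  At inflection points the fit is linear:
there the second derivative vanishes, so a symmetric-window
ordinary-least-squares line is unbiased to second order — which is
precisely why the tangents are evaluated at inflections.  At curve
*endpoints* the window is one-sided and curvature generally does not
vanish, biasing a linear fit by ~½·curvature·window; segment
measurement therefore uses a local quadratic there, whose linear
coefficient at the endpoint is unbiased to third order.  The window
default of 20 mm keeps the worst-case error on the analytic test
family (amplitude/length up to 0.1) near 0.1°; wider windows
visibly bias tight curves (30 mm → 1.3° worst case).

The frontal primary curve is the largest segment angle.  Sagittal
labelling uses the sign of z″ within each segment: kyphotic
(posteriorly convex, cranial) z″ < 0, lordotic z″ > 0; with more
than one interior inflection the two largest segments are used with a
warning, and a monotone sagittal profile raises a single-curve error
(the batch maps a *straight* profile to 0°/0°).  Angles are unsigned
degrees, clinical convention; each measurement stores its bounding
tangent positions and slopes.

An independent reference implementation
(`spinalign.validation.dense_cobb_reference`) reads the angle between
the most tilted tangents off 10⁴-point central differences; it shares
nothing with the inflection/regression path and bounds its error in
the tests and acceptance checks.

Paired comparison against a reference rater reports pairwise
differences with median and IQR (linear-interpolation quantiles
throughout the package) and the Pearson correlation with a 95%
Fisher-z confidence interval — the CI method is a documented
assumption, as is the quantile rule.

## Phantom generator

The generator emulates the acquisition protocol: standing biplanar
radiography with nine 5 mm radiopaque skin markers, then a 3D surface
scan in a replicated posture, i.e. a rigid offset between frames plus
small non-rigid noise.

* **Internal line**: L5 at y = 0, C7 at y = 450 mm (default spine
  length).  Frontal deviation is a sine A·sin(2πy/λ) (defaults
  A = 16.5 mm, λ = 400 mm, i.e. a primary Cobb of 29°) or a single
  circular arc parameterised by its sagitta, both with closed-form
  tangents.  The sagittal profile is built from its tangent-angle
  function: slope runs from the L5 value through an extremum at the
  thoracolumbar junction (40% of spine length) to the C7 value,
  blended with sin² ramps — C², exactly one curvature sign change,
  and kyphotic/lordotic Cobb angles (defaults 41°/40°) exact by
  construction.
* **Skin line**: the internal line displaced 35 mm posteriorly, with
  frontal amplitude damped to 0.55 and a low-frequency lateral skin
  shift of 0.2 × amplitude added, so the frontal correlation of the
  construction is high but below 1; the sagittal correlation is near
  1.  The reference correlation of each phantom is computed at
  generation time from the noiseless construction.
* **Markers**: C7, L5, PSIS pair below the pelvis, plus five
  auxiliary markers (mid-thoracic, scapulae, flanks) spread ±100 mm
  laterally on the skin sheet.
* **Surface**: a 120 mm-wide sheet around the skin line with flanks
  curving 18 mm anteriorly, ~2700 points (≈5 points/cm²) — enough
  for point-cloud I/O and registration tests, with no anatomical
  realism beyond that.
* **Noise**: Gaussian, applied to scan markers (σ default 2 mm in
  cohorts) and surface points (0.5 mm); radiographic annotations are
  synthesized exactly (sub-pixel floats), so spine-line recovery
  isolates the smoothing/regression error.  One integer seed
  determines every draw; phantom timestamps are derived from the seed
  so folders are bitwise reproducible.

Cohort sampling emulates the study population: primary frontal Cobb
from a truncated normal (mean 29°, SD 12°, bounds 9–54°) converted to
a sine amplitude, wavelength uniform 360–440 mm, kyphosis/lordosis
truncated normals around 41°/40°, postural rotations up to 10° about
random axes with translations up to ±100 mm per axis.

What passing phantom tests do **not** show: the generator has no
ribcage or soft-tissue asymmetry, no palpation error model for the
drawn lines, no vertebra-level structure, and marker noise is
isotropic Gaussian rather than the spatially correlated error of a
patient changing rooms.  Recovery numbers on phantoms are therefore a
floor for method error, not an estimate of clinical accuracy.

## Batch behaviour and determinism

Per-patient results are JSON files containing only deterministic
content; wall-clock timestamps and per-stage timings go to the
logging stream, so re-running a batch on unchanged inputs reproduces
byte-identical outputs.  A failing stage marks the patient `failed`
with the stage's message and the batch continues; summaries exclude
and count failures.  Cohort summaries report medians and IQRs
(type-7/linear-interpolation quantiles) of marker RMSE, residual SD
(both per-patient and pooled per-marker — published residual
statistics do not state which pooling they use, so both are
available), per-plane correlations and the three Cobb angles.

## Known limitations

* The internal line ends at L5, so lordotic angles referenced to the
  superior endplate of S1 by clinical raters will read systematically
  larger than this package's lordotic angle; no S1 extrapolation is
  attempted.
* The orthogonal projection model ignores the true scanner beam
  geometry; pixel-level calibration beyond the DICOM tags (per-view
  origin offsets) is configurable but defaults to the tags.
* Correlation is linear (Pearson) on coordinates after Procrustes;
  rank-based or derivative-based shape statistics are out of scope.
* No surface-based (ICP) refinement: registration is strictly
  marker-based and rigid.
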
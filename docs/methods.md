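# Methods

This note records the models, parameter choices and numerical decisions
behind `mousequant`, and what the synthetic validation does and does not
demonstrate.

## Coordinate and transform conventions

Grids are axis-aligned; voxel index `(i, j, k)` maps to world millimetres as
`origin + index * spacing` (no direction matrix — oblique acquisitions are
out of scope). All transforms map **fixed-space** (atlas) points to
**moving-space** (subject) points, the standard backward-resampling
convention: warping the subject onto the atlas grid evaluates the subject
image at `T(x)` for every atlas voxel centre `x`.

The affine model has 12 parameters — translation (mm), rotation (radians,
composed as `Rz·Ry·Rx`), scale and shear — applied about the centre of the
fixed domain. Neither the rotation composition order nor the centre is
observable from registration quality alone; both are fixed for
reproducibility. An affine matrix is decomposed back to canonical parameters
via `A = R·K` with `K = chol(AᵀA)ᵀ` (upper-triangular, positive diagonal),
which is unique for `det A > 0`.

The free-form deformation is a displacement field interpolated from a
regular control lattice with tensor-product cubic B-splines
(`β³(0) = 2/3`, `β³(±1) = 1/6`, support |u| < 2). Coefficients beyond the
finite lattice are zero, so the field decays smoothly to the identity
off-grid — subjects slightly exceeding the atlas extent are handled rather
than rejected. Evaluation uses `scipy.ndimage.map_coordinates(order=3,
prefilter=False)`, which computes exactly this tensor-product sum; a
brute-force full-lattice summation serves as the test oracle.

Image resampling at order 3 prefilters the moving image so cubic
interpolation *interpolates* (reproduces) the samples; the prefilter's
boundary influence decays geometrically (≈ 0.27 per voxel), which the tests
account for. CT is padded with −1000 HU (air), PET with 0 (clipped at 0
after cubic resampling to remove ringing); labels resample with
nearest-neighbour and background 0.

## Registration engine

Protocol: affine → B-spline → masked B-spline, each driven by the normalized
correlation coefficient over 2,500 random points redrawn per iteration on a
5-level pyramid (factors 32, 16, 8, 4, 2; Gaussian smoothing with
σ = factor/2 voxels before subsampling; budgets 4096, 4096, 2048, 2048, 1024
iterations). Levels that would leave any axis under 4 voxels are skipped —
at the default phantom grid the factor-32 level is. Budgets are multiplied
by `iteration_scale` (default 1/8), the package's desk-scale working point;
all validation uses this default.

Design choices that were genuinely open:

* **Optimizer gains.** The adaptive stochastic gradient descent gain is
  γ(t) = a_eff/(A+t)^α with A = 50, α = 0.602. `a_eff` is auto-calibrated
  per level from probe gradients so the first step moves about half a
  level-voxel (clamped to 0.2–3 mm); a zero probe gradient (e.g.
  self-registration, where NCC is exactly stationary) freezes the level. A
  trust region caps any single update at twice that step. The artificial
  time advances by a sigmoid of the cosine similarity of successive
  gradients, bounded in (0.5, 2) per iteration and non-decreasing — more on
  agreement, less on opposition. The final quarter of each level's iterates
  is averaged (Polyak-style) to shrink the stochastic equilibrium ball.
* **Gradients.** Analytic chain rule: the d(−NCC)/d(sample) vector times the
  trilinearly interpolated moving-image gradient times the transform's
  parameter Jacobian (affine: 12 matrix derivatives by central differences
  of the exact matrix construction; B-spline: the 4×4×4 tensor weights,
  scatter-added per control point). Trilinear interpolation is used during
  optimization; third-order B-spline interpolation is reserved for the final
  resampling of outputs.
* **Parameter scaling.** Each affine parameter is rescaled by the inverse
  RMS point displacement a unit step produces over the fixed domain, so the
  optimizer works in mm-equivalent coordinates. This matters for an
  elongated, near-axisymmetric body: rotation about the long axis and the
  long-axis shears are weakly constrained by the image and converge poorly
  under a single global scale.
* **Lattice schedule.** The control-point spacing is 8 mm for the unmasked
  B-spline step and half that (4 mm) for the masked step ("finer
  registration of internal organs"); the lattice covers the affine-image of
  the fixed domain plus a one-point border. No bending-energy penalty is
  applied — the stochastic resampling of metric points acts as the
  regularizer at these deformation scales.
* **Mask.** The masked step samples inside the atlas body mask (nonzero
  labels, or CT > −400 HU largest component with holes filled, dilated by
  2 voxels).
* **Convergence.** No early stopping: levels run their full (scaled)
  budgets. Per-step metrics reported by the three-step driver are dense
  seeded NCC evaluations on a common unmasked domain, so they are comparable
  across steps.

## Synthetic phantoms

The generator stands in for a pre-segmented mouse atlas and for simulated
subject studies; projection/reconstruction physics are deliberately not
modelled.

* **Geometry.** The body is a superellipsoidal tube: quartic profile along
  the cephalad–caudad axis (length 92.64 mm, the experimental-group mean),
  elliptical cross-section whose area is derived from the total body volume
  target (20.99 ml) with the ventral-dorsal : lateral aspect ratio — the
  printed bounding dimensions of a real mouse include the limbs and exceed
  the trunk. Seven regions: brain, lungs, heart, kidneys, bladder, skeleton
  and "remaining organs & skin". Ellipsoidal organs at fixed anatomical
  stations are sized analytically to their target volumes (experimental
  means: brain 0.344 ml, … skeleton 1.697 ml); the skeleton is a dorsal
  spine cylinder plus four limb rods whose spine radius absorbs the volume
  target; "remaining" is the body residual. Labels are exclusive, painted in
  listed order with later organs winning (the layout is designed overlap
  free); generation fails loudly if any organ misses its volume target by
  more than 5 %.
* **Intensities.** CT: per-organ HU (air −1000, lungs −500, soft tissue
  35–45, bladder 10, bone 700) plus additive Gaussian noise (SD 20 HU).
  PET: per-organ activity times multiplicative Gaussian noise (SD 10 %),
  clipped at 0. Organ activity means are a plausible FDG-like
  biodistribution (bladder 18, kidneys 6, heart 3, brain 2.5, remaining 1.8,
  skeleton 1.2, lungs 1 arbitrary units; SDs 15–20 %), chosen to reproduce
  the characteristic NMA ordering (bladder ≫ kidneys > others); they are
  package defaults, not literature values.
* **Subjects.** A subject is the atlas warped through a known random
  transform: a 12-DOF affine (translations ≤ 5 mm, rotations ≤ 10°, scales
  0.9–1.1, shears ≤ 0.05) composed with a cubic B-spline field (12 mm
  lattice) rescaled so its maximum body displacement equals the requested
  magnitude. Draws whose warp folds (Jacobian determinant ≤ 0.05 anywhere
  in the body, checked by finite differences) are retried with damped
  magnitude. The label map is resampled through the numerically inverted
  warp (fixed-point iteration on the displacement equation, exact affine
  preconditioning) and CT/PET are re-painted from the warped labels with
  fresh noise and per-subject activity draws (Normal, truncated at 0) — so
  each subject records an exact ground-truth transform and exact
  ground-truth activities.

What the phantom does **not** emulate: reconstruction artifacts and
resolution loss (Feldkamp/MAP), attenuation and scatter, respiratory and
cardiac motion, bladder filling, inter-animal anatomical topology changes,
and the tumour xenografts that dominate the hard experimental cases (an
optional surface lesion exists but is off by default). Passing the synthetic
validation therefore demonstrates that the pipeline recovers known smooth
deformations and preserves quantification under them — not that it handles
gross pathology-driven deformation.

## Metrics and quantification

* Dice and Hausdorff are computed over voxel-centre point sets; the
  directed Hausdorff uses the Euclidean distance transform of the opposite
  region (exact for centre points, anisotropic spacing as EDT sampling),
  with an exhaustive pairwise oracle in the tests. Empty regions yield NaN
  ("missing"), never zero. Agreement-bin boundaries (0.20, 0.40, 0.60,
  0.80) fall in the upper bin.
* NMA normalizes the regional mean by the **body-restricted** PET maximum
  (all nonzero-label voxels). The normalization scope is configurable
  (`"image"` for the global maximum); the body scope avoids background
  noise spikes. Relative error is signed, negative = underestimation.
* The harvested-activity regression is OLS of the estimated mean VOI
  activity on the painted ground truth, per mouse (across regions) and per
  organ (across mice); R² is the squared Pearson correlation. At least 3
  shared regions and nonzero truth variance are required.

## Problem sizes and determinism

Default study conditions: 0.4 mm isotropic grid (≈ 248×59×70 voxels),
five-subject cohorts, 2 mm deformation bound, iteration scale 1/8. A full
single-study pipeline takes ~30 s on one CPU; the five-subject acceptance
run a few minutes. Every stochastic component (phantom draws, metric
sampling, optimizer) derives from explicit integer seeds; identical inputs
and seeds give bit-identical results, which the tests assert.

## Known limitations

* Registration accuracy along weakly constrained directions (long-axis
  rotation/shear of a near-axisymmetric body) is the residual-error
  bottleneck; automatic parameter scaling mitigates but does not remove it,
  and occasional draws near the scale/shear bounds recover body overlap of
  ≈ 0.93 rather than ≥ 0.95.
* The bladder — small, hottest, and boundary-dominated — is the consistent
  quantification outlier, as expected from its overlap behaviour.
* Affine inversion is closed-form; composite/B-spline inversion is numeric
  (contractive fixed point) and assumes a non-folding field.
* 4-D (dynamic) PET, DICOM input, oblique grids and mutual-information
  metrics are out of scope.
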
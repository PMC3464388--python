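# mousequant

Atlas-guided automated quantification of small-animal PET/CT studies.

Preclinical PET can measure absolute radiotracer concentration per organ, but
drawing volumes of interest (VOIs) by hand on every mouse of a serial study is
slow and operator-dependent. `mousequant` automates the analysis: the
subject's CT is registered to the CT of a pre-segmented anatomical mouse atlas
with a deformable transform, the same transform carries the subject's PET (and
any reference segmentation) into atlas space, and the atlas label map then
defines the VOIs for per-organ activity quantification — no fiducial markers,
no user interaction.

Everything is validated on synthetic voxelized mouse phantoms with known
ground-truth deformations and activities, generated by the package itself.

## Method

**Registration.** The atlas CT is the fixed image *F*, the subject CT the
moving image *M*. A spatial transform *T* maps fixed-space world points
(mm) into moving space; *M* is resampled backward through *T*. Registration
proceeds in three steps, each maximizing the normalized correlation
coefficient (Pearson correlation of paired intensity samples)

&nbsp;&nbsp;&nbsp;&nbsp;NCC(F, M∘T) = cov(F, M∘T) / (σ_F σ_{M∘T})

over 2,500 random sample points redrawn every iteration, with adaptive
stochastic gradient descent (gain γ(t) = a/(A+t)^α) on a 5-level image
pyramid (down-sampling 32, 16, 8, 4, 2; per-level budgets 4096, 4096, 2048,
2048, 1024 iterations, scaled by 1/8 at the default desk-scale grid):

1. **Affine** (12 DOF: translation, rotation, scale, shear) — global
   pre-alignment;
2. **B-spline free-form deformation** — displacements on a cubic B-spline
   control lattice (8 mm default spacing), composed after the affine;
3. **Masked B-spline** — a finer lattice (4 mm) with metric samples
   restricted to a dilated atlas body mask, refining internal organs.

Transforms are saved as ASCII parameter files and can be re-applied to any
volume (PET with third-order B-spline interpolation, labels with
nearest-neighbour).

**Evaluation.** Registration accuracy between a warped segmentation *S* and
the atlas segmentation *T* uses the Dice coefficient
D = 2|S∩T| / (|S|+|T|) (with the kappa-style agreement bins: < 0.20 poor …
0.80–1.00 excellent) and the generalized Hausdorff distance
HD = max(HD_{S→T}, HD_{T→S}), HD_{S→T} = max_{s∈S} min_{t∈T} d(s,t), in mm
over voxel centres.

**Quantification.** The normalized mean activity of region *R* is
NMA(R) = mean PET over R / max PET over the body. Reference NMAs come from
the subject's own PET + segmentation before transformation; automated NMAs
from the transformed PET under the atlas segmentation; the signed relative
error (%) compares them. Ground-truth ("harvested") activities painted into
simulated subjects are correlated against the automated estimates by ordinary
least squares, summarized by R².

## Worked example

```python
from mousequant import (default_phantom_spec, generate_atlas_phantom,
                        sample_subject, run_study, RegistrationConfig)

spec = default_phantom_spec()                      # 0.4 mm grid, 7 organs
atlas = generate_atlas_phantom(spec, seed=0)
subject = sample_subject(atlas, spec, deform_magnitude=2.0, seed=1)

result = run_study(atlas.ct, atlas.pet, atlas.labels,
                   subject.ct, subject.pet, subject.labels,
                   RegistrationConfig(seed=42),
                   truth_activities=subject.truth_activities)
```

Printing the per-step metrics, the post-registration overlap report and the
NMA records gives:

```
per-step NCC: [0.933, 0.9921, 0.9923]
   region     dice    hd_mm agreement
    brain 0.924508 0.894427 excellent
    lungs 0.946567 0.894427 excellent
    heart 0.945503 0.692820 excellent
  kidneys 0.918983 0.692820 excellent
  bladder 0.894683 0.979796 excellent
 skeleton 0.960092 0.894427 excellent
remaining 0.956101 2.800000 excellent
bladder    NMA ref 0.713 auto 0.714  error +0.1 %
brain      NMA ref 0.091 auto 0.090  error -0.5 %
heart      NMA ref 0.109 auto 0.109  error +0.5 %
kidneys    NMA ref 0.162 auto 0.158  error -2.4 %
lungs      NMA ref 0.040 auto 0.041  error +3.3 %
remaining  NMA ref 0.056 auto 0.056  error -0.7 %
skeleton   NMA ref 0.044 auto 0.046  error +2.9 %
```

The NCC rises across the three registration steps; every organ of this
subject lands in the excellent-agreement overlap bin, and the automated NMA
reproduces the reference quantification to within a few percent (the bladder,
small and by far the hottest region, is the error-prone case across a
cohort).

The same operations are available from the shell: `mousequant make-phantom`,
`register`, `transform`, `evaluate`, `quantify`, `run` (full pipeline from a
YAML config) and `cohort`.

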
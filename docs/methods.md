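# Methods

`aslnorm` spatially normalizes arterial-spin-labeling (ASL) perfusion images
of infant brains directly from their CBF contrast, bypassing structural
(T1w) segmentation, which is unreliable while myelination is incomplete and
gray/white contrast is low. This note documents the model, the numerical
choices, and what the synthetic phantoms do and do not establish.

## The pseudo-CBF registration target

The fixed image for registration is not an acquired scan but a synthetic
perfusion image built from the template's tissue-probability maps:

    pseudo_CBF = v_GM * P_GM + v_WM * P_WM,   smoothed to ASL resolution

with reference perfusion values v_GM = 60 and v_WM = 20 ml/100 g/min. These
are population-typical values; they capture the ~3:1 GM:WM perfusion
contrast that makes an ASL CBF map registrable even when structural contrast
is absent. CSF contributes zero perfusion and is not a term. "Smoothing to
ASL resolution" is implemented as a Gaussian whose per-axis FWHM equals the
ASL acquisition voxel size (3.75 x 3.75 x 4.0 mm by default); the true
point spread of a 3-D spiral FSE readout is wider and non-Gaussian, so this
is a configurable approximation.

## Transform model

All transforms map fixed (template) world coordinates (mm, RAS+) to moving
(native) world coordinates — the pull-back convention — so the output image
is always produced by one interpolation, however many stages are composed.

* **Rigid** (6 dof): `T(t) . Rx . Ry . Rz`.
* **Affine** (12 dof): `T . R . Shear . Scale`, scales strictly positive
  (optimized in log-scale).
* **Nonlinear**: `native = Affine(x + u(x))` where the displacement `u` is a
  tensor product of the first K = 16 orthonormal discrete-cosine basis
  functions per axis (3 x 16^3 = 12,288 coefficients, in mm). The constant
  (k = 0) basis term is kept; its redundancy with translation is controlled
  by the optimizer starting from zero coefficients with the affine frozen.
  Composition order (rotations, affine factors, displacement inside the
  affine) is fixed as stated for reproducibility; the conventions follow the
  classic low-frequency-basis spatial normalization literature.

Chains of transforms collapse into one dense deformation field;
consecutive matrix transforms are pre-multiplied, so a linear chain is
numerically identical to its composite matrix.

## Similarity metric and optimization

The cost is scaled SSD: `sum_mask (f - s*m(phi(x)))^2 / sum_mask f^2`, with
`s` the closed-form least-squares intensity scale. Against a same-contrast
pseudo-CBF target this is the natural metric; it is invariant to the global
CBF calibration of the input. The cost is evaluated on every second template
voxel inside the brain mask (the images are pre-smoothed far beyond that
sample spacing).

Resolution matching matters: trilinear sampling of the moving image during
cost evaluation convolves it with a triangle kernel of its own voxel size.
The fixed image is therefore pre-smoothed by that kernel's
Gaussian equivalent (FWHM 0.961 x voxel) in addition to the capture-range
smoothing (8 mm FWHM for rigid/affine, 4 mm for the nonlinear stage).
Without this the optimizer trades geometry for blur: we measured the cost at
the true warp to be *higher* than at a geometrically wrong one.

* Rigid and affine stages: derivative-free Powell search on scaled
  parameters (1 mm / 0.02 rad / 0.02 log-scale / 0.02 shear per unit),
  initialized at the intensity centroid offset. Powell never returns a cost
  above its initialization, which yields the nested-cost guarantees
  (affine <= rigid on the same smoothed pair).
* Nonlinear stage: L-BFGS on the DCT coefficients with an analytic gradient.
  The separable basis makes each gradient a few small tensor contractions
  plus one trilinear sampling pass. The affine part stays frozen. The
  coefficients are optimized in a diagonally preconditioned variable — the
  Gauss–Newton curvature diagonal of the data term (computed once at the
  stage start, again a separable contraction) plus the exact penalty
  curvature. Without preconditioning, the mixed curvature scales of
  data-driven and penalty-dominated modes make quasi-Newton progress per
  iteration vanishingly small long before convergence. The stage stops when
  the per-iteration cost decrease falls below 1e-6 of the current cost, or
  at 300 iterations (one L-BFGS step on 12k coefficients is far weaker than
  one Powell outer iteration, of which rigid/affine get 64).

**Regularization.** The penalty is the bending energy of the displacement
field — the per-voxel mean squared Laplacian, diagonal in DCT space with
weights `((pi*k/Lx)^2 + (pi*m/Ly)^2 + (pi*n/Lz)^2)^2`. The default weight
`lambda_reg = 1.0` (dimensionless, on the normalized cost) was chosen from
the measured energy scales: smooth anatomically plausible warps have
energies of 1e-5–1e-4 under this definition, while the high-frequency
displacement modes that live in the intensity null space of a smooth
brain (tangential sliding, interior drift) reach ~1e-2. λ = 1 leaves the
former essentially free and suppresses the latter.

## The two-iteration nonlinear strategy

The 60/20 defaults are only approximate for an individual subject, and the
nonlinear stage is sensitive to target contrast: a wrong GM:WM ratio makes
the optimizer bend geometry to imitate intensity. The `dct` strategy
therefore runs twice:

1. rigid + affine registration against the default pseudo-CBF, one
   trilinear resample of the CBF image to template space;
2. subject GM/WM perfusion estimated by least squares
   (`cbf ~ a*GM + b*WM` over brain-mask voxels), the pseudo-CBF rebuilt
   with `(a, b)`, and the DCT coefficients fitted against it.

The estimation regressors are the template tissue maps smoothed to the
*effective* resolution of the aligned data: acquisition FWHM combined in
quadrature with the Gaussian equivalent of the interpolation kernel
(0.961 x native voxel). Because smoothing is linear this leaves the model
exact for blurred data; regressing on sharp maps systematically attenuates
the estimated contrast (we measured ~(53, 22) for a true 60/20).
Implausible estimates (b > a or a <= 0) fall back to the defaults with a
warning. Rank deficiency of the tissue design is an error.

The final standard-space CBF is produced by composing all stages into one
deformation field and resampling the native image once, with cubic splines.
Out-of-volume samples are zero (CBF outside the head is ~0); negative CBF
values (ASL noise) are preserved in the output image but clipped to zero by
the QC metric.

## Quality metric: real-valued Tanimoto coefficient

    TC = 100 * sum(ab) / (sum(a^2) + sum(b^2) - sum(ab))

on masked, percentile-normalized intensities: within the brain mask each
image is divided by its own 97th-percentile value (linear interpolation
between order statistics; negatives clipped first), and voxels brighter than
the percentile are excluded. Exclusion is **joint** — a voxel is dropped if
it exceeds either image's percentile — because the formula's 0–100% bounds
require both sums to run over one voxel set. TC is 0% for disjoint images,
100% for identical ones, and > 70% is conventionally read as excellent
agreement between a normalized CBF image and a reference. Region statistics
(mean CBF per atlas label) are computed on the single-interpolation output
without partial-volume weighting.

## The synthetic phantom

The generator makes every stage testable without data downloads. It
emulates:

* a pediatric-like tissue template on a 64^3, 2 mm grid: a lumpy cortical
  GM shell (low-order angular modulation of an ellipsoid), WM core, CSF rim,
  ventricles, and two deep-GM nuclei. The lumps and nuclei are there for
  identifiability: on a perfectly smooth ellipsoid, small rotations and
  tangential displacements slide along isointensity surfaces and no
  intensity metric can recover them;
* ground-truth deformations expressed exactly in the registration's own
  DCT parameterization (order 8), so representability never confounds
  optimizer error: a trigonocephaly-like warp (medially directed anterior
  compression, midline protrusion, mild posterior widening; peak
  displacement = severity x 8 mm; left-right antisymmetric lateral
  component) and/or a smooth random warp with a 1/(1+k+m+n)^2 spectral
  shading, scaled to a stated peak amplitude (4 mm default);
* a global size offset (0.94/0.97/0.95 scales by default): infants are
  scanned before the template age, and this size mismatch is precisely why
  rigid-only normalization underperforms;
* a small rigid offset (3/-2/2 mm, 2/-1/2 degrees), coarse ASL voxels
  (3.75 x 3.75 x 4.0 mm), Gaussian point spread at voxel-size FWHM, and
  additive white noise (sigma 5 ml/100 g/min by default, ~8% of GM signal).

The native image is rendered by inverting the ground-truth transform with a
fixed-point iteration, pulling tissues with cubic splines (linear
interpolation would add ~2.7 mm of implicit blur beyond the stated point
spread), blurring, downsampling and adding noise. Cohorts mix ~69%
"patients" (severity uniform in 0.4–0.8) with controls, matching the
composition of a craniosynostosis study population. All generators are
bit-reproducible under a fixed seed.

**What the phantom does not emulate:** gyral-scale texture, physiological
noise and ASL artifacts (labeling efficiency, transit delay), skull/scalp
signal, the non-Gaussian spiral readout point spread, and anatomical variability
beyond one deformed template. Passing recovery tests therefore
shows the estimator is correct and well-conditioned under its own model
class — it does not certify accuracy on clinical data.

Known quantitative behavior on phantoms (reproduced by the test suite):
mean displacement error of the nonlinear strategy is ~0.7–1.5 mm at 4 mm
warp amplitude; GM-dominant native voxels average ~45 ml/100 g/min for a
true 60 (partial-volume washout of a thin shell at ASL resolution — the
realistic bias direction); and an intensity-null displacement floor of
~0.5–1 mm remains in flat interior regions that no intensity metric can
constrain.

## Structural-mediated baseline

`normalize_via_structural` reproduces the conventional pathway for
comparison: M0 rigidly aligned to a synthetic 60/20 image built from the
subject's (externally produced) tissue segmentations, the structural frame
registered to the template by affine + DCT stages on tissue pseudo-CBF
images, and the joint three-stage chain applied to the CBF image with one
interpolation. Degrading the subject tissue maps (blur + gamma compression,
mimicking low myelination contrast) degrades this route below the direct
perfusion route — the motivating phenomenon for the direct approach.

## Degenerate inputs and tie-breaks

Empty masks, all-nonpositive images within a mask, nonpositive percentiles,
collinear tissue regressors, and 4-D NIfTI inputs raise typed errors rather
than propagating NaNs. Optimizer stages never return a cost above their
initialization (falling back to the initial parameters if the search fails
to improve). Masks resampled with interpolation orders above 0 lose their
mask payload tag; probabilities resampled with cubic splines are clipped
back to [0, 1].

## Problem sizes

Default test and acceptance problem sizes — 64^3 template grid, ~42^3
native grids, 20 rigid trials, 5 nonlinear-recovery seeds, an 8-subject
cohort — were chosen so the full suite exercises every claim at
single-workstation scale; all simulations scale with the spec fields if
larger studies are wanted.
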
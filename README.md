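# aslnorm

Direct spatial normalization of arterial-spin-labeling (ASL) perfusion
images to a standard template space, using the perfusion contrast itself.

## Why

Group analysis of cerebral blood flow (CBF) requires every subject's CBF
map in a common stereotactic space. The conventional route goes through the
subject's structural T1w scan — segment, normalize, carry the ASL along.
In newborns and infants this breaks down: ongoing myelination leaves T1w
images with little gray/white contrast, so segmentation and normalization
fail exactly in the populations (e.g. craniosynostosis patients) where
regional CBF is most interesting. ASL itself, however, shows a robust ~3:1
GM:WM perfusion contrast from early infancy.

`aslnorm` registers the native CBF map directly to a **pseudo-CBF** target
built from the template's tissue-probability maps:

```
pseudo_CBF = 60 · P_GM + 20 · P_WM        (ml/100 g/min)
```

smoothed to the ASL acquisition resolution. Three direct strategies are
provided — rigid (6 dof), affine (12 dof), and nonlinear, the latter a
displacement field spanned by 16 discrete-cosine (DCT) basis functions per
axis composed with the affine:

```
x_native = A · (x + u(x)),     u(x) = Σ_kmn c_kmn B_k(x₁)B_m(x₂)B_n(x₃)
```

fitted by scaled-SSD under a bending-energy penalty. The nonlinear strategy
runs in two iterations: subject GM/WM perfusion is first estimated from the
roughly aligned CBF image (least squares against resolution-matched tissue
maps) and the target is rebuilt with those values before the DCT fit. All
stages are combined into a single joint deformation field, so the output
CBF image is produced with **one** interpolation. A structural-mediated
baseline (`normalize_via_structural`), the masked 97th-percentile
real-valued Tanimoto QC coefficient, atlas region statistics, overlay
montages, and a synthetic pediatric phantom generator complete the toolkit.

## Worked example

```python
import aslnorm as an

# a synthetic infant: 4 mm smooth warp, size + rigid offset, noise σ=5
subject = an.make_subject(an.PhantomSpec(seed=1))

result = an.normalize_asl(subject.native_cbf, subject.template, "dct")

reference = an.build_pseudo_cbf(subject.template)
score = an.real_valued_tc(result.cbf_std, reference, subject.template.brain_mask)
truth = an.compose_to_field([subject.true_transform], subject.template.geometry)
mean_mm, max_mm = an.displacement_error(truth, result.field, subject.template.brain_mask)

print(f"tissue CBF used (GM, WM): ({result.tissue_cbf_used[0]:.1f}, "
      f"{result.tissue_cbf_used[1]:.1f}) ml/100g/min")
print(f"Tanimoto coefficient vs reference: {score.tc_percent:.1f}%")
print(f"residual displacement error: mean {mean_mm:.2f} mm, max {max_mm:.2f} mm")
```

prints

```
tissue CBF used (GM, WM): (59.3, 19.9) ml/100g/min
Tanimoto coefficient vs reference: 98.5%
residual displacement error: mean 0.74 mm, max 1.79 mm
```

The second-iteration tissue estimates recover the phantom's true 60/20
perfusion; the Tanimoto coefficient is far above the 70% "excellent
agreement" convention; and the composed transform lands within a fraction
of an ASL voxel of the ground truth.

The same pipeline is scriptable from the shell:

```bash
aslnorm simulate --n 8 --seed 1 -o cohort/
aslnorm normalize --cbf cohort/sub-000_cbf.nii.gz \
    --template-gm cohort/template_gm.nii.gz \
    --template-wm cohort/template_wm.nii.gz \
    --strategy dct -o out/
aslnorm evaluate out/*_cbf_std.nii.gz \
    --reference cohort/template_pseudo_cbf.nii.gz \
    --mask cohort/template_mask.nii.gz -o tc.csv
```

`normalize` writes, per subject and strategy: the standard-space CBF NIfTI,
a JSON transform container, the optimizer cost trace as CSV, and a 12-axial
+ 12-sagittal overlay montage of CBF with the 50% WM border for visual
rating. `regions` extracts mean CBF per atlas label.

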
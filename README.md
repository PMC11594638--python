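# pvsmap

Quantification of enlarged perivascular spaces (PVS) on brain MRI, with a
statistical analysis layer and synthetic phantoms for validation.

Enlarged PVS — thin fluid-filled tubules around penetrating vessels,
bright on T2-weighted images — are a marker of cerebral small vessel
disease (SVD). `pvsmap` implements the standard computational pipeline for
measuring their regional burden in stroke and SVD cohorts:

1. **Vesselness filtering.** Multiscale 3D Frangi enhancement. At each
   Gaussian scale *s* (in mm), the eigenvalues of the scale-normalized
   Hessian, sorted |λ₁| ≤ |λ₂| ≤ |λ₃|, score each voxel's tubularity:

       V = (1 − exp(−R_A²/2α²)) · exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),

   with R_A = |λ₂|/|λ₃|, R_B = |λ₁|/√|λ₂λ₃|, S = ‖λ‖₂, zeroed where
   λ₂ > 0 or λ₃ > 0 (bright tubes), maximized over scales. Bright-tube
   polarity is used on T2; dark-tube polarity on FLAIR.
2. **Segmentation.** In normal-appearing white matter the T2 vesselness is
   thresholded; inside white-matter hyperintensities (WMH) the T2 and the
   dark-tube FLAIR responses are combined by voxelwise minimum (both
   sequences must agree). Candidates are restricted to the quantification
   regions, lesion areas (lacunes, subacute stroke, plus a rim margin) are
   excluded, and connected components of ≤ 5 voxels (3.65 mm³ at 0.9 mm
   isotropic) are removed as noise. The cohort-wide threshold is calibrated
   against visual PVS ratings by rank correlation.
3. **Quantification.** Fractional PVS volume (%) per region — white matter
   (WM), basal ganglia (BG), brainstem (BS) — the WM/BG-PVS ratio, and
   WMH volume normalized by intracranial volume (WMH/ICV, %).
4. **Statistics.** Pearson/Spearman correlation matrices with R² = r²;
   a nine-candidate transformation ladder (cubic, square, identity, √,
   log, 1/√, 1/x, 1/x², 1/x³) scored by Shapiro–Wilk W and aggregated by
   the worst region; unadjusted and adjusted (age + sex + hypertension)
   OLS regressions of transformed PVS burden on clinical covariates; and
   ANOVA / Kruskal–Wallis tests across burden quartiles.
5. **Phantoms.** Synthetic co-registered T2/FLAIR volumes with a region
   atlas, capsule-shaped PVS of known exact volume, WMH blobs, lacunar
   cavities, noise, and a cohort covariate generator with configurable
   log-scale effects — so every stage can be validated against ground
   truth without patient data.

## Worked example

Segment one synthetic subject and compare with the planted truth:

```python
from pvsmap import (PhantomSpec, FrangiParams, SegmentationParams,
                    generate_atlas, generate_pvs_tubes, generate_lesion_masks,
                    render_sequences, multiscale_max, segment_pvs,
                    compute_subject_metrics)

spec = PhantomSpec(noise_sigma=4.0, tube_radius_mm_range=(1.0, 1.5), seed=42)
atlas = generate_atlas(spec)
truth = generate_pvs_tubes(spec, atlas)
wmh, lacunes = generate_lesion_masks(spec, atlas)
t2, flair = render_sequences(spec, atlas, truth, wmh, lacunes)

v_t2 = multiscale_max(t2, FrangiParams())
v_flair = multiscale_max(flair, FrangiParams(polarity="dark"))
mask = segment_pvs(v_t2, v_flair, atlas, wmh, lacunes, None, SegmentationParams())
metrics = compute_subject_metrics(mask, atlas, wmh)
```

This prints (via the obvious `print` statements):

```
true fractional volumes (%): WM 3.383, BG 7.083, BS 5.714
segmented fractional volumes (%): WM 3.020, BG 6.891, BS 5.268
WM/BG-PVS ratio: 0.438
WMH/ICV: 0.243 %
PVS cluster counts (WM/BG/BS): 18/3/1
Dice vs ground truth: 0.922
```

The segmented fractions track the exact planted fractions within ~10%
despite noise, and the mask overlaps the true tubes with Dice 0.92. The
WM/BG ratio contrasts lobar against deep burden: values < 1 mean the
basal ganglia carry relatively more PVS than the white matter.

On the statistics side, a 500-subject synthetic cohort with planted
effects (lacunes on WM burden, sleep quality / PSQI on the WM/BG ratio,
both acting on the log scale):

```python
from pvsmap import generate_cohort_table, select_transformation, fit_models, EffectConfig

table = generate_cohort_table(500, EffectConfig(), seed=7)
ladder = select_transformation({r: table[f"frac_{r}"].to_numpy()
                                for r in ("wm", "bg", "bs")})
res = fit_models(table, "frac_wm", ["lacune_count"], adjust=True, transform=ladder)[0]
```

```
chosen transformation: logarithmic
frac_wm ~ lacune_count (adjusted): beta=0.1047, p=1.03e-21, R2=38.4%
wm_bg_ratio ~ psqi (adjusted): beta=0.0406, p=3.06e-13, R2=14.4%
```

The ladder recognizes the log-normal outcome, and the adjusted models
recover the planted coefficients (0.12 and 0.04) within sampling error.

## Command line

```
pvsmap simulate  --out phantom/ --seed 1 --n-subjects 20
pvsmap vesselness --in phantom/t2.nii.gz --scales 0.5,0.9,1.4,2.0 --out v.nii.gz
pvsmap segment   --t2 ... --flair ... --atlas ... --wmh ... --lacunes ... --out mask.nii.gz
pvsmap quantify  --mask mask.nii.gz --atlas ... --wmh ... --out metrics.json
pvsmap stats     --table cohort.csv --outcome frac_wm --out models.csv
pvsmap run       --out run/ --seed 1 --n-subjects 20
```

All volumes are NIfTI-1 (`.nii.gz`), tables are CSV, configs are YAML, and
`pvsmap run` writes a manifest with per-file checksums so a run can be
reproduced bit-for-bit.

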
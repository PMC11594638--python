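# Methods

This note documents the models, parameters, and design choices behind
`pvsmap`, and what the synthetic-phantom validation does and does not
establish about real data.

## Vesselness operator

The tubularity score is the classic three-term Frangi filter on the
eigenvalues of the scale-normalized Gaussian Hessian. Implementation
details that matter:

- **mm-true derivatives.** Gaussian smoothing scales are specified in mm;
  the per-axis sigma passed to the separable filters is `scale / spacing`,
  so anisotropic grids are handled correctly. Derivatives are divided by
  the voxel spacing of each differentiated axis and the Hessian is
  multiplied by `scale²` so responses are comparable across scales.
- **DC removal.** The volume mean is subtracted before filtering. Truncated
  derivative-of-Gaussian kernels are not exactly zero-sum, so without this
  a constant offset leaks a small spurious Hessian; with it the operator
  is exactly invariant to intensity shifts and a constant volume maps to
  identically zero eigenvalues.
- **Boundary handling** is reflective, which avoids spurious responses at
  the volume faces.
- **Eigenvalues** come from `numpy.linalg.eigvalsh` on the stacked 3×3
  symmetric matrices and are re-sorted by absolute value, the ordering
  the Frangi ratios are defined on.
- **Constants.** α = β = 0.5. The structureness constant c defaults to
  `"auto"`: half the maximum Hessian Frobenius norm at each scale. On
  images whose strongest second-order structure is not the tubules
  themselves (lesion rims, tissue interfaces) this compresses the tube
  response into the lower part of [0, 1]; we evaluated quantile-based
  robustifications (half the 99th percentile, quarter of the max) and
  found they widen the flat region of the threshold-calibration objective
  without improving recovery, so the canonical definition stands. All
  constants are exposed in `FrangiParams`.
- **Scales** default to {0.5, 0.9, 1.4, 2.0} mm, spanning sub-voxel to the
  conventional upper caliber of enlarged PVS (≈3 mm diameter) at the
  0.9 mm isotropic T2 geometry the defaults assume.
- **Polarity.** Bright-tube on T2. Dark-tube (PVS are CSF-dark on FLAIR) is
  implemented by negating the input, which flips the eigenvalue signs.

## Segmentation

Fixed stage order: combine → threshold → region restriction → lesion
exclusion → cluster filter. Rationale for each:

- **Dual-sequence combination.** Inside the WMH mask the T2 vesselness is
  replaced by the voxelwise minimum of T2 (bright) and FLAIR (dark)
  responses — a fuzzy AND. Requiring both sequences to agree is the most
  false-positive-averse combination rule; outside WMHs the T2 response is
  used alone.
- **Region restriction.** Candidate voxels are limited to the three
  quantification regions (WM, BG, BS). PVS are measured there, and the
  intracranial boundary — which lies outside every region — otherwise
  contributes edge responses that are never of interest.
- **Lesion exclusion with a rim margin.** Lacune and stroke masks are
  dilated (default 2 × 26-neighbourhood iterations ≈ 1.8 mm at 0.9 mm
  voxels) before subtraction. Cavity rims are bright on T2 and generate
  curvilinear vesselness just outside the lesion; without the margin,
  zero-PVS phantoms segment small rim clusters. Exclusion runs *before*
  cluster filtering so lesion remnants cannot keep a sub-threshold cluster
  alive.
- **Cluster filter.** Connected components with ≤ 5 voxels (3.65 mm³ at
  0.9 mm isotropic) are removed under 26-connectivity; 26 keeps obliquely
  oriented tubes connected. The cutoff counts voxels, not mm³.
- **Idempotence.** Filtering a filtered mask is a no-op, tested.

### Threshold calibration

One vesselness threshold is chosen for the whole cohort by maximizing the
Spearman correlation between per-subject fractional volumes and visual PVS
ratings, with exact ties broken toward the higher (more conservative)
threshold. Two details make this well-posed:

- **Per-region ratings.** When separate BG and WM ratings are available,
  each region's fractional volume is correlated with its own rating and
  the correlations are averaged. This doubles the rank constraints and
  substantially sharpens the optimum.
- **Cohort heterogeneity.** On a perfectly homogeneous cohort any
  threshold that preserves the subject ordering ties at the same
  correlation, and the tie rule drifts conservative. Real cohorts are
  heterogeneous — subjects differ in PVS caliber and contrast — and that
  heterogeneity is what pins the optimum: subjects with fainter, thinner
  PVS lose their segmentations first as the threshold rises. The
  reference calibration cohort (`pvsmap.pipeline.build_phantom_cohort`)
  therefore draws a per-subject caliber factor (radius range shifted by up
  to 0.3 mm) and a per-subject PVS contrast jitter (±20 intensity units).

The default `SegmentationParams` thresholds (0.15 for both NAWM and WMH
compartments) are the operating point produced by
`pvsmap.pipeline.reference_calibration()` on that fixed reference cohort —
calibrated once and applied cohort-wide, exactly as a single cohort-wide
threshold is fixed against visual ratings in practice. Recalibrate when
changing filter scales, constants, contrast model or voxel geometry.

## Quantification

Fractional PVS volume is `100 × |mask ∩ region| / |region|` in voxels.
Region denominators include WMH areas (PVS are detected inside WMHs and
belong to the WM compartment). The WM/BG ratio is undefined when the BG
fraction is zero and is reported as missing. Cluster counts assign each
surviving component to the region holding the majority of its voxels,
ties to WM. WMH burden is `100 × |WMH| / |ICV|`; a WMH voxel outside the
ICV is treated as a registration fault and raises.

## Statistics

- **Correlations.** Pearson r (with R² reported as r², an identity that is
  asserted rather than recomputed separately) and Spearman rho with
  average ranks for ties; pairwise complete observations.
- **Transformation ladder.** Nine candidates: x³, x², x, √x, log x, 1/√x,
  1/x, 1/x², 1/x³. Candidates mapping any observation to a non-finite
  value (domain guards: log and reciprocal-family require positives) are
  disqualified. Normality is scored by Shapiro–Wilk W per region and
  aggregated by the minimum across the three regions — the worst region
  decides — and the maximizing candidate wins; exact ties break by ladder
  order. Log-normal burdens therefore select the logarithm.
- **Regressions.** OLS via statsmodels. Unadjusted: outcome ~ regressor.
  Adjusted: outcome ~ regressor + age + sex + hypertension (the covariate
  set is configurable); when the regressor *is* one of the covariates its
  adjusted row is read from the covariates-only model. Binary encodings:
  female = 1, hypertension = 1. Complete-case per model. A regressor
  constant or collinear with a covariate is flagged degenerate, not
  fitted. No multiple-testing correction: each regressor is tested
  marginally, two-sided, at α = 0.05.
- **Quartile tests.** Type-7 quantiles, ties to the lower bin, empty bins
  merged downward with a warning; one-way ANOVA for continuous variables
  and Kruskal–Wallis for ordinal/skewed ones.

## Phantom generator

What it emulates: three disjoint regions with roughly anatomical topology
(WM as a thick ellipsoidal shell, BG as paired central ellipsoids, BS as
an inferior cylinder, all inside an ellipsoidal ICV); PVS as capsules
(cylinders with hemispherical caps) of configurable radius/length,
uniformly oriented, wholly contained in their region, rasterized by
voxel-center inclusion so the true volume is an exact voxel count; WMH
blobs (FLAIR-bright) in WM; lacunar cavities (T2-bright, FLAIR-dark) with
tissue precedence lacune > PVS > WMH > tissue; piecewise-constant
contrast plus additive Gaussian noise (Rician available by flag, default
σ = 5 on ~100-intensity tissue, i.e. SNR ≈ 20; segmentation operates far
above this floor).

The cohort generator draws covariates with the frequencies typical of an
RSSI population (27% female, 66% hypertension, mean age 70, overdispersed
lacune counts, mostly-zero microbleed counts, ~1% WMH/ICV) and produces
latent regional burdens from a log-scale linear model: centered covariate
effects plus a shared per-subject severity factor (SD 0.30) that couples
the three regions, plus region noise (SD 0.35), exponentiated. Mean
burdens default to 4.0 / 1.1 / 0.6 % (BG / WM / BS). Default effect sizes
(per-year age 0.02, hypertension 0.3–0.5, per-lacune 0.05–0.12, PSQI on
the WM-only equation 0.04) are on the scale such regressions report on
the log scale. The PSQI coefficient enters only the WM equation, so it
surfaces in the WM/BG log-ratio. `EffectConfig.null()` zeroes every
effect for type-I-error studies.

What the phantoms do **not** emulate: bias fields, motion, partial-volume
fading at tube ends, curved or branching PVS, anatomically faithful region
shapes, spatially correlated noise, or any coupling between a subject's
covariates and their lesion geometry beyond the planted burden scaling.
Passing recovery tests therefore demonstrates the correctness of the
operator/threshold/metric chain under known geometry — not field
performance on clinical MRI, which additionally depends on registration,
atlas quality and manual editing.

## Validation problem sizes

Recovery runs use 64³ voxel grids (0.9 mm isotropic) with ~14/4/3 expected
tubes in WM/BG/BS and 10–12 subjects per cohort; ladder and regression
studies use n = 500 subjects × 100 replicates and 200 null replicates at
n = 100. These sizes keep the full validation suite in the minutes range
on a single CPU while leaving all statistical checks well-powered.

## Known limitations

- Tubes thinner than half a voxel may vanish under rasterization (a
  warning is issued); sub-voxel PVS are genuinely at the resolution limit
  of the acquisition the defaults model.
- The rank-based threshold calibration identifies ordering fidelity, not
  volumetric scale; its tie-breaking is conservative by design. The
  shipped default threshold comes from the reference calibration described
  above, and cohorts with very different contrast need recalibration.
- The brainstem region is small; per-subject BS fractions are noisy, and
  stable estimates need pooling across subjects (the validation pools
  voxels over the cohort).
- Visual scores in phantoms are deterministic quantile bins of true
  burden; real ratings add observer noise, which weakens calibration in
  ways the phantoms do not probe.
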
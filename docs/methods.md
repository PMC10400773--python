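# Methods

## The measurement

The glymphatic system clears interstitial waste through perivascular
channels. At the level of the lateral-ventricle body, three tissue
orientations coexist in a small neighbourhood: projection fibers (corona
radiata) run head–foot, association fibers (superior longitudinal
fasciculus) run anterior–posterior, and the perivascular spaces around the
medullary veins run left–right — perpendicular to both tracts. Diffusion
along x in those two fiber regions therefore cannot be explained by the
fiber architecture, and its excess over the cross-fiber diffusivities is
read as water movement along the perivascular space:

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

where Dxx/Dyy/Dzz are diffusion-tensor diagonal entries (mm²/s) averaged
over 5 mm-radius spherical ROIs in the projection and association fiber
regions of each hemisphere. The bilateral index is the unweighted mean of
the two hemispheric indices. An index of 1 means no preferential
perivascular diffusion; healthy adults sit around 1.4–1.6 and the index
declines with glymphatic impairment.

Axis convention throughout the package: x = left–right (perivascular),
y = anterior–posterior (association-fiber axis), z = head–foot
(projection-fiber axis). This is the convention under which the formula's
Dyy_proj and Dzz_assoc are cross-fiber diffusivities, which is what makes
the ratio meaningful.

## Tensor estimation

The single diffusion tensor is fitted per voxel by ordinary least squares
on the log signal, `ln S_i = ln S0 − b_i g_iᵀ D g_i`, with design row
`[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]`. Choices:

- **OLS, not WLS or nonlinear.** At the signal-to-noise ratios the package
  targets, OLS is exact on noise-free data and unbiased enough under
  moderate Rician noise (the tests bound the median per-element error at
  SNR 50 below 5% of the mean diffusivity). A weighted fit is a natural
  extension and is deliberately left out of scope.
- **b=0 handling.** Multiple b=0 volumes are averaged into one measurement
  before fitting.
- **Degenerate voxels.** Voxels outside the mask or with any non-positive
  signal are skipped and flagged, never fatal.
- **Eigenvalue clamping.** Noise can make fitted tensors indefinite.
  Eigenvalues are clamped at zero for FA/MD (keeping FA in [0, 1]); the raw
  tensor diagonals are retained unclamped because the ALPS ratio consumes
  the fitted Dxx/Dyy/Dzz, not the spectrum.
- **Smoothing.** Scalar maps can be smoothed with an isotropic Gaussian
  (default FWHM 6 mm) using mask-normalized convolution, so values outside
  the mask never bleed in and constants are preserved. Smoothing is applied
  to derived maps, not to the raw DWI. Spatial normalization to a template
  is out of scope: inputs are assumed to share a 2 mm grid, which the
  phantom generator guarantees by construction.

ROI means are taken on smoothed maps by default (matching the order
normalize → smooth → extract); the analytic-value validations run on
unsmoothed maps, because on a small phantom the 6 mm kernel deliberately
blends the isotropic background into the fiber regions and the analytic
ratio is only exact without that blending.

## The phantom

`generate_phantom_dwi` builds a 24×24×12-voxel volume (2 mm isotropic)
with four non-overlapping fiber boxes (left/right × projection/association)
in an isotropic background:

| region       | tensor (diagonal)            | principal axis |
|--------------|------------------------------|----------------|
| projection   | (Dxx, d_perp, d_axial)       | z (head–foot)  |
| association  | (Dxx, d_axial, d_perp)       | y (ant–post)   |
| background   | d_perp · I                   | —              |

with `Dxx = d_perp + g·(d_axial − d_perp)`. The single parameter
`g ∈ [0, 1]` is the phantom's glymphatic dial: the noise-free ALPS index is
analytically `Dxx / d_perp`, equal to 1 at `g = 0` with equal diffusivities
and strictly increasing in g. Defaults `d_axial = 1.4e-3`,
`d_perp = 0.4e-3 mm²/s`, `S0 = 1000`, b = 1000 s/mm² with 32 spread
directions (golden-spiral hemisphere relaxed by antipodally symmetric
electrostatic repulsion; deterministic) are plausible white-matter values;
at `g = 0.5` the analytic index is 2.25. Noise is Rician,
`sqrt((S+n1)² + n2²)`, because magnitude MR data is the modality being
emulated. ROIs are returned centered in each fiber region with the standard
5 mm radius.

What the phantom does **not** emulate: anatomy, partial volume, crossing
fibers within a voxel, eddy currents, motion, susceptibility distortion, or
any spatial normalization error. Passing the phantom checks shows the
numerics are right, not that the index is robust to real-world confounds.

## The synthetic cohort

`generate_cohort` draws a three-group cohort (NC / MCI / AD; default sizes
111/120/69) whose demographics (age, education, gender ratio), Fazekas
white-matter-hyperintensity scores (integers clamped to [0, 6]) and
thirteen cognitive scales follow configurable per-group means and SDs taken
from the clinical characteristics of the emulated study population.

Generation model per subject, given group g and a latent severity
`z ~ N(0,1)`:

- biological ALPS = group mean + covariate effects + `sd·z`, with additive
  effects of centered age (−0.004/yr), education (+0.003/yr) and WMH
  (−0.012/point);
- measured bilateral ALPS = biological + batch location + batch scale ×
  residual; L/R hemispheres are Bi ± a symmetric N(0, 0.03) asymmetry, so
  Bi = (L+R)/2 holds exactly;
- ROI-mean FA = group mean + SD·(0.3·z + √(1−0.09)·ε) — weakly coupled to
  the same latent so that FA carries some, but less, disease signal;
- each scale = group mean + SD·(ρ·z + √(1−ρ²)·ε) with coupling magnitude
  ρ = 0.25, negative for the scales where worse performance means higher
  scores (IADL, TMT-A, TMT-B). The programmed ρ is realized as the
  ALPS–scale correlation exactly when batch and covariate effects are
  absent; that configuration is what the convergence tests use.

Batch structure follows the three acquisition protocols of the emulated
study (proportions 0.53/0.32/0.15) with location effects (0, +0.06, −0.04)
and scale effects (1, 1.15, 0.9) applied to the ALPS features only; FA is
generated batch-free.

The ALPS group means are not published for the emulated population, so they
are a design choice of this package: NC 1.52, MCI 1.40, AD 1.30 (SD 0.12),
in the range reported across the ALPS literature. The NC–MCI gap is set
wider than the MCI–AD gap deliberately: the groups differ in age, education
and WMH, and covariate adjustment without group in the design (the
protocol emulated here) absorbs part of the group gradient into the
covariate fit. The programmed gradient is chosen so that the defining
qualitative pattern — a significant covariate-adjusted NC-vs-MCI and
NC-vs-AD difference, correctly signed FDR-surviving ALPS–cognition
correlations, and better classification with FA+ALPS than FA alone —
is actually present in the generated population.

Ground truth (latent severities, batch-free ALPS, generating parameters)
is returned as a sidecar object and never written into the cohort CSV.

## Harmonization

ComBat models feature j of subject i in batch b as
`y = α_j + X β_j + γ_bj + δ_bj ε`. Fitting standardizes each feature by
the covariate-adjusted grand mean and pooled SD, estimates per-batch
location/scale, shrinks them across features with parametric empirical
Bayes (normal prior on location, inverse-gamma on scale, moment-matched
hyperparameters, iterative conditional updates to `max|Δ| < 1e-4` or 100
iterations), adjusts, and re-adds the covariate effects. Choices:

- Group is included among the harmonization covariates by default so the
  biological signal is protected.
- A single batch degrades to a warned pass-through rather than an error.
- With a single feature the across-feature priors are undefined, so the
  estimator falls back to unshrunk location/scale adjustment.
- Per-batch scale estimates use the ddof=0 variance; with this convention
  the non-EB adjustment is exactly idempotent (re-harmonizing harmonized
  data is a no-op to machine precision), which the tests exploit. The EB
  adjustment is idempotent only approximately, because shrinkage leaves a
  small residual batch mean; the tests bound it loosely instead.
- Harmonization applies to the ALPS/FA feature table, never to images.

Test–retest stability is summarized by ICC(2,1) — two-way random effects,
absolute agreement, single measurement, from the two-way ANOVA mean
squares — plus a paired t test. ICC(2,1) is chosen over ICC(3,1) because
cross-scanner test–retest should penalize systematic offsets; ICC(3,1) is
available via an option.

## Statistics

- **Adjustment** is residualize-then-test: each feature is replaced by its
  OLS residual on [intercept, gender (female=1), age, education, WMH]
  before the one-way ANOVA. Because the covariates are confounded with
  group in the emulated design, this is conservative for group contrasts
  (see the cohort section).
- **Post-hoc**: Tukey HSD with adjusted p-values and the usual star codes.
- **Partial correlation**: residualize both variables on the covariates,
  Pearson-correlate the residuals, p from `t = r·√((n−2−k)/(1−r²))` with
  df = n−2−k. Missing values are handled by pairwise deletion per
  (feature, scale) cell with the effective n reported.
- **Multiplicity**: Benjamini–Hochberg across the full feature × scale
  grid of a family; the domain-general scales (MoCA-B, MMSE, IADL) and the
  ten domain-specific scales form separate families.

## Classification

Linear-kernel SVM (one or two standardized features cannot justify more),
RBF available via config. Per repeat: stratified 4:1 train/test split;
5-fold CV on the training portion selects C from {0.01, 0.1, 1, 10, 100}
by AUC; refit on the full training portion; decision scores on the test
fifth give one ROC/AUC. 100 repeats by default; the summary is the mean
AUC with a 2.5/97.5 percentile interval over repeats. Standardization
parameters come from training data only. All randomness flows from one
seed through deterministically derived per-repeat seeds, so results are
bit-reproducible. The FA feature fed to the classifier is the mean FA over
the four ALPS ROIs.

## Numerical and calibration checks

The acceptance layer recomputes, from freshly generated inputs:

- exactness of the tensor fit and of the ALPS identities (isotropy → 1.0;
  g=0.5 → 2.25; strict monotonicity in g);
- ComBat recovery on a two-batch simulation (additive offset 5, residual
  scale ×2, n=200/batch, balanced group effect 1.0, residual SD 0.25 over
  4 features — the SD chosen so the sampling error of the recovered group
  effect is well inside the 10% reporting band);
- ICC recovery from variance components (3, 1) → 0.75 at n = 2000;
- null calibration: 1000 null cohorts (n = 20/group, all effects zero) for
  the adjusted-ANOVA rejection rate at α = 0.05 and the fraction of
  FDR-significant correlation cells;
- SVM/AUC calibration against the analytic value for equal-variance
  Gaussian classes, `AUC = Φ(d/√2)`: d = 1 at n = 1000/class (sampling SE
  of the empirical AUC ≈ 0.011, so the comparison is meaningful), label
  permutation at chance, d = 10 near 1;
- the full disease-pattern analysis on the default cohort, including the
  FA-vs-FA+ALPS AUC comparison;
- byte-level determinism of two identical end-to-end CLI runs.

Problem sizes are the package's own choices balancing statistical
resolution against a desk-scale single-CPU run.

## Known limitations

- The phantom validates numerics, not robustness to anatomy or artifacts;
  no registration, eddy/motion correction or skull stripping is provided.
- ROI placement is coordinate-driven (config or phantom geometry); there is
  no automatic localization of the lateral-ventricle plane.
- Parametric ComBat only; no ComBat-GAM or longitudinal variants.
- The cohort generator's linear latent-coupling model produces elliptical
  feature–scale dependence; real scale distributions are bounded, skewed
  and often floor/ceiling-limited, so generated scores are left unbounded
  rather than pretending otherwise.
- Single-tensor model only; crossing-fiber voxels are out of scope.
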
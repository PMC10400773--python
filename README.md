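# dtialps

Analysis pipeline for **DTI-ALPS**, the diffusion-MRI index of water
movement **a**long the **p**erivascu**l**ar **s**pace, used as a
non-invasive proxy for glymphatic (brain waste-clearance) function in
studies of the Alzheimer's disease continuum (normal control → mild
cognitive impairment → AD dementia).

At the level of the lateral ventricles, projection fibers run head–foot
(z), association fibers run anterior–posterior (y), and the perivascular
spaces around the medullary veins run left–right (x), perpendicular to
both tracts. Excess x-diffusivity inside the two fiber regions is
therefore attributed to perivascular flow:

```
ALPS-index = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

with Dxx/Dyy/Dzz the diffusion-tensor diagonals averaged over 5 mm
spherical ROIs in each hemisphere; the bilateral index averages left and
right. The index is 1 when nothing distinguishes the perivascular
direction and declines as glymphatic function deteriorates.

The package is aimed at imaging/biostatistics researchers who want the
whole published analysis protocol as tested, scriptable code:

- **`dtialps.tensor`** — log-linear (OLS) diffusion-tensor fit from
  NIfTI + FSL bval/bvec inputs; FA/MD/directional-diffusivity maps;
  mask-normalized Gaussian smoothing.
- **`dtialps.alps`** — sphere ROIs in world coordinates, ROI-coordinate
  averaging across subjects, diffusivity extraction and the ALPS formula.
- **`dtialps.harmonize`** — ComBat empirical-Bayes batch harmonization
  (scikit-learn transformer style) plus ICC(2,1)/paired-t test–retest
  stability.
- **`dtialps.stats`** — covariate residualization (gender, age,
  education, Fazekas WMH score), one-way ANOVA with Tukey HSD post-hoc,
  partial correlations with 13 cognitive scales, Benjamini–Hochberg FDR.
- **`dtialps.classify`** — repeated-split linear-SVM classification
  (stratified 4:1 split, 5-fold CV model selection, 100 repeats) with
  ROC/AUC and percentile confidence intervals.
- **`dtialps.synthetic`** — DWI phantoms with known tensor geometry and a
  single glymphatic-activity parameter g (noise-free ALPS = analytically
  known), and three-group cohort tables with programmed effect sizes,
  covariate structure and scanner-batch effects — ground truth for every
  downstream stage.
- **`dtialps` CLI** — `simulate-dwi`, `simulate-cohort`, `fit-tensor`,
  `compute-alps`, `harmonize`, `analyze`, `classify`, `run-all`, all
  seeded and byte-reproducible.

See `docs/methods.md` for the model, the generator's assumptions and the
numerical choices.

## Worked example

Phantom arm — simulate a noisy DWI phantom at glymphatic activity
g = 0.5 (analytic ALPS = 2.25), fit tensors, compute the index:

```python
import dtialps as d

gtab = d.default_gradient_table()                 # 1 b0 + 32 dirs, b = 1000
spec = d.default_phantom_spec(g=0.5, noise_sigma=10.0, seed=0)
dwi, truth, rois = d.generate_phantom_dwi(spec, gtab)
maps = d.derive_maps(d.fit_tensor_loglinear(dwi, gtab))
res = d.compute_alps(maps, rois)
```

prints (via the obvious f-strings):

```
L-ALPS  = 2.2491
R-ALPS  = 2.2574
Bi-ALPS = 2.2532   (analytic, noise-free: 2.25)
ROI-mean FA = 0.5071
```

Rician noise at SNR 100 perturbs the index by ~0.2%; noise-free it matches
the analytic value to <1e-3.

Cohort arm — generate the default three-group cohort (111 NC / 120 MCI /
69 AD, programmed NC > MCI > AD ALPS gradient), harmonize across scanner
batches, and run the group-difference, correlation and classification
analyses:

```python
from dtialps.harmonize import combat_harmonize
from dtialps.stats import (encode_covariates, residualize, anova_oneway,
                           run_correlation_program)
from dtialps.classify import run_classification

df, _ = d.generate_cohort(d.CohortGenSpec(seed=0))
feats = ["L_ALPS", "R_ALPS", "Bi_ALPS", "FA_mean"]
cov = encode_covariates(df, ("group", "gender", "age", "education", "WMH"))
df[feats], _ = combat_harmonize(df[feats], df["batch"], covariates=cov)

resid = residualize(df["Bi_ALPS"], encode_covariates(df))
anova = anova_oneway(resid, df["group"])
corr = run_correlation_program(df)            # domain-general scales
cls = run_classification(df, pairs=(("NC", "AD"),),
                         feature_sets=("FA", "FA+ALPS_Bi"),
                         n_repeats=25, seed=0)
```

Output:

```
one-way ANOVA on adjusted Bi-ALPS: F = 70.17, p = 1.10e-25
group1 group2  mean_diff        p_adj stars
    NC    MCI   0.117514 9.146017e-12   ***
    NC     AD   0.218289 1.143530e-14   ***
   MCI     AD   0.100775 3.335593e-07   ***

feature  scale         r            p            q   n  significant stars
Bi_ALPS   IADL -0.473580 5.940889e-18 7.638285e-18 300         True   ***
Bi_ALPS   MMSE  0.548722 1.132525e-24 2.038545e-24 300         True   ***
Bi_ALPS MoCA-B  0.646566 1.964181e-36 8.838812e-36 300         True   ***

NC_vs_AD FA:          mean AUC = 0.7487 (95% CI 0.5532–0.8831)
NC_vs_AD FA+ALPS_Bi:  mean AUC = 0.9640 (95% CI 0.9182–1.0000)
```

Read: the adjusted bilateral index separates all three stages (Tukey
p < 0.001 for each pair); it correlates positively with the cognitive
screens (MMSE, MoCA-B) and negatively with the disability scale (IADL),
all surviving FDR; and adding the index to ROI-mean FA lifts NC-vs-AD
discrimination substantially. Magnitudes are properties of the programmed
generator, not clinical estimates.

The same pipeline end-to-end from a shell:

```bash
dtialps run-all --out results/demo --config examples/fixture_config.yaml --seed 7
```

writes the phantom, tensor maps, `alps.csv`, the cohort tables, ANOVA and
correlation CSVs, `classification.json` and timestamp-free provenance
records; a second run with the same seed is byte-identical.

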
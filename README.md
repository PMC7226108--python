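# bcradiomics

MRI-radiomics pipeline for predicting **biochemical recurrence (BCR)** and
recurrence-free survival after radical prostatectomy from a single ADC-map
texture feature: the **small-zone emphasis (SZE)** of the grey-level
size-zone matrix (GLSZM).

After surgery for high-risk prostate cancer, clinicians must decide between
adjuvant radiotherapy and early-salvage radiotherapy. Clinical covariates
(stage, margins, Gleason score, PSA) stratify this already-selected
population poorly; a pre-operative imaging biomarker can do better. This
package reimplements that analysis as a tested, reusable library for
researchers who want to train, harmonize, freeze and externally validate
single-feature threshold models on volumetric imaging cohorts.

## The model

For a delineated tumour ROI, intensities are discretized to $N_g$ grey
levels (fixed bin number, default 64). The GLSZM entry $P(i,j)$ counts the
maximal 26-connected 3-D *zones* of discretized level $i$ and size $j$
voxels. With $N_z = \sum_{i,j} P(i,j)$ zones,

$$\mathrm{SZE} \;=\; \frac{1}{N_z}\sum_{i,j}\frac{P(i,j)}{j^{2}} \in (0, 1],$$

equal to 1 exactly when every zone is a single voxel. Low SZE means large
homogeneous zones; the recurrence model predicts BCR when
$\mathrm{SZE} \le c$, with the cut-off $c$ chosen on the training cohort by
the Youden index $J = Se + Sp - 1$ and then **frozen** for external
validation. Survival separation of the predicted classes is quantified by
Kaplan–Meier curves, the log-rank test and Cox hazard ratios. Multi-scanner
feature tables are harmonized with parametric empirical-Bayes **ComBat**
before modelling, and inter-reader delineation stability is assessed with
DICE, average Hausdorff distance and ICC(2,1)/(2,k).

The package also provides the single-level undecimated coiflet-1 wavelet
bank (8 sub-band images per volume) as candidate feature sources, clinical
covariate derivations (risk-factor count, Roach lymph-node risk, CAPRA-S,
the 0.2 ng/mL confirmed-rise BCR rule), and a synthetic-data module that
generates textured ellipsoidal phantoms and full two-institution cohorts
with scanner batch effects and feature-linked recurrence hazards — no
patient data are required to exercise any stage.

## Worked example

```python
from bcradiomics import (PhantomSpec, generate_phantom, extract_roi,
                         discretize_fbn, build_glszm, small_zone_emphasis,
                         RunConfig, run_retrain, run_validate,
                         two_institution_specs, generate_cohort)

# one textured phantom: coarse zones (theta = 8 voxels) -> low SZE
vol, mask = generate_phantom(PhantomSpec(theta=8.0, n_levels=16, seed=0))
roi = extract_roi(vol, mask)
sze = small_zone_emphasis(build_glszm(discretize_fbn(roi, 64)))
print(f"phantom SZE (theta=8): {sze:.3f}")

# a full synthetic two-institution study (train n=107, validate n=88)
train_spec, test_spec = two_institution_specs(seed=1)
train, test = generate_cohort(train_spec), generate_cohort(test_spec)
config = RunConfig()
result = run_retrain(config, train.features, train.clinical)
report = run_validate(config, result.models, test.features, test.clinical)

m = result.models["radiomics"]
tr = result.report["training"]["radiomics"]
va = report["validation"]["radiomics"]
print(f"radiomics cut-off: SZE <= {m.cutoff:.2f}")
print(f"training:   AUC {tr['auc']:.2f}, BAcc {100*tr['BAcc']:.0f}%, "
      f"HR {tr['stratification']['HR']:.1f}")
print(f"validation: AUC {va['auc']:.2f}, BAcc {100*va['BAcc']:.0f}%, "
      f"HR {va['stratification']['HR']:.1f}, "
      f"log-rank p = {va['stratification']['logrank_p']:.1e}")
```

prints

```
phantom SZE (theta=8): 0.060
radiomics cut-off: SZE <= 0.63
training:   AUC 0.66, BAcc 67%, HR 5.3
validation: AUC 0.66, BAcc 67%, HR 3.6, log-rank p = 1.3e-02
```

The phantom's coarse zoning drives SZE far below 1. In the simulated
study, the single-feature model learns that *low* SZE marks recurrence
(direction `<=`), its Youden cut-off lands near the generative risk
threshold, and the frozen model still stratifies recurrence-free survival
in the unseen second cohort — the same qualitative behaviour the method
shows on real cohorts, at simulation-scale effect sizes.

A command-line interface mirrors the workflow
(`bcradiomics simulate | extract | harmonize | retrain | validate |
variability`); run `bcradiomics --help`.

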
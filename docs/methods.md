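# Methods

This note records the models, conventions and design choices behind
`bcradiomics`, in the order the pipeline applies them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Images, grids and the ROI

Volumes are 3-D scalar arrays indexed `(x, y, z)` (0-based) with voxel
spacing in mm; all physical distances go through the spacing, never raw
indices. Masks are uint8 on the same grid; any value > 0 is foreground.
NIfTI is the interchange format (nibabel), with a JSON provenance sidecar
per written file. Loading rejects NaN/Inf voxels outright rather than
imputing. Each (volume, mask) pair is treated independently; no
registration between sequences is attempted. Optional isotropic
resampling (linear for images, nearest for masks) exists but is **off by
default**, since the analysis is defined on the native grid; when used it
is recorded in provenance.

## Wavelet filter bank

`wavelet_bank` computes the eight single-level sub-bands LLL…HHH by
separable 1-D convolution with the orthonormal coiflet-1 decomposition
filters (taps from PyWavelets) along each axis. The transform is
**undecimated** (stationary) so every sub-band retains the input shape and
the original tumour mask indexes it directly — the property that makes
sub-bands usable as drop-in feature sources. Boundaries are mirror-padded
(symmetric, no edge repeat). We convolve directly with
`scipy.ndimage.convolve1d` rather than `pywt.swtn` because the stationary
transform in PyWavelets demands even dimensions and periodic boundaries,
neither of which suits arbitrary clinical grids. Character k of a sub-band
label is the filter (L = low-pass, H = high-pass) applied along axis k.

## Discretization and the GLSZM

Intensities inside the ROI are discretized by **fixed bin number**:

    g = min(N, 1 + floor(N * (x - min) / (max - min)))

over the ROI-interior range, with a constant ROI mapping wholly to level 1.
The default is N = 64 bins (a common benchmark setting for this matrix
family); 32/128 are available as a sensitivity flag. FBN makes the feature
invariant to affine intensity rescaling, which the tests assert explicitly.

Zones are maximal connected components of equal-level voxels **within the
mask only**, computed per level with `scipy.ndimage.label`. Connectivity
defaults to 26 (faces + edges + corners), configurable to 18 or 6. The
matrix entry P(i, j) counts zones of level i and size j; the identities
ΣP = N_z and Σ j·P = N_v hold by construction and are re-checked against a
pure-Python flood-fill oracle in the tests. SZE = (1/N_z) Σ P(i,j)/j² is
reported at full float precision; rounding happens only at display time.
Note that SZE ignores the grey-level index entirely, so any permutation of
levels leaves it unchanged.

The direction of the SZE–risk association is **learned from the data**,
not hard-coded: the threshold model orients its rule (`<=` or `>=`) by
which side maximizes the training AUC. On cohorts where large homogeneous
zones mark aggressive tumours, this resolves to "predict recurrence when
SZE ≤ c".

## ComBat harmonization

Multi-scanner feature tables are harmonized with parametric location/scale
ComBat: per-feature standardization against a pooled mean and variance
(optionally after removing protected covariate effects), per-batch
additive (γ) and multiplicative (δ) effects estimated and shrunk by
parametric empirical Bayes (normal prior on γ, inverse-gamma on δ), then
removed. The implementation matches the reference R implementation
(`sva::ComBat`), which a test verifies numerically on a small table.

Choices worth knowing:

- **No covariates are protected by default** (pure technical
  harmonization); a `covariates` argument enables protection and is stored
  in the model file.
- The model is fitted **once, on the pooled table containing every batch
  that validation will see**, and then frozen; applying it to an unseen
  batch label is an explicit error, never a silent pass-through. Pooling
  only informs the batch location/scale estimates — the predictive models
  are still fitted on training rows exclusively.
- Zero-variance features are flagged and passed through untouched; a
  single-batch table yields a warning and a no-op model.
- EB shrinkage means the pooled mean is preserved only to the shrinkage
  magnitude (~1e-2 relative in our simulations), and refitting on
  already-harmonized data changes values by ~0.3% (ddof and prior
  conventions), not by floating-point epsilon. The tests assert these
  realistic bounds rather than exact idempotence.

## Clinical covariates

- **Risk-factor count** (0–3): stage ≥ pT3a, margins R1, Gleason 8–10.
  The clinical model binarizes at > 1 by default (configurable).
- **Roach lymph-node risk** (%): PSA·2/3 + (Gleason − 6)·10, clamped to
  [0, 100], high-risk flag strictly above 15%.
- **CAPRA-S**: summed category points from the vendored table
  (`data/capra_s_points.csv`); high-risk flag strictly above 3.
  Extracapsular extension and seminal-vesicle invasion are derived from
  the pT stage (≥ pT3a and ≥ pT3b); a Gleason total of 7 without a
  recorded primary pattern is scored as 3+4.
- **BCR rule**: two successive PSA samples above 0.2 ng/mL; the event time
  is the first confirmatory sample — the paper-style rule fixes the
  threshold but not the time convention, so the convention is ours and is
  documented here.

## Threshold models

ROC curves are empirical over all distinct score thresholds (via
scikit-learn), AUC by trapezoid — equal to the normalized Mann–Whitney
statistic, which the tests verify to 1e-10. The Youden optimum maximizes
J = Se + Sp − 1 with ties broken toward higher specificity; the reported
cut-off is the **midpoint between the two adjacent observed scores** it
separates, so it is well-defined for unseen data. The radiomics model is
the identity score on SZE; clinical and combined models score patients
with a maximum-likelihood logistic combination (statsmodels Newton/IRLS at
tolerance 1e-8; perfect separation is flagged, a quasi-Newton fallback
supplies coefficients, and the cut-off still comes from the training ROC).
Predictors enter the logistic combination continuously by default; a
binarized coding is available. Confidence intervals on Se/Sp/PPV/NPV are
exact Clopper–Pearson.

**Frozen-validation semantics**: cut-offs, directions and coefficients
learned on cohort 1 are applied unchanged to cohort 2. `run_validate`
performs no estimation, and the CLI checksums model files before and after
validation.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test and Cox partial
likelihood are delegated to lifelines; this package adds Greenwood
variances, the median convention (first time with S(t) ≤ 0.5), and an
O/E-based hazard ratio (O_B/E_B)/(O_A/E_A) from the log-rank table
reported alongside the Cox estimate, since threshold-model stratification
is sometimes summarized either way. Ties are handled by Breslow's
approximation (lifelines' method); an Efron variant is not provided
because no installed implementation exposes the standard errors needed for
Wald intervals. All p-values are two-sided; no multiplicity correction is
applied across the three models, matching the analysis design, and raw
p-values are reported. A group with zero events yields an `infinite_hr`
flag rather than a number.

## Inter-reader variability

Boundary voxels are foreground voxels with a 6-connected background
neighbour (stated explicitly because "average Hausdorff" definitions
vary); the AHD is the mean of the two directed mean nearest-boundary
distances in mm. Feature agreement uses two-way random-effects
absolute-agreement ICC — ICC(2,1) for single measures, ICC(2,k) for
average measures (pingouin, cross-checked against from-scratch ANOVA mean
squares). Classification stability counts patients whose frozen-model
prediction differs between any pair of readers.

## Synthetic data: what it emulates, and what it does not

`generate_phantom` tiles an ellipsoidal ROI into contiguous zones by
multi-source breadth-first growth from round(N_v/θ) random seeds, so zone
sizes concentrate around θ without singleton fragments between large
zones; θ = 1 gives exact singletons and θ = N_v a single zone, the two
closed-form SZE cases. Zone grey levels are assigned by greedy graph
colouring that avoids equal levels on 26-adjacent zones whenever the
palette allows (with ≥ 27 levels the guarantee is exact), keeping grown
regions identical to the zones the GLSZM sees; optional Gaussian noise
then perturbs intensities.

`generate_cohort` draws per-patient θ (log-normal, median 1.35, log-sd
0.25 in feature mode), maps it to SZE = 1/θ² with multiplicative jitter,
injects per-scanner additive/multiplicative batch effects at the feature
level, and draws recurrence times from an exponential hazard
λ₀·exp(β·z + β_c·c) with uniform censoring on [24, 84] months (24-month
minimum follow-up). Image mode generates an actual phantom per patient
and runs the real extractor; its θ scale (median 2.0, log-sd 0.4) is set
so the extracted SZE distribution is centred near the clinical cut-off
scale (~0.53), because the phantom's θ→SZE map differs from the 1/θ²
feature link.

Two hazard links are provided. The default, `threshold`, sets
z = 1[SZE ≤ 0.53] with β = log 5.5 — a step-risk cohort with a
well-defined generative cut-off that the pipeline's Youden threshold
should approximate. The `linear` link uses the within-cohort standardized
feature (β is then a log-HR per SD). c is the centred risk-factor count
with β_c = log 1.3, giving clinical covariates a deliberately weaker
association than the imaging feature, as observed in this population.
Remaining cohort parameters (n = 107/88, scanner mixes 70/30 and
55.7/44.3, λ₀ = 0.002/month, age ~ N(65.5, 7), preop PSA ~ LN(log 8.5,
0.5), 65% R1, stage/Gleason frequencies) were chosen once to mirror the
published cohort structure.

What the generator does **not** emulate: prostate anatomy, MRI physics,
T2 contrast, spatially correlated noise, reader-specific segmentation
bias, or informative censoring. Passing tests therefore demonstrate the
pipeline's statistical machinery — not that the feature would perform
identically on real MRIs; its image-level batch mode applies only an
additive intensity offset, which FBN discretization absorbs by design.

## Problem sizes and numerical conventions

Simulation-based tests use the smallest sizes at which the checked
property is stable: 6³ arrays for zone-oracle equivalence (100 instances),
200/batch for ComBat recovery, 500/group × 50 replicates for Cox coverage
at HR 5.5, 400 runs for null log-rank calibration, and a 200-patient
image-mode cohort (16³ phantoms) for the end-to-end study. Logistic and
Cox fits use tolerance ≤ 1e-8; Youden ties break toward specificity;
degenerate inputs (empty masks/series, one-class labels, constant
matrices, unseen batches) raise typed errors rather than returning
sentinel values.

## Known limitations

- Single-level wavelet decomposition only; no LoG or multi-level filters.
- GLSZM family only (SZE, LZE, zone percentage); no GLCM/GLRLM/NGTDM or
  shape features.
- Parametric ComBat only; no longitudinal or image-level (voxelwise)
  harmonization.
- Breslow ties only in Cox fits; no competing risks or time-varying
  covariates.
- The cohort generator's feature→hazard link is a design idealization;
  real effect sizes and censoring patterns will differ.
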
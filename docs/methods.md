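# Methods

This note records the models, conventions and deliberate design choices
behind `pathomics`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, what the synthetic generators do and do not
emulate, and where the design was genuinely open.

## Synthetic data: what it emulates

The generators stand in for scanned H&E slides and their downstream
artifacts; they are first-class, tested code, not fixtures.

- **Nuclei scenes** (`NucleiSceneSpec`, `generate_patch`): nuclei are
  anti-aliased dark disks (radius ~ N(μ, σ), clipped at 2 px) on a
  pink-ish tissue background, rendered in 3 channels by default to
  exercise the grayscale-conversion path (`grayscale=True` gives the
  flat-gray variant used by oracle tests). `cluster_factor` interpolates
  between uniform placement and a two-level process (≈ n/8 cluster
  centers, Gaussian scatter with sd = 4·mean radius) — a simple,
  controllable source of the spatial heterogeneity density maps are
  meant to capture. With `overlap_allowed=False`, placement is
  rejection-sampled so disks are pairwise disjoint and fully inside the
  raster; the returned mask is exactly the union of the disks, which
  makes count and area recovery assertable without tolerance fudging.
- **Slides** (`generate_wsi`): the tissue region is the super-level set
  of a Gaussian-blurred noise field (σ = side/8) cut at the requested
  quantile, so the true mask fraction is exact up to rasterization ties
  and the shape is organically blobby. The palette keeps tissue
  luminance (~0.52) well below the glass background (~0.96) with nuclei
  darker still (~0.28); this mirrors real H&E contrast and is what lets
  a single global Otsu threshold separate tissue from background even
  though the image is trimodal. Nuclei are placed only on tissue.
- **Feature cohorts** (`generate_cohort`): standard-normal features;
  the planted subset is shifted by `effect_size` SDs in the positive
  class (so effect size ≡ standardized mean difference); labels are
  fixed counts `round(n·balance)` rather than Bernoulli draws so tests
  are deterministic. An optional equicorrelated block (up to 10
  non-informative columns) uses Pearson r = 2·sin(π·ρ/6) so the
  *Spearman* correlation matches the requested ρ in expectation.
- **Expression** (`generate_expression`): Gaussian log-expression,
  genes in planted up/down sets shifted by ±`effect_size` SDs in the
  high group. This suffices for the t-statistic/GSEA contract; it does
  **not** emulate RNA-seq count overdispersion, library-size effects,
  gene–gene correlation, or realistic set overlap — so passing tests
  demonstrate correctness of the enrichment machinery, not power on
  real transcriptomes.

More generally the image generators omit staining chemistry, scanner
optics, compression artifacts, pen marks and tissue folds; recovery
results on them certify the pipeline's logic, not its robustness to
real-slide artifacts.

## Tissue masking and patching

Pipeline order: grayscale → Otsu (tissue = darker side) → binary
dilation (3 × 3 square, 1 iteration) → fill holes ≤ 64 px → remove
objects ≤ 64 px. The morphology parameters are conventional defaults
(all configurable); a constant image leaves Otsu undefined and returns
an empty mask with a warning rather than failing. The slide gate and
the patch coverage gate are both inclusive (≥ 0.80, ≥ 0.15). The patch
grid is non-overlapping (stride = patch size), coordinates are 0-based
x-rightward/y-downward with half-open extents, and border patches are
kept when ≥ 50 % of their pixels are tissue. Patch scoring reuses the
package's own watershed segmentation, so patch selection and density
estimation agree on what counts as a nucleus.

## Nuclei segmentation and density maps

Marker-controlled watershed: Otsu foreground → 3 × 3 opening and hole
filling → Euclidean distance transform → sure-foreground where
dist > α · max(dist), α = 0.4 — taken **per connected foreground
component**, not globally, so small nuclei adjacent to large ones keep
their markers — → connected-component markers → watershed on the
negated distance restricted to the foreground. α trades
over-segmentation (low α splits single nuclei) against merged pairs
(high α); 0.4 resolves touching equal-sized disks whose neck is thinner
than 0.4 r.

Density maps read "50 μm² tiles" as 50 μm *side length* (100 × 100 px at
the default 0.5 μm/px, a typical 20X sampling); a literal 50 μm² area
(≈ 7 × 7 μm) is available via `tile_is_area=True`. Nuclei are assigned
to tiles by centroid so tile counts partition the segmentation count
exactly. Counts are rescaled linearly onto 0..255 **per patch**; a
per-tile constant would make the map uniform and textureless, and
per-patch scaling makes the texture features describe *relative*
spatial heterogeneity of cell density rather than absolute counts.
Nucleus size/shape bins (area cutpoints 80/300 px², eccentricity 0.75)
are descriptive output only and feed nothing downstream.

## Texture features

Density-map rasters are re-quantized from 8 bits to 32 levels (GLCMs at
256 levels on 20 × 20 rasters would be hopelessly sparse), distance 1,
symmetric accumulation, four orientations with explicit offsets
(horizontal (0,1), vertical (1,0), minor diagonal (1,1), major diagonal
(1,−1)). The 13 Haralick statistics use log base 2, 0·log 0 := 0, and
define the degenerate cases to keep every value finite: correlation = 0
when a marginal sd is 0, first information measure = 0 when both
marginal entropies vanish. Sum variance is taken about the *sum
average* (the original formula's reference to sum entropy is widely
regarded as a typo); difference variance is the variance of the |i−j|
marginal. Slide aggregation uses sample variance (n−1), Fisher excess
kurtosis and adjusted Fisher–Pearson skewness, all 0 for degenerate
samples (a single patch, or zero spread); an empty patch list is an
error because the slide is unusable.

## Feature selection

The Spearman filter is a greedy left-to-right scan dropping any column
with |ρ| strictly above 0.9 against an already-retained column; the
retained set provably contains no offending pair, and constant columns
(ρ undefined) are treated as 0 and kept. Mutual information uses
equal-frequency binning with ⌈√n⌉ bins (duplicate quantile edges
collapse, so binary features keep two levels and MI(feature = label) =
H(label) exactly). Relief scores z-score features internally for the
Manhattan distances and use range-normalized differences, making all
variants invariant to affine rescaling of any feature; iteration runs
over all samples in order (deterministic), with seeded subsampling
available. Within each target, hit and miss contributions are averaged
per group before the 1/m normalization, which keeps variants on a
common scale regardless of neighborhood sizes.

**A caution on SURF\*:** its defining inversion of far-neighbor updates
(far hits add, far misses subtract) systematically *penalizes* additive
main-effect features: informative features make cross-class pairs
farther, so the far-miss penalty meets or exceeds the near-miss reward
and such features end near the bottom of the ranking. This is inherent
to the published update rule — it is the reason later work dropped the
far term — and the package documents rather than "fixes" it. The
recovery acceptance check encodes the ideal expectation for all six
scorers and is accordingly expected to fail for SURF\* on planted
main-effect cohorts; use SURF\* for interaction-driven signals, not
additive ones.

## Benchmark harness

Z-normalization uses the sample (n−1) sd; zero-variance training
columns are centered only. SVMSMOTE fits an RBF-kernel SVC, takes the
minority-class support vectors as seeds (falling back to all minority
samples if none), and synthesizes each new sample as x + λ(x_nn − x),
λ ~ U(0,1), toward one of the seed's 5 nearest minority neighbors; a
singleton minority class degrades to duplication with a warning.

Cross-validation is stratified 5-fold (shuffled, seeded). Per fold, the
order is: fit z-transform → score features on the (un-oversampled)
training part → take the top n columns → oversample the selected
training block → fit the classifier → score the held-out part with
continuous decision scores (decision_function, else predict_proba).
When n is "sweep", the candidate grid {2, 5, 10, 15, 20, 30, p} is
evaluated on the same folds and the n maximizing mean out-of-fold AUC
is reported (smallest on ties) — note this is the classical optimistic
select-then-report scheme; the external cohort, scored once by the
pipeline refit on the full training cohort, is the honest estimate.
Classifiers run with library-default hyperparameters, seeded.
The full model × selector grid shares one fold split; failed cells are
recorded as missing rather than aborting; per-model summaries are the
median ± sample sd of external AUC across selectors. A PFS of exactly
12 months, unassigned by strict > / < dichotomization, belongs to the
non-responder (≤ 12) group by this package's convention.

## Pathomic score and enrichment

The pathomic score is the per-sample median of the selected (z-scored)
features; "high" requires *strictly* exceeding the cohort median, so an
all-identical cohort is entirely "low". Gene ranking uses Welch t
statistics (high − low); all genes are ranked — no prior DEG filter —
since the enrichment statistic itself weighs per-gene evidence. The ES
is the Subramanian-style weighted KS statistic (weight exponent 1;
exponent 0 gives the classic unweighted form, which is exactly
antisymmetric under ranking reversal — the weighted form is only
approximately so). Null distribution: sample-label permutations (the
statistic is group-derived, so phenotype permutation is the honest
null), vectorized in blocks; p-values use the add-one estimator, so
p ≥ 1/(N+1) and p = 0 is impossible. FDR control is Benjamini–Hochberg
across all tested sets; calls are up/down only when ES sign and
q < 0.1 agree, else ns. The ES is treated purely as the
direction-of-effect statistic, not as a fold change.

## Problem sizes used by tests and the acceptance script

Chosen as the smallest sizes at which each property is comfortably
demonstrated: 256–384 px synthetic slides and 20-nucleus scenes for
mask/count recovery; cohorts of 200 × 100 (10 informative, effect 2)
for selector recovery; 100-sample null grids over all 7 × 6 cells with
10 features per cell; 60-gene, 40-sample expression with 10-gene sets
and 500-permutation nulls (50 seeds for the uniformity check). The
default 10 000-permutation setting remains the recommendation for real
analyses.

## Known limitations

- Flat rasters only; no pyramid/multiresolution WSI containers
  (SVS/NDPI) and no stain normalization.
- Haralick's 14th feature (maximal correlation coefficient) is
  deliberately omitted; the feature set is the classical 13.
- No wrapper/embedded selection (RFE, LASSO), no hyperparameter search
  beyond the feature-count sweep, no survival modeling (endpoints are
  dichotomized), no leading-edge analysis in enrichment.
- Synthetic validation certifies correctness and calibration of the
  machinery, not clinical performance; headline AUCs on real cohorts
  are outside what desk-scale synthetic data can reproduce.
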
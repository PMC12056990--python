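# pathomics

A whole-slide-image (WSI) pathomics pipeline for binary clinical
endpoints in H&E histopathology, built around handcrafted cell-density
texture features. It covers the full path from raw slide raster to
biological read-out:

1. **Tissue masking & gating** — grayscale → Otsu threshold → binary
   dilation → hole filling → small-object removal; slides must carry at
   least 80 % tissue.
2. **Nuclei-aware patching** — non-overlapping 2000 × 2000 px patches
   (20X), kept only when ≥ 15 % of their pixels are segmented as nuclei.
3. **Cell-density maps** — marker-controlled watershed segmentation
   (Otsu foreground, distance transform, per-component relative
   threshold for markers), then a 50 μm tile grid whose gray level
   encodes the per-tile nuclei count.
4. **Texture features** — four symmetric gray-level co-occurrence
   matrices (GLCMs; horizontal, vertical, minor- and major-diagonal
   adjacency) per density map, 13 Haralick statistics each → 52
   features per patch; slide vectors summarize each feature over
   patches with mean, median, variance, kurtosis and skewness → 260
   features per slide.
5. **Selector × classifier benchmark** — Spearman |ρ| > 0.9 redundancy
   filter; six relevance scorers (ANOVA F, mutual information, ReliefF,
   SURF, SURF\*, MultiSURF); SVMSMOTE minority oversampling; seven
   classifiers (AdaBoost, decision tree, random forest, LDA, SVM, KNN,
   XGBoost). Everything data-dependent is fitted per stratified CV fold
   (leak-free); an external cohort is scored once by the refit
   pipeline; grids report AUC per cell and per-model medians.
6. **Pathomic score & enrichment** — per-sample median of the selected
   z-scored features, median split into high/low groups, per-gene Welch
   t statistics, weighted-KS gene-set enrichment scores with a
   sample-permutation null (10 000 permutations by default), and
   Benjamini–Hochberg FDR < 0.1 up/down calls.

Because real WSI cohorts of this kind are rarely shareable, the package
ships first-class synthetic generators (`pathomics.synthetic`) that
emulate every input — stained tissue on bright background, nuclei as
partially overlapping dark disks, slide-level feature cohorts with a
planted discriminative subset, and expression matrices with planted
up/down gene sets — each returning its ground truth so every stage is
testable without any download.

## The core statistics

For a quantized density map with gray levels $i,j \in \{0..L-1\}$ the
GLCM at offset $(\Delta r, \Delta c)$ is the symmetric, normalized pair
count $P(i,j)$. The 13 Haralick statistics are the classical set:
angular second moment $\sum_{ij} P^2$, contrast
$\sum_k k^2\,p_{x-y}(k)$, correlation
$(\sum_{ij} ij\,P - \mu_x\mu_y)/\sigma_x\sigma_y$, sum of squares,
inverse difference moment, sum average/variance/entropy, entropy,
difference variance/entropy, and the two information measures of
correlation (entropies in bits, $0\log 0 := 0$).

Relief-family scores update
$W_f \mathrel{+}= \operatorname{diff}(f, x, \text{miss})/m -
\operatorname{diff}(f, x, \text{hit})/m$ with the range-normalized
difference; variants differ in the neighbor rule (k-nearest for
ReliefF; a global mean-distance threshold for SURF; the same plus
inverted far updates for SURF\*; a per-instance threshold
$\bar d_i - s_i/2$ for MultiSURF).

The enrichment score of a gene set is the signed maximum of the
weighted Kolmogorov–Smirnov running sum over the t-ranked gene list
(hit increments $\propto |t|$, uniform miss decrements),
ES ∈ [−1, 1]; nominal p-values use the add-one permutation estimator
$(1 + \#\{|ES_\pi| \ge |ES|\})/(1 + N_\pi)$.

## Worked example

```python
import numpy as np
from pathomics import synthetic, preprocess, nuclei, texture

spec = synthetic.NucleiSceneSpec(width_px=512, height_px=512, n_nuclei=400, seed=7)
wsi, true_mask = synthetic.generate_wsi(0.9, spec)

mask = preprocess.tissue_mask(wsi)
print(f"tissue fraction: {mask.tissue_fraction:.3f} (true {true_mask.mean():.3f})")
print(f"passes 80% gate: {preprocess.passes_tissue_gate(mask)}")

patches = preprocess.extract_patches(wsi, mask, patch_px=256)
vectors = []
for rec in patches:
    score, ok = preprocess.nuclei_coverage_score(rec)
    if ok:
        seg = nuclei.segment_nuclei(rec.image)
        dmap = nuclei.density_map(rec.image, seg, tile_um=16.0)
        vectors.append(texture.patch_features(dmap.gray))
print(f"patches: {len(patches)} extracted, {len(vectors)} accepted (>=15% nuclei)")

slide = texture.slide_aggregate(vectors, slide_id="demo")
print(f"slide vector length: {slide.size}")
print(slide[["contrast_horizontal_mean", "entropy_horizontal_mean",
             "asm_vertical_variance"]].round(3).to_string())
```

prints

```
tissue fraction: 0.906 (true 0.900)
passes 80% gate: True
patches: 4 extracted, 4 accepted (>=15% nuclei)
slide vector length: 260
contrast_horizontal_mean    84.821
entropy_horizontal_mean      1.623
asm_vertical_variance        0.182
```

The recovered tissue fraction tracks the generator's ground truth to
well under one percentage point; every accepted patch contributes 52
texture values and the slide vector has exactly 260 entries. High
`contrast_*_mean` reflects strongly heterogeneous per-tile nuclei
counts in the density maps; `asm_*_variance` measures how much texture
uniformity varies between patches of the slide.

A command-line interface mirrors the library
(`pathomics simulate | preprocess | density | features | select | bench | enrich`);
run `pathomics --help` for the subcommands and options.

## Orientation convention

"Minor/major diagonal" adjacency is ambiguous in the field, so the
package fixes pixel offsets explicitly: horizontal (0, +1), vertical
(+1, 0), minor diagonal (+1, +1), major diagonal (+1, −1) — symmetric
accumulation makes the opposite directions equivalent.

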
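# Methods

This note records the models, conventions and numerical choices behind the
package, including every place where a published description was
under-specified and a concrete decision had to be made.

## Preprocessing

Frames are mapped to a common internal intensity scale — float64 in
[0, 255] — regardless of source bit depth (8-bit verbatim, 16-bit scaled by
255/65535), so a single quantization path serves all inputs. Before feature
computation every frame passes a separable Gaussian low-pass filter
(default σ = 1.0 px, kernel truncated at 4σ, reflect boundary); the filter
width is configurable because no canonical value exists for B-mode speckle
suppression. Filtering is applied to the whole frame, before and
independently of the mask.

Gray-level quantization for run-length analysis uses N_g = 32 equal-width
bins over the [min, max] of in-ROI intensities; the maximum maps to level
N_g and a constant region maps to level 1. N_g is stored in the provenance
of every feature vector: texture values are only comparable at equal N_g.
Quantization is monotone in source intensity, which makes all quantized
texture features invariant to additive intensity shifts (bin edges follow
min/max).

ROI masks must contain at least 16 foreground pixels and form exactly one
8-connected component; anything else is rejected as a bad segmentation.
Contours are rasterized by testing pixel centers against the polygon
(even-odd rule, centers on an edge count as inside).

## The feature bank

**Morphology (9).** The tumor is imaged as a 2-D section, so the 3-D-named
features use documented planar proxies: volume = area·spacing², surface
area = perimeter·spacing, maximum 3-D diameter = maximum pairwise distance
between boundary pixel centers (Feret diameter, computed on the convex hull
of the boundary), spherical disproportion = perimeter/(2π·r_eq) with
r_eq = √(area/π), spherical ratio its reciprocal, compactness =
4π·area/perimeter², convexity = area/convex-hull area, and max radius /
radius STD from centroid-to-boundary distances. The perimeter uses the
4-direction Crofton estimator, which is asymptotically unbiased on smooth
rasterized shapes (the chain-code estimator overestimates disks by ≈4 %,
which would bias compactness and the sphericity pair).

**Density (21).** First-order statistics of in-ROI intensities. Five of the
conventional names have no standard formula; the definitions used here are:
ISO-intensity = fraction of ROI pixels within ±10 % of the ROI mean;
fluctuation mean/STD = mean/STD of |v − local 3×3 mean|; mean contrast =
(mean_ROI − mean_band)/(mean_ROI + mean_band) against a 5-pixel outer
morphological band; contrast = (max − min)/(max + min) over the ROI; STD
ratio = ROI STD / band STD. If the band is empty (ROI touches every border)
the band mean/STD are taken as 0 and the ratio as 0. Gradients are Sobel
magnitudes. Entropy (bits) and uniformity use an N_g-bin histogram over the
in-ROI range. Zero-variance conventions: skewness = kurtosis = 0 (kurtosis
is excess), entropy = 0, uniformity = 1. All 21 are validated against an
independently coded formula evaluation on an enumerated patch.

**Run-length texture (44).** The GLRLM p(i, j) counts maximal runs of equal
quantized level along each of four directions — 0° rows, 90° columns, 45°
up-right diagonals, 135° up-left diagonals; out-of-ROI pixels break runs.
Two exact integer identities hold by construction and are enforced in
tests: Σp = n_runs and Σ j·p = n_pixels. The 11 statistics follow the
classical Galloway/Chu definitions and are checked for exact agreement
against a brute-force pixel-walking enumerator on 200 random quantized
ROIs, and for the exact direction swap under 90° rotation. The
implementation shears the level image so each direction becomes one
contiguous 1-D pass (a ~20× speedup over per-scanline extraction with
identical output).

**Wavelet (210).** One-level 2-D DWT, Haar (db1), periodization mode —
chosen because Haar/periodization is orthonormal, giving an exact Parseval
check (subband energies sum to input energy within 1e-8 relative) for
even-dimension images; odd dimensions are periodically extended (ceil(n/2)
subband shapes) and do not conserve energy exactly. A subband pixel is
in-ROI iff ≥1 of its 2×2 source pixels is; each subband is rescaled to
[0, 255] (its coefficient scale is arbitrary) before the 21 density + 44
texture features are recomputed. The full recomputation yields 260 values;
the published layout counts only 210 wavelet features against a 284 total,
an arithmetic inconsistency (21 + 44 = 65 × 4 = 260 ≠ 210) the package
resolves by profile: `paper_284` keeps the first 210 in canonical order
(LL, LH, HL complete plus the first 15 HH density features), `full_334`
keeps everything. Which 210 the original selection used is unknowable; the
truncation preserves the published vector length while the full profile
loses nothing.

## Pools, outcome, selection

TSIR = (x2 − x1)/x2 × 100 with the *endpoint* size in the denominator, kept
exactly as published even though RECIST-style conventions normalize by
baseline. Difference pools are raw post − pre subtractions, normalized
afterwards (per pool, per feature, across subjects); Pearson r is invariant
to that scaling, so the normalization order can only affect the fused
marker's value range, not any reported correlation. Constant columns
normalize to all zeros with a logged warning. Subjects missing any of the
four scans are excluded with a logged reason.

Ranking is by signed r descending by default (the published tables list
positive correlations), with an |r| mode available since difference
features may legitimately anticorrelate; ties break by canonical feature
order. Note the two modes interact with fusion: under |r| ranking the
least-correlated pair can mix signs, and an equal-weight average of
opposite-signed predictors cancels. The fusion pair minimizes |pairwise r|
over all C(k,2) candidates (brute force, k = 5 by default). P-values
comparing dependent correlations use the Hotelling–Williams t-test with
n − 3 df — the published tables report such comparisons without naming a
method, and Hotelling–Williams is the standard test for two correlations
sharing one variable. Correlation strength labels use the conventional
bands (|r| ≥ 0.70 very strong, 0.40–0.69 strong, 0.30–0.39 moderate,
0.20–0.29 weak, 0.01–0.19 negligible), magnitudes rounded to two decimals
first so gap values like 0.395 land in a band; edges are inclusive at the
lower magnitude.

## Frame reproducibility

A per-feature correlation across the frames of a *single* scan is
statistically ambiguous (one scalar per frame has no second axis), so both
defensible readings are implemented. `vector` mode (default): for each
frame, Pearson r between the base frame's full feature vector and that
frame's vector; summarized as mean, SD and a 95 % normal-approximation CI
(mean ± 1.96·SD/√m over m comparisons), plus a leave-one-feature-out
contribution per feature. Pearson r is affine-invariant per vector, so no
normalization is needed. `cohort` mode: for each feature, r across subjects
between base-frame and frame-k values, averaged over k — a true per-feature
coefficient, but it needs several subjects. Zero frame noise gives mean
r = 1 and SD = 0 exactly; the summary is invariant to frame order. The same
mask is reused across frames (the tumor is segmented once per scan).

## Synthetic cohort generator

The generator emulates the *structure* of a longitudinal mouse study — it
makes no claim of acoustic fidelity (no point-spread function, no RF data,
no 3-D volumes).

* **Speckle**: multiplicative Rayleigh field on a two-level echogenicity
  map (background 100, tumor 140 on the 8-bit scale), clipped to [0, 255].
  The default Rayleigh scale √(2/π) gives a unit-mean field, so echogenicity
  levels are preserved on average; scale → 0 collapses to a constant image.
  This reproduces first-order B-mode statistics only — real speckle is
  spatially correlated by the system PSF, whereas this field is i.i.d.
* **Tumor shape**: ellipse (aspect 0.7–1.0, random rotation) with low-order
  Fourier boundary perturbation (modes 2–4, amplitudes ≤ 0.06), giving
  nontrivial morphology while staying star-shaped and single-component.
  Day-6 tumors are 15 % larger than day-3.
* **Frames**: one speckle realization per day; frames within a scan differ
  only by i.i.d. additive Gaussian noise (default SD 2.0, ≈0.8 % of dynamic
  range) and an integer jitter of ≤1 px, mirroring near-redundant cine
  frames. Zero-noise conditions (noise 0, jitter 0) produce identical
  frames.
* **Planted effect**: each group carries a response in [0, 1], monotone
  across groups (default linspace 0.9 → 0.1 over 7 groups, per-subject
  noise SD 0.05). The post-treatment scan blends the intra-tumoral speckle
  toward its σ = 1.5 Gaussian-smoothed version with weight
  clip(gain × response, 0, 1): runs of equal level lengthen, so LRE rises
  and SRE/RP/RLN fall, and local-fluctuation density features drop.
  Amplitude-only contrast changes would be invisible after min-max
  quantization, which is why the effect is planted as smoothing.
* **Outcome link**: x1 ≈ 50 (unitless; sizes at the endpoint are supplied
  directly, no caliper formula) with lognormal jitter (σ = 0.05);
  x2 = x1·exp(1.5·(1 − response) + ε), ε ~ N(0, 0.15). TSIR therefore rises
  as response falls and stays in (−∞, 100); across 50 subjects the planted
  response correlates with normalized TSIR at r ≤ −0.5.
* **Cohort layout**: subjects split over groups as evenly as possible
  (23/7 → sizes 4,4,3,3,3,3,3); everything is a pure function of the seed.

Passing tests on these cohorts demonstrate that the pipeline recovers
planted monotone texture–outcome links under realistic first-order speckle
statistics and near-redundant frames; they do not certify performance on
real tissue, where speckle correlation, attenuation, shadowing and
operator-dependent segmentation all intervene.

## Problem sizes and degenerate inputs

The test suite and acceptance script use scaled-down cohorts chosen as the
smallest sizes at which each property is informative: 64×64 frames, tumor
radius ≈14 px, 1–10 frames per scan, with the full 23-subject / 7-group
design and the replicate counts fixed by the experimental design (20 for
recovery, 50 for fusion gain). Degenerate inputs are rejected rather than
coerced: empty/fragmented/tiny masks, constant vectors in correlation,
n < 3 for Pearson, n < 4 for Hotelling–Williams, x2 ≤ 0 in TSIR, images
< 8×8 for the DWT, < 2 frames for reproducibility.

## Known limitations

* The speckle model is first-order only (no spatial correlation), so
  absolute texture values are not comparable to scanner data.
* 2-D morphology proxies under the names of 3-D quantities; spacing
  defaults to 1 px unless calibration is supplied.
* The `paper_284` wavelet truncation is a convention, not a recovery of the
  original 210-feature selection.
* Real-data correlation magnitudes from any specific animal study are not
  reproducible from synthetic cohorts; the pipeline reports whatever its
  inputs support.
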
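# Methods notes

## Detection model

A carbon particle's broadband emission saturates the detector in both
spectral bands, while the label-free tissue signals are band-specific:
collagen SHG in the narrow 405/10 nm channel, tissue autofluorescence
in the broad 550/200 nm channel. The caller thresholds each channel at
a fraction of its *own per-tile maximum* — 99.5 % (narrow) and 55 %
(broad) — and intersects the two masks. The tile is the acquisition
unit, so maxima are per tile, not per study. Comparisons are `>=`, so
all pixels tied at the maximum (saturated pixels) pass by construction.

Design choices where the method description is silent:

- **Connectivity.** "Connected pixels" is implemented as 8-connected
  components (configurable to 4). Saturated footprints are a few
  pixels across; 8-connectivity avoids splitting a blob whose corner
  pixels touch diagonally.
- **One particle = one component.** No sub-peak splitting: the method
  counts thresholded overlapping pixels, not resolved peaks. Two
  particles closer than a footprint merge into one call; at the
  simulated densities (≤ ~10⁴ /mm³, i.e. ≤ ~12 particles on a 512-px
  tile) the expected number of merges per tile is < 0.01.
- **Minimum component size** defaults to 1 px and no pre-smoothing is
  applied.

A z-stack check classifies calls as tissue-embedded vs surface
contamination: the axial profile (per-slice window maximum around the
call) must peak in an interior slice and span ≥ 2 slices to count as
embedded; a profile confined to a boundary slice is surface; anything
else is indeterminate.

## Volumetric loads

`load = N / (tissue area × 7 µm)`, with the tissue area from an
automated segmentation of the broad channel standing in for a manual
area annotation: Gaussian smoothing (σ = 4 px at full resolution),
bright-outlier capping at the 90th percentile (so saturating particles
cannot hijack the global threshold), Otsu threshold, morphological
closing, small-hole filling, small-object removal. If the below-
threshold class is not genuinely dark (mean > 0.35 × tissue class), the
tile is treated as fully covered by tissue. Segmentation runs on
block-mean-downsampled images (factor 2 by default, 4 in the
end-to-end pipeline); on simulated tiles the recovered area is within
~3 % of truth at either factor, and any residual area bias is common
to both exposure groups so it cancels in fold-change and deficit
ratios.

Region loads (≥ 5 regions per sample by design; fewer triggers an
under-sampled flag) are averaged per sample. The description "average
CPs normalised for tissue area" is ambiguous between mean-of-region-
loads and pooled-count/pooled-area; the default is mean of region
loads, with the pooled variant behind `pool_regions=True`. Zero-load
samples are retained as 0, and log-transforms replace zeros by half
the smallest positive load (count reported).

## Hierarchical inference

Fetus-level loads are pooled to litter (dam) means after an
exchangeability check: per group × organ, Kruskal–Wallis across the
dams' fetuses with Dunn's Bonferroni-adjusted pairwise z-tests on mean
ranks; pooling is refused for a family only when an adjusted pairwise
p < 0.05. The verdict is per family because a study-wide conjunction
of 12 families at nominal 5 % would refuse far too often under the
null.

All small-sample tests are exact by enumeration, with mid-rank tie
handling inside the enumeration itself:

- Mann–Whitney U: all C(n+m, n) group allocations (3432 at 7 vs 7);
  two-sided p = P(|U − nm/2| ≥ |u − nm/2|), valid because U is
  symmetric about nm/2 under exchangeability even with ties. Beyond
  10⁶ allocations, a tie-corrected normal approximation (flagged).
- Wilcoxon signed-rank: zero differences dropped; the exact
  distribution of W⁺ is built by dynamic programming over the doubled
  (integer) mid-ranks, equivalent to enumerating all 2ⁿ sign patterns,
  for n ≤ 20.
- Spearman: ρ is the Pearson correlation of mid-ranks; exact
  permutation p over all n! orderings for n ≤ 8 (5040 at n = 7), else
  the t approximation.

Fold changes are ratios of group **means** of litter means (medians
behind `stat="median"`); organ deficits are 1 − organ/placenta over
exposed litter means with the paired Wilcoxon p. Both are functions of
litter means only, hence invariant to relabelling fetuses within a dam.

Mixed models (`statsmodels MixedLM`): response ~ log10(load) +
treatment + sex with a random dam intercept, plus a random slope on
log10(load) for the placenta (the compartment with the strongest load
gradient). Fits use maximum likelihood (not REML) so fixed effects are
comparable across models; a singular random-slope fit falls back to
intercept-only with a flag, and non-convergence raises rather than
silently approximating. The load slope is reported per 10-fold
increase in load. The quartile convention everywhere is linear
interpolation (type 7), which the median (Q1; Q3) displays depend on.

## Multiple factor analysis

Columns are centred and scaled by the population (1/n) standard
deviation; each variable group g is weighted by 1/√λ₁(g), the first
eigenvalue of the group's own standardized PCA, so no group can
dominate dimension 1 (its post-weighting first eigenvalue is ≤ 1); the
global fit is an SVD with uniform row weights 1/n. Consequences used
as test oracles: a single-group MFA equals standardized PCA up to the
uniform 1/√λ₁ rescaling, and duplicating a group's variables leaves
individual coordinates unchanged. Dimension signs are fixed by forcing
the variable with the largest |correlation| positive.

Qualitative factors (exposure, exposure × sex) are supplementary only:
level barycentres with
`v.test = barycentre × sqrt(n_k(n−1)/(n−n_k)) / sqrt(λ_d)` — the
z-score of a random barycentre drawn without replacement, verified
against a permutation null — cos² as the dimension's share of the
barycentre's squared norm, one-way ANOVA R² (+ F-test) per dimension,
and 95 % confidence ellipses of the barycentre (level covariance / n_k,
χ²₂ quantile radius). The default variable groups are CP loads
(log10), organ weights and weight ratios; gonads carry no weight
variable (too small to weigh), and rows missing any active variable
are dropped listwise.

## Synthetic data

The generator reproduces the study design: 2 exposure groups × 7 dams
× 4–5 fetuses × 6 organs, ≥ 5 imaged regions per sample, 0.83 µm
pixels, 7 µm sections, 512-px tiles by default (native 4096 remains
configurable; loads are volumetric, so tile size is immaterial).

**Densities** follow a lognormal hierarchy: organ group mean × shared
dam factor × fetus factor, each factor mean-corrected
(exp(σz − σ²/2)) so configured means are reproduced in expectation.
The shared dam factor induces the positive between-organ correlation
of litter means that motivates litter-level analysis. The organ means
are anchored by one scale parameter (control placental density,
default 2400 /mm³ ≈ 3 particles per 512-px region) plus the exposed
fold changes (4.1 / 3.3 / 2.6 / 1.9 / 1.8 / 1.3) and organ-vs-placenta
deficits (0.15 / 0.25 / 0.55 / 0.61 / 0.72); control organ means are
*derived* as exposed/fold, keeping the profile internally consistent.
The gonad fold of 1.3 is deliberately small: it is the one compartment
whose group difference should stay non-significant at n = 7.

Variance defaults `dam_sd_log = 0.32`, `fetus_sd_log = 0.25` (natural
log) were fixed by a power argument: at 7 vs 7 litters, the exact
Mann–Whitney should detect a 1.8-fold shift most of the time while
missing a 1.3-fold shift most of the time, which brackets the
between-litter log-sd near 0.35. These two operating rates pull in
opposite directions and cannot both exceed 80 % under this hierarchy
(the power curve of a 7v7 rank test is too shallow for effect sizes
separated by a factor log(1.8)/log(1.3) ≈ 2.2); the chosen point sits
on the attainable frontier favouring gonad non-significance.

**Rendering.** The broad channel gets smooth multiplicative texture
(±12 %) plus sparse bright granules inside a tissue region of known
fraction; the narrow channel gets curvilinear collagen fibres
(amplitude well below saturation). Particles are PSF-blurred spots
(σ = 1.2 px) at 3× the saturation level added to *both* channels, so
their cores clip at saturation. Expected particle count per region =
density × tissue area × 7 µm, with particles placed uniformly inside
the tissue mask (placing them on the whole tile would bias recovered
loads by 1/tissue-fraction). Shot noise is a variance-matched Gaussian
(σ = √signal, combined with read noise σ = 3), exact per-pixel Poisson
behind `shot_noise="poisson"`; at the simulated photon counts
(≥ ~50 per pixel in tissue) the two are indistinguishable to the
detector, and the Gaussian form keeps 42 000-tile acceptance runs
inside desk-scale runtimes. Z-stacks place embedded particles as axial
Gaussians peaking at their true depth and surface contaminants in a
boundary slice only.

What the renderer does **not** emulate: optics-accurate white-light
spectra or detector response, spatially varying illumination,
sectioning artefacts, anisotropic tissue morphology, or touching
particle aggregates. Passing recovery tests therefore demonstrates the
correctness of the calling/normalisation/inference chain under the
stated signal model, not robustness to every property of real tissue.

**Biometry** is drawn lognormally around the reference medians (fetal
36 g; placenta 7.4 g via the ratio model; heart 0.20 g, kidney 0.17 g,
liver 2.4 g, lung 0.98 g) with 10 % coefficient of variation. The
placenta/fetus weight ratio (×10) responds to log10 placental density
with slope 0.46 per decade (plus dam random intercept sd 0.15 and
residual sd 0.30), which is the structure the mixed models are asked
to recover; placental efficiency is its exact reciprocal (×10).

## Problem sizes and reproducibility

Default end-to-end runs use 512-px tiles (1 680 rendered regions per
study); recovery statistics average 25 independent studies, and the
mixed-model calibration uses 200 biometry-only replicates — sizes at
which Monte-Carlo error is well inside the assertion tolerances. Every
stage draws from `numpy` Generators seeded from the study seed (one
child stream per region), so a config + seed determines all outputs
bit-for-bit; results JSONs are byte-stable across repeated runs.

## Known limitations

- Thresholds are relative to the per-tile maximum; a tile containing
  no particle at all sets its narrow threshold from the brightest
  collagen structure, and rare collagen/granule coincidences can
  produce false calls there (measured precision at default densities
  is > 0.99).
- The exact Mann–Whitney at 7 vs 7 has a smallest attainable two-sided
  p of 2/3432; reported zeros of p are impossible by construction.
- Wald intervals from the ML mixed-model fit undercover at 14 dams:
  calibration runs measure ~88 % coverage for the nominal 95 % load-
  slope interval (87–88 % also under REML or intercept-only random
  structure). The load predictor is concentrated between dams, so the
  asymptotic SE underestimates the finite-sample estimator spread; a
  Kenward–Roger/Satterthwaite small-sample correction would be needed
  to restore nominal coverage and is not provided here.
- The MFA handles quantitative active variables only; qualitative
  variables enter as supplementary factors.
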
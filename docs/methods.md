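# Methods

## Scope and model

`coastmap` implements a pixel-based supervised mapping workflow for coastal
plant communities and its design-based validation. The chain is: (synthetic
or file-based) bi-seasonal 8-band scenes and a terrain model → per-pixel
feature stacks → seeded random-forest evaluation of the wet, dry and
bi-seasonal feature sets → prediction of the final map with cloud-mask
fallback → minimum-mapping-unit (MMU) filtering → stratified reference
sampling and error-adjusted area/accuracy estimation.

## Synthetic scene generator

The generator reproduces the *statistical* structure the classifier and the
estimators rely on, not radiometric realism. No radiative-transfer or canopy
modeling, no tides or hydrology, and no georeferencing beyond an affine grid.

**Terrain.** Elevation (cm above datum) = linear seaward-to-landward ramp
(default −15 → +38 cm over 200 rows of 2 m pixels) + a Gaussian embankment
ridge (default relief 8 cm, σ = 40 m, crest at row fraction 0.90, so the
crest sits near 45 cm absolute — the scale of the real coastal embankment the
scenario emulates) + spatially correlated Gaussian noise (sd 2.5 cm,
correlation length 12 m). The noise field is white noise smoothed with a
Gaussian kernel and rescaled to the requested sd, so the zero-noise case is
exactly deterministic.

**Communities.** Nine zonal classes occupy contiguous elevation bands
(water < mud flat < red mangrove < black mangrove < white mangrove <
halophyte prairie < buttonwood/halophyte < buttonwood/glycophyte < hardwood
hammock; default bands 6 cm wide with open ends). Bands are a partition;
pixels outside every band raise an error. Patch-process classes (the two
invasive shrubs by default) are stamped as random disks (Poisson count,
configurable density and radius, optionally restricted to host classes) over
the zonal map and may locally violate the zonation — as real invasives do.

**Spectra.** Per class × season × band mean reflectance plus independent
Gaussian within-class noise (sd 0.02), clipped to [0, 1]. The signature
table is a synthetic fixture: visible/NIR shapes plausible for vegetation,
water and bare soil, a dry-season stress transform (NIR ×0.85, visible
×1.10), and NIR-concentrated seasonal contrast for two confusable pairs —
the buttonwood forests differ only in wet-season NIR, the invasives only in
dry-season NIR. `seasonal_contrast_config()` sharpens this into the
comparison scenario by making the glycophyte buttonwood a patch class inside
the halophyte-buttonwood band, so the terrain feature carries no information
about either pair and each single season is blind to exactly one pair.

**Clouds.** Per season, random disks (radius jittered around 24 m, capped so
one blob stays below the target) are unioned until the configured scene
fraction is reached; defaults 0.006 (wet) and 0.009 (dry). Realized cover
overshoots by at most about one blob.

**Training points.** Field protocols collect points > 7 m inside community
boundaries within patches > 14 m across. Operationalization: a pixel is
eligible when its center-to-boundary distance (Euclidean distance transform
to the nearest foreign-pixel center minus half a pixel) strictly exceeds the
buffer, and its 8-connected patch has maximum inscribed-circle diameter
(2 × max EDT) above the minimum. Per-class counts are drawn uniformly
without replacement; infeasible requests fail loudly naming the class.
Distances are measured to in-grid foreign pixels only, so patches touching
the scene edge are treated as continuing beyond it.

All stages draw from independent streams derived from the single config seed
(`SeedSequence([seed, stage_tag])`), so any stage is reproducible in
isolation and the whole generation is bit-identical per seed.

*What passing tests do not show:* the generator has no mixed pixels, no
spatial autocorrelation of spectral noise, no georeferencing error between
seasons, and training data with exactly correct labels. Accuracies on
synthetic scenes are therefore upper bounds; the tests validate the
machinery and its contracts, not real-world attainable accuracy.

## Feature stacks

Per season: 8 reflectance bands, then 3×3 moving-window mean, range and
standard deviation per band, then NDVI — 33 features; the terrain model adds
one more. Single-season sets have 34 features, the bi-seasonal union 67
(one shared terrain feature). Choices where conventions differ:

- NDVI uses the first NIR band (770–895 nm) as the NIR term — the
  conventional choice for this sensor family.
- Window statistics use the truncated in-grid neighborhood at borders (no
  padding, which would invent reflectance); the standard deviation is the
  sample (n−1) statistic, 0 when fewer than two valid neighbors exist.
- Cloud-masked pixels become NaN in all features of that season only and
  propagate through the window statistics as missing neighbors; the terrain
  feature is never masked. Training points on NaN pixels are dropped with a
  logged count.
- Terrain resampling to the scene grid is nearest-neighbor (each target
  center takes the source cell containing it), so output values are a subset
  of input values.

## Classifier evaluation

Random forests (scikit-learn) with 1000 trees by default. The
features-per-split parameter (mtry) is tuned by stratified k-fold
cross-validation (default 10 folds) over all integers 2..p when p ≤ 40, else
20 log-spaced integers including the endpoints; ties break to the smallest
candidate (parsimony, determinism). The headline accuracy is the CV mean ±
sd over folds; the refit model's out-of-bag accuracy and per-class omission
errors (from OOB majority votes) are reported alongside. The three feature
sets are compared with identical samples and identical fold assignments, so
the comparison is paired; per-class omission errors in the comparison table
come from pooled out-of-fold predictions, and the difference columns are
exact subtractions of the stored errors.

Feature importance is permutation importance of the refit forest on the
training table, expressed as mean decrease in accuracy (percentage points).
Computing it on out-of-bag samples per tree would cost p × n_trees extra
prediction passes for the same ranking; the reported quantity is the
standard scikit-learn permutation importance instead.

Final-map prediction routes per pixel: clear in both seasons → bi-seasonal
model; clouded in exactly one season → the other season's single-season (+
terrain) model; clouded in both → unassigned sentinel 0, left for the MMU
filter's gap filling.

## MMU filter

Clumps are per-class connected components (default 8-connectivity — the 3×3
neighborhood). Clumps strictly below the area threshold (default 20 m², so a
5-pixel clump at 2 m pixels survives) are voided; voids are refilled
iteratively from the outside in: each pass, every void pixel with ≥ 1
labeled 3×3 neighbor takes the majority label among labeled neighbors, with
all fills in a pass reading the previous pass's labels (deterministic,
scan-order independent). Ties break to the tied class most frequent in the
whole map at fill start, then to the lowest class id. Because filling can
create new sub-threshold slivers, up to 3 bounded re-passes re-void slivers
made purely of filled pixels; residual violations are logged, never silently
"fixed" by touching surviving clumps, whose pixels are bit-identical in the
output. The area threshold and the connectivity are independent parameters
(a 20 m² threshold and a 9-pixel neighborhood are different readings of the
same cartographic intent; both are exposed).

## Design-based estimation

Strata are the map's assessment classes (merge groups — the two invasives —
collapsed before sampling), sampled by simple random sampling without
replacement; the default 53 pixels per stratum is a design input. The
worst-case multinomial sample-size helper uses B = χ²(1 df) at the
1−(1−confidence)/k quantile, n = B·Π(1−Π)/b² (b = 0.1 half-width default);
it is advisory and always overridable.

The estimators are the standard stratified good-practice formulas (see
README). Producer's-accuracy standard errors use the stratified variance
with mapped areas playing the role of stratum sizes. Adjusted-quantity CIs
are normal-approximation ±z·SE; the naive overall accuracy gets an exact
Clopper–Pearson interval. Strata with fewer than 2 samples are rejected
(variance undefined). Useful identities hold exactly: Σ p̂ = 1,
Σ Â<sub>j</sub> = Σ A<sub>i</sub>, and ÔA = Σ p̂<sub>jj</sub> =
Σ W<sub>i</sub>Û<sub>i</sub>.

**Validation scenario.** `confusion_scenario()` fixes a 200×200 synthetic
map (terrain seed 2026) and a "classified" version with seeded per-pixel
confusion: each class keeps 82% of its pixels and leaks 6% to each of the
next three classes in cyclic legend order. Spreading the leak over three
strata keeps every error-matrix cell away from 0/1, where the binomial
variance terms vanish and CIs would degenerate. Against this known truth the
package checks that a full-census "sample" reproduces areas and confusion
proportions exactly, and that 95% CIs over 500 stratified replicates cover
the truth at the nominal rate.

**Worked-example fixtures.** The packaged tables are the published
stratified assessment of an Everglades coastal vegetation map: a 10-class
error matrix printed as two-decimal row proportions, mapped areas
(7063.5 ha) and per-class adjusted user's accuracies. Integer counts are
reconstructed as round-half-away-from-zero(proportion × 53), which restores
every row total to exactly 53. The published matrix's diagonal and the
published per-class user's accuracies disagree for some classes (their row
orders appear inconsistent at the source); the area/user's-accuracy table is
taken as authoritative for area-weighted quantities, the matrix for raw
counts, and per-class adjusted areas are not treated as exact reference
values.

## Problem sizes and numerical choices

Default scenes are 200×200 pixels (2 m), a scale at which every community
band is wide enough to satisfy the field sampling protocol while the whole
pipeline runs in seconds; the evaluation scenarios use 140×140 scenes,
30–40 training points per class, 100-tree forests with a fixed mtry and
5-fold CV, and the validation studies 500 sampling replicates — sizes chosen
so properties are estimated with useful precision at desk-scale cost.
Reflectance is clipped to [0, 1] after noise; NDVI returns 0 at a zero
denominator; all random draws flow from explicit seeds, and fixed-seed runs
are bit-reproducible (the pipeline manifest records content hashes).

## Known limitations

- Synthetic spectra are invented fixtures; absolute accuracies on synthetic
  scenes do not transfer to real imagery.
- Atmospheric correction, orthorectification, pan-sharpening and GLCM
  textures are out of scope; file-mode inputs are assumed already in
  reflectance units and co-registered.
- The MMU filter can, in adversarial geometries, leave logged sub-threshold
  slivers after its bounded re-passes.
- Only the stratified estimator family is implemented — no model-assisted or
  spatially balanced designs; no classifiers beyond the random forest and no
  hyperparameters beyond trees / mtry / folds.
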
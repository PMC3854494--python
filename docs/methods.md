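# Methods

## Overview

`facegeo` tests whether genotypes at candidate SNPs predict normal facial
shape variation, using dense point-wise correspondence rather than a
small set of distances. The pipeline is: establish correspondence
(registration) → remove nuisance pose (superimposition) → test group
shape differences (permutation) → characterise them (PCA, genetic
models, hyperline, profiles). This note records the model, the defaults
and why, what the synthetic generator does and does not emulate, and the
numerical choices.

## Dense registration

One reference face is resampled to an even point set by area-weighted
uniform sampling of its triangles (expected count = surface area ×
density; default 1 point/mm², or an explicit count). The ordered
reference points are the correspondence index: point *i* means the same
anatomical location on every registered face.

For each sample, a 3D thin-plate spline maps the reference's 15
landmarks exactly onto the sample's landmarks (kernel U(r) = r — the
standard biharmonic choice in 3D — plus a full affine term, no
smoothing), the reference points are pushed through the warp, and each
warped point is projected to the globally closest point on the sample's
triangulated surface. Closest-point projection (rather than normal-ray
casting) is robust to mesh holes and grazing geometry. The candidate
search combines a KD-tree over triangle centroids with the faces
incident to the nearest vertices; the latter matters for elongated
boundary triangles whose centroids lie far from their corners. An
exhaustive search over all triangles is available and is used as the
oracle in tests.

The 15 landmarks (four eye canthi, nasion, pronasale, both alares,
subnasale, both lip corners, stomion, upper/lower lip points, chin) are
inputs; automatic landmark detection is out of scope. Earlobe landmarks
are excluded a priori. A landmark can be withheld from the warp (e.g.
stomion) to reproduce sensitivity analyses for non-neutral expressions.

Degenerate landmark configurations (coplanar or duplicated points) make
the TPS system singular; this is detected via the condition number
(threshold 1e12) and raised with a diagnostic rather than silently
regularised.

## Superimposition and the PPD

Partial generalized Procrustes analysis (PGPA) centres every
configuration at its centroid and iteratively rotates each onto the
evolving mean using the SVD solution with a determinant correction, so
reflections are never introduced. **No scaling step is applied** — size
is part of the phenotype. Full GPA (unit centroid size) is available
behind a `scale=True` flag for comparison. Convergence is declared when
the relative change of the mean shape falls below 1e-8 (cap 100
iterations; non-convergence is flagged, not fatal). The alignment
objective (total squared distance to the mean) is non-increasing across
iterations, which the tests verify.

The pair-wise shape distance is PPD = sqrt(Σᵢ dᵢ²/n), the RMS point
distance in mm. Normalising by the number of points makes values
comparable between the 15-landmark and dense data, which is the property
that makes the statistic useful across schemes; it is a metric on
superimposed shapes of fixed n. Signed point-wise distance maps use the
reference template's outward normals: positive where the reference mean
lies outside the compared mean.

## Association tests

**Geometric (LMG/DG).** Observed statistic: PPD between the two genotype
groups' mean shapes. Null: labels reshuffled over the two groups' pooled
individuals, group sizes preserved; larger PPD = stronger difference, so
p = (#{perm ≥ obs} + 1)/(N + 1) one-sided, with the unsmoothed
proportion also reported. The test accepts arbitrary labels (it is also
the age-group shape test). Permutations are evaluated in blocks as a
single matrix product (mean difference = shapeᵀ · weight vector), which
keeps 5,000-permutation tests on dense data in milliseconds. The pair is
canonicalised internally so the p-value is exactly invariant to which
group is named first. Groups under n = 20 are flagged as unreliable but
not excluded; under n = 2 the comparison is skipped.

**Landmark distances (LMD).** Traits failing Shapiro–Wilk normality at
α = 0.05 are removed (Tukey's HSD assumes normality; constant traits are
excluded with a diagnostic). Raw p-values per trait and genotype pair
come from the studentized range with the pooled one-way-ANOVA error term
(Tukey–Kramer for unequal group sizes). Family-wise correction over
traits is by min-P permutation: per permutation the minimum raw p across
traits is recorded per comparison, and a trait's corrected p is the
proportion of permutation minima at or below its raw p. Because group
sizes — hence degrees of freedom — are fixed within a comparison, the
minimum p corresponds to the maximum q statistic, so permutations rank q
directly and never evaluate the (slow) studentized-range tail. The
family is the trait set within one genotype comparison; corrected p is
floored at the raw p. Reshuffles preserve group sizes, so a permutation
can never degenerate a group.

**Supporting machinery.** Hardy–Weinberg equilibrium is checked with the
1-df chi-square against expectations from the sample allele frequency
(monomorphic markers return p = 1 with a warning). Bonferroni corrected
p = min(1, p·m); thresholds α/m are reported to two significant figures
(0.05/60 → 0.00083, 0.05/12 → 0.0042).

**Two-stage design.** Stage I screens all SNPs × three genotype
comparisons × both sexes on panel I (defaults mirroring the full design:
10,000 LMD permutations, 5,000 geometric). SNPs reaching nominal p < 0.1
in any geometric comparison advance; stage II re-tests them on panel II
and the combined panel (default 100,000 permutations). Tests are always
sex-stratified; permutations act only within the analysed stratum. All
permutation counts are configurable so the design runs at reduced scale.

## Shape modelling

PCA is computed on the flattened superimposed shape vectors with no
per-coordinate scaling ("equal variance for all points"), via SVD of the
centred data matrix — the covariance is never formed, which matters when
3n ≫ m. All m−1 non-trivial modes are kept, so eigenvalues sum to the
total coordinate variance. Genetic model fits are OLS of a shape score
on coded genotypes (additive 0/1/2; dominant 0/0/1), reporting the slope
p and R². PC group tests use the classical pooled two-sample t-test
(Welch by flag). The hyperline is the axis through two group mean
shapes, with its origin at their midpoint (so the means score at ± half
their separation); shape transformation along a mode is s_t = s_m +
k·σ_v·v. Profile lines take the points within a 1 mm half-width slab
about the sagittal plane x = 0, ordered top to bottom; the default
half-width is a display choice, configurable.

Mouth-region analyses extract a fixed index set (the bounding box of the
five mouth landmarks plus a 6 mm margin) from the whole-face alignment
**without re-superimposition**: the planted lip effect is largely a
rigid offset of the mouth patch, and re-aligning the patch alone would
absorb exactly the signal being tested. Region tests depend only on the
region's points.

## Synthetic cohort generator

The generator defines the study conditions for all tests.

* **Template**: an analytic height field (elliptic facial dome with
  nose, lip and chin features, 140 × 180 mm) triangulated on an
  x-symmetric grid, so outward normals and the 15 landmark positions are
  exact; landmarks snap to grid vertices and therefore ride consistently
  on any deformation. Default resolution 3,000 points (32,251 reproduces
  full scale; both configurable).
* **Demographics**: 856 individuals in two panels (376 with 208 females;
  480 with 306 females), ages uniform on 17–25. No age effect is
  generated, matching the finding that age groups do not differ in shape
  over so narrow a range.
* **Genotypes**: ten candidate SNPs drawn i.i.d. under Hardy–Weinberg
  frequencies (1−p)², 2p(1−p), p²; the effect SNP rs642961 defaults to
  MAF 0.15.
* **Effect**: TT females (dominant model, female-restricted) have every
  mouth-region point displaced 2.5 mm along its outward normal —
  thicker, more protrusive lips.
* **Individual variation**: five smooth global modes (lip prominence,
  global prominence, vertical gradient, lateral asymmetry, cheek
  curvature), each a unit-RMS scalar field times the outward normals,
  with Gaussian coefficients; plus isotropic Gaussian point noise of
  0.2 mm, the stated accuracy of the 3dMD-class scanners the data model
  emulates.

**Calibration of the mode variances.** Inside the small mouth region all
normal-displacement modes are nearly collinear with the effect field, so
the share of leading-PC variance attributable to the genotype reduces to
q(1−q)(d·v₁)²/λ₁, computable exactly from the generator's low-rank +
isotropic population covariance (`expected_pc1_r2`). The default mode
SDs (0.40, 0.45, 0.45, 0.80, 0.45 mm) set this share to ≈5% for the
default effect, the magnitude reported for real lip-shape variance
explained; fitted R² across seeds lands slightly above the analytic
share (≈0.5 percentage point) because sample PC1 estimation has a small
positive selection bias at n ≈ 500.

**What the generator does not emulate**: texture, expression, hair and
clothing artefacts, mesh holes, anisotropic or spatially correlated
scanner noise, population structure or linkage between SNPs, and
age-related shape change. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under a clean data
model, not that real scan artefacts are handled.

## Numerical choices and degenerate inputs

* TPS: direct dense solve; singular configurations raise with a
  diagnostic (no ridge fallback).
* GPA initialisation: the first shape; tolerance 1e-8; rotation ties
  broken by the SVD determinant correction (no reflections ever).
* Permutation p-values: add-one smoothing so p = 0 is impossible; the
  unsmoothed proportion is reported alongside.
* Constant traits, monomorphic SNPs, empty groups/regions/subsets, and
  meshes with zero area all raise or warn explicitly rather than
  propagating NaNs.
* The pipeline derives per-stage seeds from one master seed via
  `SeedSequence.spawn`, and identical configuration + seed reproduces
  every report byte for byte.

## Problem sizes used by the shipped checks

The test suite and acceptance script run the full design arithmetic at
full resolution (32,251 points once), and the simulation studies at
3,000 points / 856 individuals (effect recovery, 50 and 30 seeds), 600
points / 400 individuals (null type-I calibration, 200 replicates), and
99 traits × 300 individuals (min-P family-wise error, 200 replicates) —
sizes chosen so the whole battery completes in a few minutes on one CPU
while keeping every Monte-Carlo interval tight enough to be meaningful.

## Known limitations

* Closest-point projection can fold correspondences at very high
  curvature or for badly mismatched landmark sets; the non-rigid warp is
  only as anatomically meaningful as the 15 landmarks driving it.
* PPD compares mean shapes only; it is blind to variance differences
  between genotype groups.
* The min-P correction controls the family-wise error per genotype
  comparison; correction across SNPs, sexes and comparisons is by
  Bonferroni at the study level, which is conservative.
* No covariate adjustment (age, BMI), mixed models, kinship correction
  or genome-wide scanning; candidate-SNP designs only.
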
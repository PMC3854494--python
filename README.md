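# facegeo

Dense 3D facial registration and geometric genotype–phenotype association
testing.

Human facial shape is a complex, highly heritable trait, but most genetic
association studies have reduced it to a handful of inter-landmark
distances. `facegeo` implements the alternative: every face surface is
brought into dense point-wise correspondence (tens of thousands of
mathematically derived marker points), superimposed into a common frame,
and tested for genotype-linked shape differences directly in shape space.
It is aimed at researchers in geometric morphometrics and craniofacial
genetics who want a tested, reproducible pipeline they can run end to end
on synthetic cohorts or adapt to their own scans.

## What it computes

Three phenotype schemes over the same cohort:

* **LMD** — the k(k−1)/2 Euclidean distances between k named anatomical
  landmarks (15 landmarks → 105 traits), tested per trait with Tukey's
  HSD across the three genotype groups and corrected for multiple traits
  by min-P permutation.
* **LMG** — the 15-landmark configurations after partial generalized
  Procrustes superimposition (translation and rotation removed, **size
  retained**), tested as whole shapes.
* **DG** — the dense correspondence configurations (~32,000 points per
  face at full resolution), tested the same way and restrictable to a
  region such as the mouth.

The whole-shape test statistic is the point-wise Procrustes distance
between two genotype-group mean shapes,

    PPD(s, s′) = sqrt( (1/n) Σᵢ dᵢ² ),   dᵢ² = (xᵢ−xᵢ′)² + (yᵢ−yᵢ′)² + (zᵢ−zᵢ′)²,

an RMS point distance in mm, comparable across point densities. Its
significance comes from a permutation test: genotype labels are
reshuffled (group sizes preserved) and the one-sided p-value is
(#{perm PPD ≥ observed} + 1)/(N + 1).

Dense correspondence is established by resampling one reference face
evenly (≈1 point/mm²), warping it onto each sample with a thin-plate
spline driven by the 15 landmarks (3D kernel U(r) = r, exact
interpolation), and projecting each warped point to the closest point on
the sample surface.

Downstream shape modelling includes un-scaled PCA of the superimposed
shapes, per-PC two-sample t-tests, additive/dominant genetic model fits
(dominant: CC, CT → 0, TT → 1) with variance explained, hyperline (HL)
discriminant scores through two group means, mean-shape transformation
s_t = s_m ± 3σ_v·v along any mode, signed point-wise distance maps, and
mid-sagittal profile lines.

Because no real scans ship with the package, a synthetic-cohort module
generates parametric face meshes with exact landmarks and normals,
two-panel demographics, Hardy–Weinberg genotypes and a configurable
genotype-linked regional deformation (by default a female-specific
dominant 2.5 mm lip protrusion), so the entire pipeline is testable and
every result reproducible from a seed.

## Worked example

Generate the default study-scale cohort (856 individuals, two panels,
3,000 dense points, planted rs642961 effect), superimpose the female
stratum, and test the mouth region:

```python
import numpy as np
from facegeo import (SyntheticConfig, generate_cohort, partial_gpa,
                     extract_region, geometric_permutation_test,
                     shape_pca, fit_genetic_model)

cohort = generate_cohort(SyntheticConfig(seed=1))
fem = cohort.subset_ids(sex="female")
pos = [cohort.ids.index(i) for i in fem]
aligned = partial_gpa(cohort.dense_shapes()[pos], ids=fem)
mouth = extract_region(aligned, cohort.effect_indices)
codes = np.array([cohort.individuals[p].genotype_codes["rs642961"]
                  for p in pos])
for label, pair in (("CC:TT", (0, 2)), ("TT:CT", (2, 1)), ("CC:CT", (0, 1))):
    r = geometric_permutation_test(mouth, codes, pair, n_perm=5000, seed=1)
    print(f"{label}: PPD = {r.ppd:.2f} mm, p = {r.nominal_p:.4g}")
pca = shape_pca(mouth)
fit = fit_genetic_model(pca.scores[:, 0], codes, model="dominant")
print(f"dominant-model PC1 R^2 = {fit.r_squared:.4f} (p = {fit.p_value:.3g})")
```

Output:

```
CC:TT: PPD = 2.15 mm, p = 0.0002
TT:CT: PPD = 2.03 mm, p = 0.0002
CC:CT: PPD = 0.14 mm, p = 0.2753
dominant-model PC1 R^2 = 0.0333 (p = 3.15e-05)
```

This is the signature of a dominant effect: the TT homozygotes differ
from both CC and CT by ~2 mm RMS over the mouth (both p at the
permutation floor of 1/5001), while CC and CT are indistinguishable; the
dominant coding explains a few percent of the leading mouth-shape PC.

The same flow is available from the shell:

```
facegeo simulate --n 100 --points 800 --write-meshes --out cohort/
facegeo register --reference cohort/template.obj \
    --landmarks cohort/template_landmarks.tsv \
    --samples cohort/meshes --out shapes/
facegeo assoc --shapes shapes/ --genotypes cohort/genotypes.tsv \
    --snp rs642961 --sex female --n-perm 5000
facegeo run-all --config run.yaml --seed 1
```

`run-all` executes the full two-stage design (stage I screening on panel
I, stage II validation of advanced SNPs on panel II and the combined
panel) and writes TSV reports, a Markdown summary and a manifest with
every stage seed, so a run is bit-reproducible.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its calibration, numerical choices and known limitations.
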
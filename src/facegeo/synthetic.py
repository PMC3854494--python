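"""Synthetic face cohorts with planted genotype effects.

Generates cohorts of triangulated face surfaces — a smooth parametric
template plus per-individual variation — together with sexes, ages,
two-panel assignment and Hardy–Weinberg genotypes, and optionally plants a
genotype-linked regional deformation (e.g. a female-specific dominant lip
protrusion).  Because each individual's mesh is a deformation of the
template evaluated at the template's own vertices, the ground-truth dense
correspondence is known exactly, so every downstream stage (registration,
superimposition, association testing, shape modelling) can be validated
without any external data.

The template is an analytic height-field face (elliptic dome with nose,
lip and chin features) so outward normals and landmark ground truth are
exact.  Individual variation is a small number of smooth global
deformation modes with Gaussian coefficients — a known ground-truth basis
for PCA — plus isotropic Gaussian point noise emulating scanner error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .registration import (
    LANDMARK_NAMES,
    MOUTH_LANDMARKS,
    DenseShape,
    FaceMesh,
    ReferenceTemplate,
)

__all__ = [
    "SNP",
    "GeneticEffect",
    "SyntheticConfig",
    "Individual",
    "Cohort",
    "make_template_face",
    "sample_genotypes",
    "genotype_labels",
    "apply_genetic_effect",
    "generate_cohort",
    "mouth_region_indices",
    "resolve_region",
    "expected_pc1_r2",
]

# Face extents (mm): lateral semi-axis, vertical semi-axis, dome height.
_FACE_A, _FACE_B, _FACE_H = 70.0, 90.0, 45.0

# Landmark positions in the (x, y) parameter plane; +x is the subject's
# anatomical left, +y up.  Heights come from the template height field.
_LANDMARK_XY: dict[str, tuple[float, float]] = {
    "LExtCan": (-44.0, 28.0),
    "LIntCan": (-16.0, 28.0),
    "RIntCan": (16.0, 28.0),
    "RExtCan": (44.0, 28.0),
    "Prn": (0.0, 4.0),
    "Nsn": (0.0, 30.0),
    "LAla": (-17.0, -6.0),
    "RAla": (17.0, -6.0),
    "Sbn": (0.0, -16.0),
    "RLipCn": (26.0, -34.0),
    "LLipCn": (-26.0, -34.0),
    "Stm": (0.0, -34.0),
    "ULipP": (0.0, -28.0),
    "LLipP": (0.0, -41.0),
    "ChiP": (0.0, -68.0),
}


def _height_field(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Template face height z = f(x, y): dome + nose + lips + chin (mm)."""
    dome = _FACE_H * np.sqrt(np.clip(1.0 - (x / _FACE_A) ** 2 - (y / _FACE_B) ** 2, 0.0, None))
    nose = 14.0 * np.exp(-((x / 9.0) ** 2 + ((y - 5.0) / 16.0) ** 2))
    lips = 3.5 * np.exp(-((x / 24.0) ** 2 + ((y + 34.0) / 8.0) ** 2))
    chin = 2.0 * np.exp(-((x / 22.0) ** 2 + ((y + 72.0) / 12.0) ** 2))
    return dome + nose + lips + chin


@dataclass(frozen=True)
class SNP:
    """A biallelic marker: name, minor (derived) allele frequency, alleles."""

    name: str
    maf: float
    alleles: tuple[str, str] = ("A", "B")   # (wild type, derived type)

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.name}: minor-allele frequency must be in [0, 0.5]")


@dataclass(frozen=True)
class GeneticEffect:
    """A genotype-linked outward displacement of a face region.

    Under the dominant model only derived-allele homozygotes are displaced
    (dose 1); under the additive model heterozygotes receive half the
    displacement.  ``sex_restriction`` limits the effect to one sex.
    """

    target_snp: str
    model: str = "dominant"                 # {dominant, additive}
    sex_restriction: str = "none"           # {female, male, none}
    region: object = "mouth"                # region name or index array
    magnitude: float = 2.5                  # mm outward along point normals

    def __post_init__(self) -> None:
        if self.model not in ("dominant", "additive"):
            raise ValueError(f"unknown genetic model {self.model!r}")
        if self.sex_restriction not in ("female", "male", "none"):
            raise ValueError(f"unknown sex restriction {self.sex_restriction!r}")
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")

    def dose(self, genotype_code: int, sex: str) -> float:
        """Displacement multiplier for a coded genotype (0/1/2 derived alleles)."""
        if self.sex_restriction != "none" and sex != self.sex_restriction:
            return 0.0
        if self.model == "dominant":
            return 1.0 if genotype_code == 2 else 0.0
        return genotype_code / 2.0


# Default SNP set: ten candidate markers (wild/derived alleles as reported
# for ENPP1, GHR, FGFR1 and IRF6 candidates) with plausible Han Chinese
# minor-allele frequencies; rs642961 carries the planted effect by default.
_DEFAULT_SNPS: tuple[SNP, ...] = (
    SNP("rs7773292", 0.20, ("C", "T")),
    SNP("rs6925433", 0.30, ("A", "G")),
    SNP("rs6569759", 0.25, ("G", "A")),
    SNP("rs7754561", 0.35, ("G", "A")),
    SNP("rs6180", 0.45, ("A", "C")),
    SNP("rs6184", 0.18, ("C", "A")),
    SNP("rs4647905", 0.30, ("G", "C")),
    SNP("rs3213849", 0.40, ("C", "T")),
    SNP("rs642961", 0.15, ("C", "T")),
    SNP("rs2236907", 0.25, ("G", "T")),
)

# Standard deviations (mm RMS displacement) of the five smooth individual
# variation modes: lip prominence, global prominence, vertical gradient,
# lateral asymmetry, cheek curvature.  The leading lip-prominence mode is
# sized so that the default planted effect accounts for roughly 5% of the
# leading PC of mouth-region variation (see docs/methods.md).
_DEFAULT_MODE_SDS: tuple[float, ...] = (0.40, 0.45, 0.45, 0.80, 0.45)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings (sizes, markers, effect, noise)."""

    n_individuals: int = 856
    sex_ratio: float = 0.60                     # fraction female
    panel_sizes: tuple[int, int] = (376, 480)
    females_per_panel: tuple[int, int] | None = (208, 306)
    snps: tuple[SNP, ...] = _DEFAULT_SNPS
    effect: GeneticEffect | None = GeneticEffect(
        "rs642961", model="dominant", sex_restriction="female",
        region="mouth", magnitude=2.5)
    noise_sd: float = 0.2                       # mm, isotropic scanner noise
    n_dense_points: int = 3000
    mode_sds: tuple[float, ...] = _DEFAULT_MODE_SDS
    age_range: tuple[int, int] = (17, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.panel_sizes) != self.n_individuals:
            raise ValueError("panel sizes must sum to n_individuals")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.females_per_panel is not None:
            for nf, np_ in zip(self.females_per_panel, self.panel_sizes):
                if nf > np_:
                    raise ValueError("females_per_panel exceeds panel size")
        if self.effect is not None and all(s.name != self.effect.target_snp for s in self.snps):
            raise ValueError(f"effect targets unknown SNP {self.effect.target_snp!r}")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)

    @classmethod
    def null(cls, n: int = 400, n_dense_points: int = 600, seed: int = 0,
             snps: tuple[SNP, ...] | None = None) -> "SyntheticConfig":
        """A cohort with no planted genetic effect (for calibration tests)."""
        half = n // 2
        return cls(n_individuals=n, panel_sizes=(half, n - half),
                   females_per_panel=None, sex_ratio=0.5,
                   snps=snps if snps is not None else _DEFAULT_SNPS,
                   effect=None, n_dense_points=n_dense_points, seed=seed)


@dataclass
class Individual:
    id: str
    sex: str                                     # {female, male}
    age: int
    panel: str                                   # {I, II}
    genotypes: dict[str, str]                    # SNP name -> e.g. "CT"
    genotype_codes: dict[str, int]               # SNP name -> derived-allele count
    mesh: FaceMesh
    shape: DenseShape                            # ground-truth dense correspondence


@dataclass
class Cohort:
    """A generated cohort plus the ground truth used to build it."""

    config: SyntheticConfig
    template: FaceMesh
    reference: ReferenceTemplate
    individuals: list[Individual]
    mode_fields: np.ndarray                      # (K, n, 3) unit-RMS mode fields
    effect_field: np.ndarray                     # (n, 3), zero outside region
    effect_indices: np.ndarray                   # region point indices

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def dense_shapes(self) -> np.ndarray:
        """(m, n, 3) stack of ground-truth corresponded shapes."""
        return np.stack([ind.shape.points for ind in self.individuals])

    def genotype_table(self):
        """Per-individual metadata and genotype calls as a DataFrame."""
        import pandas as pd

        rows = []
        for ind in self.individuals:
            row = {"id": ind.id, "sex": ind.sex, "age": ind.age, "panel": ind.panel}
            row.update(ind.genotypes)
            rows.append(row)
        return pd.DataFrame(rows)

    def subset_ids(self, sex: str | None = None, panel=None) -> list[str]:
        panels = None if panel is None else ({panel} if isinstance(panel, str) else set(panel))
        return [i.id for i in self.individuals
                if (sex is None or i.sex == sex)
                and (panels is None or i.panel in panels)]


def make_template_face(config: SyntheticConfig | None = None,
                       n_dense_points: int | None = None) -> FaceMesh:
    """Build the smooth, bilaterally symmetric parametric template face.

    A height field z = f(x, y) over an elliptic domain, triangulated on a
    regular grid whose resolution is chosen so the vertex count is close
    to ``n_dense_points``.  The 15 landmarks are placed at their analytic
    parameter positions and snapped to the nearest grid vertex, so each
    landmark is exactly a surface point and moves consistently with any
    later vertex deformation.  Deterministic for a fixed config.
    """
    if n_dense_points is None:
        n_dense_points = (config.n_dense_points if config is not None else 3000)
    if n_dense_points < 100:
        raise ValueError("n_dense_points must be >= 100")
    # vertices fill ~pi/4 of the bounding grid; force an odd grid so the
    # mid-sagittal line x = 0 is sampled and the grid is x-symmetric
    m = int(np.ceil(np.sqrt(4.0 * n_dense_points / np.pi)))
    if m % 2 == 0:
        m += 1
    xs = np.linspace(-_FACE_A, _FACE_A, m)
    ys = np.linspace(-_FACE_B, _FACE_B, m)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = (gx / _FACE_A) ** 2 + (gy / _FACE_B) ** 2 <= 1.0
    index = -np.ones((m, m), dtype=np.int64)
    index[inside] = np.arange(inside.sum())
    vx, vy = gx[inside], gy[inside]
    vz = _height_field(vx, vy)
    vertices = np.column_stack([vx, vy, vz])

    faces = []
    for i in range(m - 1):
        for j in range(m - 1):
            v00, v10 = index[i, j], index[i + 1, j]
            v01, v11 = index[i, j + 1], index[i + 1, j + 1]
            if min(v00, v10, v01, v11) >= 0:
                faces.append((v00, v10, v11))
                faces.append((v00, v11, v01))
    faces = np.array(faces, dtype=np.int64)

    # drop vertices not referenced by any triangle (isolated rim corners)
    used = np.unique(faces)
    if len(used) < len(vertices):
        remap = -np.ones(len(vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        vertices = vertices[used]
        vx, vy = vx[used], vy[used]
        faces = remap[faces]

    mesh = FaceMesh(vertices, faces)
    if np.any(mesh.triangle_areas() <= 0):
        raise ValueError("degenerate template: zero-area triangles")

    landmarks = {}
    for name in LANDMARK_NAMES:
        x0, y0 = _LANDMARK_XY[name]
        i = int(np.argmin((vx - x0) ** 2 + (vy - y0) ** 2))
        landmarks[name] = vertices[i].copy()
    mesh.landmarks = landmarks
    return mesh


def _landmark_vertex_indices(mesh: FaceMesh) -> dict[str, int]:
    idx = {}
    for name, p in mesh.landmarks.items():
        d = ((mesh.vertices - p) ** 2).sum(axis=1)
        i = int(np.argmin(d))
        idx[name] = i
    return idx


def mouth_region_indices(template: FaceMesh | ReferenceTemplate,
                         margin: float = 6.0) -> np.ndarray:
    """Point indices inside the mouth box spanned by the 5 mouth landmarks."""
    pts = template.points if isinstance(template, ReferenceTemplate) else template.vertices
    lms = np.stack([template.landmarks[n] for n in MOUTH_LANDMARKS])
    lo = lms.min(axis=0)[:2] - margin
    hi = lms.max(axis=0)[:2] + margin
    sel = np.all((pts[:, :2] >= lo) & (pts[:, :2] <= hi), axis=1)
    return np.flatnonzero(sel)


def resolve_region(template, region) -> np.ndarray:
    """Resolve a region spec (name or index array) to point indices."""
    if isinstance(region, str):
        if region == "mouth":
            return mouth_region_indices(template)
        if region in ("whole", "all", "face"):
            n = len(template.points if isinstance(template, ReferenceTemplate)
                    else template.vertices)
            return np.arange(n)
        raise ValueError(f"unknown region name {region!r}")
    idx = np.asarray(region, dtype=int)
    if idx.size == 0:
        raise ValueError("empty region index set")
    return idx


def _mode_amplitudes(points: np.ndarray) -> np.ndarray:
    """Five smooth scalar fields over the face, each unit-RMS (K, n)."""
    x, y = points[:, 0], points[:, 1]
    u, v = x / _FACE_A, y / _FACE_B
    fields = np.stack([
        np.exp(-((x / 26.0) ** 2 + ((y + 34.0) / 11.0) ** 2)),   # lip prominence
        np.cos(0.5 * np.pi * u) * np.cos(0.5 * np.pi * v),       # global prominence
        v,                                                        # vertical gradient
        u,                                                        # lateral asymmetry
        np.cos(np.pi * u) * np.cos(np.pi * v),                    # cheek curvature
    ])
    rms = np.sqrt((fields ** 2).mean(axis=1, keepdims=True))
    return fields / rms


def sample_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Draw n genotypes (coded 0/1/2 derived alleles) under HWE.

    Genotype frequencies are (1-p)^2, 2p(1-p), p^2 at derived-allele
    frequency p = ``maf``; draws are i.i.d. and reproducible under seed
    (an integer seed or a ``numpy.random.Generator``).
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    return rng.choice(3, size=n, p=probs)


def genotype_labels(codes: np.ndarray, alleles: tuple[str, str]) -> list[str]:
    """Convert 0/1/2 codes to two-letter genotype strings (e.g. 'CT')."""
    wild, derived = alleles
    table = {0: wild + wild, 1: wild + derived, 2: derived + derived}
    return [table[int(c)] for c in codes]


def apply_genetic_effect(shape: DenseShape, genotype_code: int, sex: str,
                         effect: GeneticEffect,
                         template: ReferenceTemplate) -> DenseShape:
    """Displace the effect region outward along the template normals.

    Individuals whose genotype/sex do not match the effect's model and
    sex restriction are returned unchanged; matching individuals have
    every region point moved ``magnitude * dose`` mm along its outward
    normal, all other points untouched.
    """
    dose = effect.dose(genotype_code, sex)
    if dose == 0.0 or effect.magnitude == 0.0:
        return DenseShape(shape.points.copy())
    idx = resolve_region(template, effect.region)
    pts = shape.points.copy()
    pts[idx] += effect.magnitude * dose * template.normals[idx]
    return DenseShape(pts)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full synthetic cohort: meshes, landmarks, genotypes.

    Each individual's surface is the template deformed by Gaussian-weighted
    smooth variation modes, plus the planted genetic effect (if any and if
    the individual matches), plus i.i.d. Gaussian point noise.  Landmarks
    ride on their template vertices, so they are perturbed consistently
    with the surface.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    template = make_template_face(config)
    reference = ReferenceTemplate.from_mesh_vertices(template)
    n = reference.n_points
    lm_idx = _landmark_vertex_indices(template)

    amps = _mode_amplitudes(reference.points)                  # (K, n)
    mode_fields = amps[:, :, None] * reference.normals[None]   # (K, n, 3)
    sds = np.asarray(config.mode_sds, dtype=float)
    if len(sds) != len(mode_fields):
        raise ValueError("mode_sds length must match the number of modes")

    if config.effect is not None:
        eff_idx = resolve_region(reference, config.effect.region)
        effect_field = np.zeros((n, 3))
        effect_field[eff_idx] = config.effect.magnitude * reference.normals[eff_idx]
    else:
        eff_idx = np.empty(0, dtype=int)
        effect_field = np.zeros((n, 3))

    # demographic layout: panels then sex within panel (shuffled), ages
    panels, sexes = [], []
    for p_i, p_size in enumerate(config.panel_sizes):
        if config.females_per_panel is not None:
            nf = config.females_per_panel[p_i]
        else:
            nf = int(round(config.sex_ratio * p_size))
        sex = np.array(["female"] * nf + ["male"] * (p_size - nf))
        rng.shuffle(sex)
        sexes.append(sex)
        panels.append(np.full(p_size, "I" if p_i == 0 else "II"))
    sexes = np.concatenate(sexes)
    panels = np.concatenate(panels)
    m = config.n_individuals
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=m)

    codes = {snp.name: sample_genotypes(m, snp.maf, rng) for snp in config.snps}
    coeffs = rng.standard_normal((m, len(sds))) * sds           # mode coefficients

    individuals: list[Individual] = []
    base = reference.points
    for i in range(m):
        disp = np.tensordot(coeffs[i], mode_fields, axes=(0, 0))
        if config.effect is not None:
            dose = config.effect.dose(int(codes[config.effect.target_snp][i]), sexes[i])
            if dose:
                disp = disp + dose * effect_field
        if config.noise_sd > 0:
            disp = disp + rng.normal(0.0, config.noise_sd, size=(n, 3))
        verts = base + disp
        landmarks = {name: verts[j].copy() for name, j in lm_idx.items()}
        mesh = template.with_vertices(verts, landmarks)
        geno_codes = {name: int(c[i]) for name, c in codes.items()}
        genos = {snp.name: genotype_labels([geno_codes[snp.name]], snp.alleles)[0]
                 for snp in config.snps}
        individuals.append(Individual(
            id=f"ind{i:04d}", sex=str(sexes[i]), age=int(ages[i]),
            panel=str(panels[i]), genotypes=genos, genotype_codes=geno_codes,
            mesh=mesh, shape=DenseShape(verts),
        ))
    return Cohort(config, template, reference, individuals,
                  mode_fields, effect_field, eff_idx)


def expected_pc1_r2(cohort: Cohort, region=None, sex: str = "female") -> float:
    """Model-implied share of leading-PC variance explained by the effect.

    Under the generator, the population covariance of the (region-
    restricted) shape vectors is low-rank plus isotropic noise:

        Sigma = sum_k sd_k^2 m_k m_k' + q(1-q) d d' + noise_sd^2 I

    where m_k are the mode fields, d the planted displacement field and q
    the frequency of displaced individuals in the analysed stratum.  The
    dominant-model R^2 on the leading PC is q(1-q) (d . v1)^2 / lambda1,
    computed exactly from the top singular pair of the low-rank part.
    """
    cfg = cohort.config
    if cfg.effect is None:
        return 0.0
    if cfg.effect.model != "dominant":
        raise NotImplementedError("analytic share implemented for the dominant model")
    maf = next(s.maf for s in cfg.snps if s.name == cfg.effect.target_snp)
    q = maf ** 2
    idx = (np.arange(cohort.reference.n_points) if region is None
           else resolve_region(cohort.reference, region))
    modes = cohort.mode_fields[:, idx].reshape(len(cohort.mode_fields), -1)
    d = cohort.effect_field[idx].reshape(-1)
    sds = np.asarray(cfg.mode_sds)
    B = np.vstack([sds[:, None] * modes, np.sqrt(q * (1 - q)) * d]).T
    U, S, _ = np.linalg.svd(B, full_matrices=False)
    v1 = U[:, 0]
    lam1 = S[0] ** 2 + cfg.noise_sd ** 2
    return float(q * (1 - q) * (d @ v1) ** 2 / lam1)
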
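"""Genotype-phenotype association testing for facial shape.

Three phenotype schemes are supported:

* **LMD** — inter-landmark Euclidean distances, tested per trait with
  Tukey's honestly-significant-difference test and corrected for the
  number of traits by min-P permutation.
* **LMG** — the superimposed 15-landmark configurations, tested with the
  PPD permutation test on group mean shapes.
* **DG** — the superimposed dense-correspondence configurations, tested
  the same way (optionally restricted to a region such as the mouth).

Plus the supporting machinery: Hardy–Weinberg equilibrium checks,
Bonferroni correction, and the two-stage panel design in which markers
with preliminary evidence in panel I are re-tested in panel II and the
combined panel.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .superimposition import AlignedShapeSet, partial_gpa, ppd

__all__ = [
    "COMPARISONS",
    "landmark_distances",
    "landmark_distance_matrix",
    "NormalityResult",
    "normality_filter",
    "tukey_hsd",
    "minp_permutation_correction",
    "AssocResultGeom",
    "geometric_permutation_test",
    "extract_region",
    "hwe_test",
    "bonferroni",
    "bonferroni_threshold",
    "TwoStageReport",
    "two_stage_pipeline",
]

#: Genotype group comparisons, as (group_i, group_j) code pairs.
#: Codes count derived alleles: AA=0 (wild-type homozygote), AB=1, BB=2.
COMPARISONS: tuple[tuple[str, tuple[int, int]], ...] = (
    ("AA:BB", (0, 2)),
    ("AA:AB", (0, 1)),
    ("BB:AB", (2, 1)),
)


def landmark_distances(landmarks: dict[str, np.ndarray]) -> pd.Series:
    """All unordered-pair Euclidean distances between named landmarks.

    Returns a Series indexed "A - B"; k landmarks give k(k-1)/2 traits.
    """
    names = list(landmarks)
    if len(names) != len(set(names)):
        raise ValueError("duplicate landmark names")
    if len(names) < 2:
        raise ValueError("need at least two landmarks")
    out = {}
    for a, b in itertools.combinations(names, 2):
        out[f"{a} - {b}"] = float(np.linalg.norm(
            np.asarray(landmarks[a], float) - np.asarray(landmarks[b], float)))
    return pd.Series(out)


def landmark_distance_matrix(individuals) -> pd.DataFrame:
    """Per-individual landmark-distance traits (rows: ids, columns: pairs)."""
    rows = {ind.id: landmark_distances(ind.mesh.landmarks) for ind in individuals}
    return pd.DataFrame(rows).T


@dataclass
class NormalityResult:
    retained: list[str]
    pvalues: pd.Series
    excluded_constant: list[str] = field(default_factory=list)


def normality_filter(trait_matrix: pd.DataFrame, alpha: float = 0.05) -> NormalityResult:
    """Drop traits that fail the Shapiro–Wilk normality test at ``alpha``.

    Constant traits (W undefined) are excluded with a diagnostic.  With
    ``alpha = 0`` every non-constant trait is retained.
    """
    pvals, retained, constant = {}, [], []
    for name in trait_matrix.columns:
        x = trait_matrix[name].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError("need at least 3 observations per trait")
        if np.ptp(x) == 0:
            constant.append(name)
            pvals[name] = np.nan
            continue
        p = float(stats.shapiro(x).pvalue)
        pvals[name] = p
        if not p < alpha:
            retained.append(name)
    if constant:
        warnings.warn(f"excluded constant traits (Shapiro W undefined): {constant}")
    return NormalityResult(retained, pd.Series(pvals), constant)


def _groups_by_code(values: np.ndarray, codes: np.ndarray) -> dict[int, np.ndarray]:
    return {c: values[codes == c] for c in (0, 1, 2)}


def tukey_hsd(values: np.ndarray, codes: np.ndarray) -> dict[str, float]:
    """Tukey HSD raw p for the three genotype-pair comparisons.

    Uses the studentized range with the pooled one-way-ANOVA error term
    over the genotype groups (derived-allele counts 0/1/2).  Comparisons
    involving a group with fewer than two observations are omitted with
    a warning.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes)
    groups = _groups_by_code(values, codes)
    usable = [c for c in (0, 1, 2) if len(groups[c]) >= 2]
    skipped = [c for c in (0, 1, 2) if len(groups[c]) < 2]
    if skipped:
        warnings.warn(f"genotype groups below n=2 omitted from Tukey: {skipped}")
    if len(usable) < 2:
        raise ValueError("fewer than two genotype groups with n >= 2")
    if all(np.var(groups[c]) == 0 for c in usable):
        raise ValueError("zero pooled variance: Tukey HSD undefined")
    res = stats.tukey_hsd(*[groups[c] for c in usable])
    pos = {c: i for i, c in enumerate(usable)}
    out = {}
    for label, (a, b) in COMPARISONS:
        if a in pos and b in pos:
            out[label] = float(res.pvalue[pos[a], pos[b]])
    return out


def _tukey_q(X: np.ndarray, codes: np.ndarray, colsq: np.ndarray) -> np.ndarray:
    """Vectorised Tukey-Kramer q statistics, (traits, 3 comparisons).

    ``X`` is (n, t); ``colsq`` is the precomputed column sum of squares.
    Returns NaN columns when a group is below n=2.  Within one comparison
    the group sizes are fixed, so the raw p is a monotone decreasing
    function of q — permutation min-p corrections can therefore rank the
    max q instead of evaluating studentized-range tail probabilities.
    """
    n = len(codes)
    masks = [codes == c for c in (0, 1, 2)]
    ns = np.array([m.sum() for m in masks])
    sums = np.stack([X[m].sum(axis=0) if ns[i] else np.zeros(X.shape[1])
                     for i, m in enumerate(masks)])
    means = sums / np.maximum(ns, 1)[:, None]
    ss_within = colsq - (ns[:, None] * means ** 2).sum(axis=0)
    k = int((ns > 0).sum())
    df = n - k
    mse = ss_within / max(df, 1)
    q = np.full((X.shape[1], len(COMPARISONS)), np.nan)
    for j, (_, (a, b)) in enumerate(COMPARISONS):
        if ns[a] >= 2 and ns[b] >= 2:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q[:, j] = np.abs(means[a] - means[b]) / se
    return q


def minp_permutation_correction(trait_matrix: pd.DataFrame, codes: np.ndarray,
                                n_perm: int = 10_000, seed=None,
                                compute_raw: bool = True) -> pd.DataFrame:
    """min-P family-wise correction of Tukey p-values over traits.

    For each permutation the genotype labels are reshuffled over the
    individuals (group sizes preserved) and, per genotype comparison, the
    minimum raw p over all traits is recorded; the corrected p of a trait
    is the proportion of permutation minima at or below its raw p (with
    add-one smoothing).  Since group sizes and degrees of freedom are
    constant within a comparison, the minimum p corresponds to the
    maximum studentized-range statistic, which is what is ranked.

    Returns a tidy frame with raw and corrected p per trait/comparison.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    X = trait_matrix.to_numpy(dtype=float)
    codes = np.asarray(codes)
    n, t = X.shape
    colsq = (X ** 2).sum(axis=0)
    q_obs = _tukey_q(X, codes, colsq)                      # (t, 3)

    ns = np.array([(codes == c).sum() for c in (0, 1, 2)])
    k = int((ns > 0).sum())
    df = n - k
    if compute_raw:
        raw = stats.studentized_range.sf(q_obs, k, df)
    else:
        # rank-based corrected p only (the raw tail evaluation is costly
        # and unnecessary for family-wise error simulations)
        raw = np.full_like(q_obs, np.nan)

    null_max = np.full((n_perm, len(COMPARISONS)), np.nan)
    for b in range(n_perm):
        perm = rng.permutation(codes)
        qp = _tukey_q(X, perm, colsq)
        null_max[b] = np.nanmax(qp, axis=0)

    rows = []
    for j, (label, (a, bb)) in enumerate(COMPARISONS):
        for i, trait in enumerate(trait_matrix.columns):
            if np.isnan(q_obs[i, j]):
                continue
            exceed = int((null_max[:, j] >= q_obs[i, j]).sum())
            corrected = (exceed + 1) / (n_perm + 1)
            rp = float(raw[i, j])
            rows.append({
                "trait": trait, "comparison": label, "raw_p": rp,
                "corrected_p": corrected if np.isnan(rp) else max(rp, corrected),
                "n_a": int(ns[a]), "n_b": int(ns[bb]),
            })
    return pd.DataFrame(rows)


@dataclass
class AssocResultGeom:
    """Result of one PPD permutation test between two genotype groups."""

    comparison: str
    ppd: float                       # observed PPD between group means, mm
    nominal_p: float                 # add-one smoothed permutation p
    p_unsmoothed: float              # plain proportion of perms >= observed
    n_perm: int
    group_sizes: tuple[int, int]
    sex: str = ""
    scheme: str = ""                 # {LMG, DG}
    region: str = "whole face"
    flagged_small: bool = False      # any group below n=20 (unreliable)


def geometric_permutation_test(aligned: AlignedShapeSet, labels, pair,
                               n_perm: int = 5000, seed=None,
                               sex: str = "", scheme: str = "",
                               region: str = "whole face",
                               flag_below: int = 20,
                               chunk: int = 256) -> AssocResultGeom:
    """PPD permutation test between two labelled groups of aligned shapes.

    The observed statistic is the PPD between the two group mean shapes;
    the null distribution is obtained by reshuffling the two groups'
    labels over their pooled individuals (sizes preserved) and recording
    the permuted-group PPD.  Larger PPD means stronger group difference,
    so the one-sided p is the proportion of permutations with PPD at or
    above the observed value, with add-one smoothing:
    p = (#{perm >= obs} + 1) / (n_perm + 1).

    Works for arbitrary labels (genotype groups, age groups, ...).
    """
    labels = np.asarray(labels)
    if len(labels) != aligned.n_shapes:
        raise ValueError("labels must cover the aligned set")
    a, b = pair
    mask_a = labels == a
    mask_b = labels == b
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na == 0 or nb == 0:
        raise ValueError(f"empty group in comparison {a}:{b}")
    X = aligned.vectors()[mask_a | mask_b]                 # (na+nb, 3n)
    n_points = aligned.n_points
    sub_labels = labels[mask_a | mask_b]
    # canonical orientation so the p-value is invariant to pair order
    first, second = sorted([a, b], key=str)
    m1 = int((sub_labels == first).sum())
    w_obs = np.where(sub_labels == first, 1.0 / m1, -1.0 / (len(sub_labels) - m1))
    obs = float(np.linalg.norm(X.T @ w_obs) / np.sqrt(n_points))

    rng = np.random.default_rng(seed)
    m = len(sub_labels)
    exceed = 0
    done = 0
    base = np.full(m, -1.0 / (m - m1))
    while done < n_perm:
        c = min(chunk, n_perm - done)
        W = np.tile(base, (c, 1))
        for i in range(c):
            idx = rng.permutation(m)[:m1]
            W[i, idx] = 1.0 / m1
        perm_ppd = np.linalg.norm(X.T @ W.T, axis=0) / np.sqrt(n_points)
        exceed += int((perm_ppd >= obs - 1e-12).sum())
        done += c
    return AssocResultGeom(
        comparison=f"{a}:{b}", ppd=obs,
        nominal_p=(exceed + 1) / (n_perm + 1),
        p_unsmoothed=exceed / n_perm,
        n_perm=n_perm, group_sizes=(na, nb), sex=sex, scheme=scheme,
        region=region, flagged_small=min(na, nb) < flag_below)


def extract_region(aligned: AlignedShapeSet, indices) -> AlignedShapeSet:
    """Restrict an aligned set to a subset of correspondence points.

    No re-superimposition is performed; shapes stay in the whole-face
    frame and the mean is recomputed on the subset.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty region index set")
    sub = aligned.shapes[:, idx]
    return AlignedShapeSet(sub, sub.mean(axis=0), list(aligned.ids),
                           aligned.converged, aligned.iterations)


def hwe_test(counts) -> tuple[float, float]:
    """1-df chi-square test of genotype counts against HWE expectations.

    ``counts`` = (n_AA, n_AB, n_BB).  Expected frequencies come from the
    sample allele frequency.  A monomorphic marker returns p = 1 with a
    warning.  The statistic is invariant to swapping the allele labels.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one individual")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic marker: HWE test undefined, returning p = 1")
        return 0.0, 1.0
    expected = np.array([p ** 2, 2 * p * (1 - p), (1 - p) ** 2]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bonferroni(p: float, m_tests: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, p * m_tests)


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Significance threshold alpha/m, reported to two significant figures."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    t = alpha / m_tests
    return float(f"{t:.1e}")


@dataclass
class TwoStageReport:
    """Assembled results of the two-stage association design."""

    lmd_stage1: pd.DataFrame
    geom_stage1: pd.DataFrame
    geom_stage2: pd.DataFrame
    hwe: pd.DataFrame
    advanced: list[str]
    n_tests_stage1: int              # geometric family: SNPs x 3 x 2 sexes
    n_tests_stage2: int              # advanced SNPs x 6 comparisons
    threshold_stage1: float
    threshold_stage2: float


def _geom_tests_for_subset(shapes: np.ndarray, ids: list[str], codes: np.ndarray,
                           n_perm: int, rng: np.random.Generator, sex: str,
                           scheme: str, region_name: str,
                           min_group: int = 2) -> list[AssocResultGeom]:
    aligned = partial_gpa(shapes, ids=ids)
    out = []
    for label, (a, b) in COMPARISONS:
        na, nb = int((codes == a).sum()), int((codes == b).sum())
        if min(na, nb) < min_group:
            continue
        res = geometric_permutation_test(
            aligned, codes, (a, b), n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)), sex=sex, scheme=scheme,
            region=region_name)
        res.comparison = label
        out.append(res)
    return out


def two_stage_pipeline(cohort, *, n_perm_lmd: int = 10_000,
                       n_perm_geom_stage1: int = 5000,
                       n_perm_stage2: int = 100_000,
                       advance_threshold: float = 0.1,
                       alpha: float = 0.05,
                       shapiro_alpha: float = 0.05,
                       region=None,
                       schemes: tuple[str, ...] = ("lmd", "lmg", "dg"),
                       min_group: int = 2,
                       seed: int = 0) -> TwoStageReport:
    """Run the two-stage association design on a cohort.

    Stage I screens every SNP with all requested schemes, separately per
    sex, on panel I (LMD: Tukey + min-P permutation; LMG/DG: PPD
    permutation).  SNPs whose geometric tests reach ``advance_threshold``
    nominal significance in any comparison advance to stage II, where the
    LMG/DG tests are repeated on panel II and the combined panel with
    ``n_perm_stage2`` permutations.  ``region`` optionally restricts the
    dense data (e.g. mouth point indices) before testing.

    Permutation counts are configurable so the design can be run at
    reduced scale; the defaults mirror the full study design.
    """
    from .registration import LANDMARK_NAMES
    from .synthetic import resolve_region

    rng = np.random.default_rng(seed)
    table = cohort.genotype_table().set_index("id")
    snps = cohort.config.snps
    all_inds = {ind.id: ind for ind in cohort.individuals}

    hwe_rows = []
    for snp in snps:
        codes = np.array([all_inds[i].genotype_codes[snp.name] for i in all_inds])
        counts = [(codes == c).sum() for c in (0, 1, 2)]
        chi2, p = hwe_test(counts)
        hwe_rows.append({"snp": snp.name, "n_AA": counts[0], "n_AB": counts[1],
                         "n_BB": counts[2], "chi2": chi2, "p": p})
    hwe = pd.DataFrame(hwe_rows)

    region_idx = None if region is None else resolve_region(cohort.reference, region)
    region_name = "whole face" if region is None else \
        (region if isinstance(region, str) else "custom")

    dense = cohort.dense_shapes()
    ids = cohort.ids
    id_pos = {v: i for i, v in enumerate(ids)}
    lm_configs = np.stack([
        all_inds[i].mesh.landmark_array(LANDMARK_NAMES) for i in ids])

    def subset(sex, panels):
        keep = [i for i in ids if all_inds[i].sex == sex and all_inds[i].panel in panels]
        pos = np.array([id_pos[i] for i in keep], dtype=int)
        return keep, pos

    lmd_rows, geom1_rows = [], []
    for sex in ("male", "female"):
        keep, pos = subset(sex, {"I"})
        if "lmd" in schemes:
            traits = landmark_distance_matrix([all_inds[i] for i in keep])
            norm = normality_filter(traits, alpha=shapiro_alpha)
            traits = traits[norm.retained]
            for snp in snps:
                codes = np.array([all_inds[i].genotype_codes[snp.name] for i in keep])
                if sorted(np.unique(codes).tolist()) != [0, 1, 2]:
                    continue
                if min((codes == c).sum() for c in (0, 1, 2)) < min_group:
                    continue
                df = minp_permutation_correction(
                    traits, codes, n_perm=n_perm_lmd,
                    seed=int(rng.integers(2 ** 31)))
                df.insert(0, "snp", snp.name)
                df.insert(1, "sex", sex)
                lmd_rows.append(df)
        for scheme, data in (("LMG", lm_configs), ("DG", dense)):
            if scheme.lower() not in schemes:
                continue
            shapes = data[pos]
            if scheme == "DG" and region_idx is not None:
                shapes = shapes[:, region_idx]
            for snp in snps:
                codes = np.array([all_inds[i].genotype_codes[snp.name] for i in keep])
                for res in _geom_tests_for_subset(
                        shapes, keep, codes, n_perm_geom_stage1, rng, sex,
                        scheme, region_name if scheme == "DG" else "whole face",
                        min_group):
                    geom1_rows.append({"snp": snp.name, "sex": sex,
                                       "scheme": scheme, **res.__dict__})

    lmd_stage1 = pd.concat(lmd_rows, ignore_index=True) if lmd_rows else pd.DataFrame()
    geom_stage1 = pd.DataFrame(geom1_rows)

    advanced = []
    if not geom_stage1.empty:
        for snp in snps:
            sub = geom_stage1[geom_stage1.snp == snp.name]
            if not sub.empty and (sub.nominal_p < advance_threshold).any():
                advanced.append(snp.name)

    geom2_rows = []
    for snp_name in advanced:
        for sex in ("male", "female"):
            for panel_label, panels in (("II", {"II"}), ("I+II", {"I", "II"})):
                keep, pos = subset(sex, panels)
                codes = np.array([all_inds[i].genotype_codes[snp_name] for i in keep])
                for scheme, data in (("LMG", lm_configs), ("DG", dense)):
                    if scheme.lower() not in schemes:
                        continue
                    shapes = data[pos]
                    if scheme == "DG" and region_idx is not None:
                        shapes = shapes[:, region_idx]
                    for res in _geom_tests_for_subset(
                            shapes, keep, codes, n_perm_stage2, rng, sex,
                            scheme, region_name if scheme == "DG" else "whole face",
                            min_group):
                        geom2_rows.append({"snp": snp_name, "sex": sex,
                                           "panel": panel_label, "scheme": scheme,
                                           **res.__dict__})
    geom_stage2 = pd.DataFrame(geom2_rows)

    n_tests_stage1 = len(snps) * 3 * 2
    n_tests_stage2 = len(advanced) * 6
    return TwoStageReport(
        lmd_stage1=lmd_stage1, geom_stage1=geom_stage1, geom_stage2=geom_stage2,
        hwe=hwe, advanced=advanced,
        n_tests_stage1=n_tests_stage1, n_tests_stage2=n_tests_stage2,
        threshold_stage1=bonferroni_threshold(alpha, n_tests_stage1),
        threshold_stage2=bonferroni_threshold(alpha, max(n_tests_stage2, 1)),
    )
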
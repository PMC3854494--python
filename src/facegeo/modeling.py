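"""Shape-space modelling: un-scaled PCA, genetic models, hyperline, profiles.

The PCA is carried out on the flattened, superimposed shape vectors with
no per-coordinate scaling ("equal variance for all points"), i.e. an
eigendecomposition of the coordinate covariance computed via SVD of the
centred data — numerically preferable when the dimension 3n far exceeds
the number of individuals.

The hyperline is the line through two group mean shapes; projecting
individuals onto it gives a one-dimensional discriminant score (HL score)
for visualising how well the groups separate.  Shape transformation along
a PCA mode (mean +/- k standard deviations) turns eigenvectors back into
viewable face shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .superimposition import AlignedShapeSet

__all__ = [
    "ShapePCA",
    "shape_pca",
    "pc_group_ttest",
    "GeneticModelFit",
    "fit_genetic_model",
    "dominant_coding",
    "additive_coding",
    "HyperlineModel",
    "hyperline_model",
    "hyperline_scores",
    "transform_shape",
    "profile_line",
]


@dataclass
class ShapePCA:
    """Un-scaled PCA of flattened shape vectors.

    ``eigenvectors`` rows are orthonormal modes in shape space;
    ``eigenvalues`` are the corresponding score variances (ddof=1);
    ``scores[i, j]`` is individual i's projection on mode j.
    """

    mean: np.ndarray                 # (3n,) mean shape vector
    eigenvectors: np.ndarray         # (k, 3n)
    eigenvalues: np.ndarray          # (k,)
    scores: np.ndarray               # (m, k)
    n_points: int

    def mode_shape(self, mode: int) -> np.ndarray:
        """Eigenvector reshaped to an (n, 3) displacement field."""
        return self.eigenvectors[mode].reshape(self.n_points, 3)

    def reconstruct(self, i: int, n_modes: int | None = None) -> np.ndarray:
        """Rebuild shape i from the mean plus (a subset of) modes."""
        k = self.scores.shape[1] if n_modes is None else n_modes
        vec = self.mean + self.scores[i, :k] @ self.eigenvectors[:k]
        return vec.reshape(self.n_points, 3)


def shape_pca(aligned: AlignedShapeSet) -> ShapePCA:
    """PCA of the aligned shapes, assuming equal variance for all points."""
    if aligned.n_shapes < 2:
        raise ValueError("need at least two shapes for PCA")
    X = aligned.vectors()
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = len(X)
    # keep the at most m-1 modes with non-trivial variance
    k = min(m - 1, Vt.shape[0])
    eigenvalues = (S[:k] ** 2) / (m - 1)
    scores = U[:, :k] * S[:k]
    return ShapePCA(mean, Vt[:k], eigenvalues, scores, aligned.n_points)


def pc_group_ttest(scores: np.ndarray, group_a, group_b,
                   welch: bool = False) -> float:
    """Two-sample t-test p for one PC's scores between two groups.

    ``group_a``/``group_b`` are boolean masks or index arrays into
    ``scores``.  Pooled-variance (classical) by default; Welch by flag.
    """
    a = np.asarray(scores)[np.asarray(group_a)]
    b = np.asarray(scores)[np.asarray(group_b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero within-group variance")
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def dominant_coding(codes: np.ndarray) -> np.ndarray:
    """Dominant genetic coding: wild-type homozygote and heterozygote 0,
    derived homozygote 1 (e.g. CC and CT -> 0, TT -> 1)."""
    return (np.asarray(codes) == 2).astype(float)


def additive_coding(codes: np.ndarray) -> np.ndarray:
    """Additive genetic coding: number of derived alleles 0, 1, 2."""
    return np.asarray(codes, dtype=float)


@dataclass
class GeneticModelFit:
    model: str
    slope: float
    intercept: float
    p_value: float                   # two-sided test of slope = 0
    r_squared: float                 # variance of the score explained
    n: int


def fit_genetic_model(scores: np.ndarray, codes: np.ndarray,
                      model: str = "dominant") -> GeneticModelFit:
    """Ordinary least squares of a shape score on coded genotypes.

    ``codes`` are derived-allele counts 0/1/2; the dominant model recodes
    them to {0, 1}, the additive model uses them as-is.  Reports the
    slope-test p-value and the variance explained (R^2).
    """
    scores = np.asarray(scores, dtype=float)
    codes = np.asarray(codes)
    if len(scores) != len(codes) or len(scores) < 3:
        raise ValueError("need matched scores/codes with n >= 3")
    if model == "dominant":
        x = dominant_coding(codes)
    elif model == "additive":
        x = additive_coding(codes)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    if np.ptp(x) == 0:
        raise ValueError("all genotype codes identical under this model")
    fit = stats.linregress(x, scores)
    return GeneticModelFit(model=model, slope=float(fit.slope),
                           intercept=float(fit.intercept),
                           p_value=float(fit.pvalue),
                           r_squared=float(fit.rvalue ** 2), n=len(scores))


@dataclass
class HyperlineModel:
    """The discriminant axis through two group mean shapes."""

    mean_g1: np.ndarray              # (3n,)
    mean_g2: np.ndarray              # (3n,)
    direction: np.ndarray            # unit vector from g1 mean to g2 mean
    midpoint: np.ndarray
    separation: float                # |mean_g2 - mean_g1|


def hyperline_model(mean_g1: np.ndarray, mean_g2: np.ndarray) -> HyperlineModel:
    g1 = np.asarray(mean_g1, dtype=float).reshape(-1)
    g2 = np.asarray(mean_g2, dtype=float).reshape(-1)
    diff = g2 - g1
    sep = float(np.linalg.norm(diff))
    if sep == 0:
        raise ValueError("group means are identical: hyperline undefined")
    return HyperlineModel(g1, g2, diff / sep, (g1 + g2) / 2.0, sep)


def hyperline_scores(shapes, mean_g1, mean_g2) -> np.ndarray:
    """Project flattened shapes onto the line through two group means.

    The origin sits at the midpoint of the two means, so the group means
    themselves map to -/+ half their mutual Euclidean distance.
    """
    hl = hyperline_model(mean_g1, mean_g2)
    X = np.asarray(shapes, dtype=float).reshape(-1, hl.direction.size)
    return (X - hl.midpoint) @ hl.direction


def transform_shape(pca: ShapePCA, mode: int, k_sd: float) -> np.ndarray:
    """Mean shape displaced k standard deviations along one PCA mode.

    s_t = s_m + k_sd * sigma_v * v, returned as an (n, 3) shape.
    """
    if not 0 <= mode < len(pca.eigenvalues):
        raise IndexError(f"mode {mode} out of range")
    sigma = np.sqrt(pca.eigenvalues[mode])
    if sigma <= 0:
        raise ValueError("mode has zero variance")
    vec = pca.mean + k_sd * sigma * pca.eigenvectors[mode]
    return vec.reshape(pca.n_points, 3)


def profile_line(shape: np.ndarray, half_width: float = 1.0) -> np.ndarray:
    """Mid-sagittal profile: points with |x| <= half_width, top to bottom.

    Assumes the shape is registered so the sagittal plane is x = 0 (true
    for template-registered faces).  Returns an ordered (k, 3) polyline
    sorted by descending y.
    """
    pts = np.asarray(shape, dtype=float).reshape(-1, 3)
    sel = np.abs(pts[:, 0]) <= half_width
    if not sel.any():
        raise ValueError("no points within the sagittal slab")
    band = pts[sel]
    return band[np.argsort(-band[:, 1])]
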
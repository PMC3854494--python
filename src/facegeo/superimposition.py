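"""Partial generalized Procrustes superimposition and the PPD statistic.

Partial GPA (PGPA) removes location and orientation differences between
corresponded point configurations while *retaining size*: each shape is
centred at its centroid and rotated onto the evolving mean by the optimal
proper rotation (SVD with determinant correction, so reflections are never
introduced), but no scaling step is applied.

The point-wise Procrustes distance (PPD) between two superimposed shapes
``s`` and ``s'`` is the root-mean-square point distance

    PPD = sqrt( (1/n) * sum_i d_i^2 ),   d_i^2 = |s_i - s'_i|^2,

i.e. the Procrustes distance normalised by the number of points, which
makes values comparable between sparse landmark data and dense
correspondence data of different n.  Units are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignedShapeSet",
    "partial_gpa",
    "optimal_rotation",
    "mean_shape",
    "ppd",
    "pointwise_signed_distances",
]


@dataclass
class AlignedShapeSet:
    """Shapes superimposed into one coordinate frame.

    ``shapes`` is an (m, n, 3) stack; every shape's centroid is at the
    origin, and ``mean`` is the per-point arithmetic mean shape.
    """

    shapes: np.ndarray                       # (m, n, 3)
    mean: np.ndarray                         # (n, 3)
    ids: list[str] = field(default_factory=list)
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if not self.ids:
            self.ids = [str(i) for i in range(len(self.shapes))]
        if len(self.ids) != len(self.shapes):
            raise ValueError("ids and shapes length mismatch")

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1]

    def vectors(self) -> np.ndarray:
        """(m, 3n) matrix of flattened shapes."""
        return self.shapes.reshape(self.n_shapes, -1)

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown individual id {e}") from None

    def subset(self, ids) -> "AlignedShapeSet":
        idx = self.index_of(ids)
        sub = self.shapes[idx]
        return AlignedShapeSet(sub, sub.mean(axis=0), [self.ids[i] for i in idx],
                               self.converged, self.iterations)


def optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising |shape @ R - target|_F.

    Both configurations must already be centred.  Solved by SVD of the
    cross-covariance with a determinant sign correction (Kabsch), so the
    result is always a rotation, never a reflection.
    """
    H = shape.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _center(shapes: np.ndarray) -> np.ndarray:
    return shapes - shapes.mean(axis=1, keepdims=True)


def partial_gpa(shapes, tol: float = 1e-8, max_iter: int = 100,
                ids=None, scale: bool = False) -> AlignedShapeSet:
    """Partial generalized Procrustes superimposition (no scaling).

    Parameters
    ----------
    shapes : sequence of (n, 3) arrays or an (m, n, 3) array
        Corresponded point configurations.
    tol : float
        Convergence threshold on the relative change of the mean shape.
    max_iter : int
        Iteration cap; non-convergence is flagged, not fatal.
    scale : bool
        If True, perform full GPA with unit-centroid-size scaling; the
        default (False) retains size, the behaviour used throughout.
    """
    X = np.stack([np.asarray(s, dtype=float) for s in shapes])
    m, n, _ = X.shape
    if m < 2:
        raise ValueError("need at least two shapes")
    if n < 3:
        raise ValueError("need at least three points per shape")
    X = _center(X)
    if scale:
        sizes = np.linalg.norm(X, axis=(1, 2), keepdims=True)
        X = X / np.maximum(sizes, 1e-300)
    rank = np.linalg.matrix_rank(X[0])
    if rank < 2:
        raise np.linalg.LinAlgError("degenerate shape: all points collinear")

    mean = X[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(m):
            X[j] = X[j] @ optimal_rotation(X[j], mean)
        new_mean = X.mean(axis=0)
        change = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-300)
        mean = new_mean
        if change < tol:
            converged = True
            break
    ids = list(ids) if ids is not None else [str(i) for i in range(m)]
    return AlignedShapeSet(X, mean, ids, converged, it)


def mean_shape(aligned: AlignedShapeSet, subset=None) -> np.ndarray:
    """Per-point arithmetic mean over a subset of individuals (by id)."""
    if subset is None:
        return aligned.shapes.mean(axis=0)
    idx = aligned.index_of(subset)
    if len(idx) == 0:
        raise ValueError("empty subset")
    return aligned.shapes[idx].mean(axis=0)


def ppd(s: np.ndarray, s_prime: np.ndarray) -> float:
    """Point-wise Procrustes distance between two superimposed shapes (mm)."""
    a = np.asarray(s, dtype=float).reshape(-1, 3)
    b = np.asarray(s_prime, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"shape length mismatch: {a.shape} vs {b.shape}")
    d2 = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def pointwise_signed_distances(ref_mean: np.ndarray, cmp_mean: np.ndarray,
                               normals: np.ndarray) -> np.ndarray:
    """Per-point signed distances between two mean shapes (mm).

    Magnitude is the Euclidean point distance; the sign is that of
    ``(ref - cmp) . normal``: positive where the reference face lies
    *outside* the compared face (along the outward normal), negative
    where it lies inside.  This is the quantity plotted as a cold/warm
    colour gradient over the face.
    """
    ref = np.asarray(ref_mean, dtype=float).reshape(-1, 3)
    cmp_ = np.asarray(cmp_mean, dtype=float).reshape(-1, 3)
    if normals is None:
        raise ValueError("outward normals are required for the sign convention")
    nrm = np.asarray(normals, dtype=float).reshape(-1, 3)
    if not (ref.shape == cmp_.shape == nrm.shape):
        raise ValueError("ref, cmp and normals must have matching shapes")
    diff = ref - cmp_
    mag = np.linalg.norm(diff, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", diff, nrm))
    sign[sign == 0] = 1.0
    out = mag * sign
    out[mag == 0] = 0.0
    return out
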
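"""Dense point-wise registration of 3D face surfaces.

A single reference face is resampled to an even point cloud, warped onto
each sample face with a landmark-driven thin-plate spline (TPS), and the
warped points are projected onto the sample surface.  Because every sample
is registered through the same reference, point *i* refers to approximately
the same anatomical position on every face, which is the correspondence
contract all downstream shape statistics rely on.

Coordinates are millimetres throughout, in a right-handed frame with +x to
the subject's anatomical left, +y up and +z anterior (out of the face).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LANDMARK_NAMES",
    "MOUTH_LANDMARKS",
    "FaceMesh",
    "ReferenceTemplate",
    "DenseShape",
    "ThinPlateSpline",
    "tps_warp",
    "resample_reference",
    "project_to_surface",
    "register_face",
    "LandmarkError",
    "SingularLandmarksError",
]

#: The 15 facial landmarks used to drive registration, in canonical order:
#: eye canthi, nose (pronasale, nasion, alare, subnasale), lip corners,
#: stomion, upper/lower lip points and the chin point.
LANDMARK_NAMES: tuple[str, ...] = (
    "LExtCan", "LIntCan", "RIntCan", "RExtCan",
    "Prn", "Nsn", "LAla", "RAla", "Sbn",
    "RLipCn", "LLipCn", "Stm", "ULipP", "LLipP", "ChiP",
)

#: The five landmarks delimiting the mouth (lip corners, upper/lower lip
#: points and stomion); used for mouth-region analyses.
MOUTH_LANDMARKS: tuple[str, ...] = ("LLipCn", "RLipCn", "ULipP", "Stm", "LLipP")


class LandmarkError(ValueError):
    """A required landmark is missing, duplicated or unknown."""


class SingularLandmarksError(np.linalg.LinAlgError):
    """Landmark configuration makes the TPS system numerically singular."""


@dataclass
class FaceMesh:
    """Triangulated face surface with named anatomical landmarks (mm)."""

    vertices: np.ndarray          # (v, 3) float
    faces: np.ndarray             # (f, 3) int vertex indices
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident triangle normals, unit length."""
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        fn = np.cross(b - a, c - a)  # area-weighted (length = 2*area)
        vn = np.zeros_like(self.vertices)
        for i in range(3):
            np.add.at(vn, self.faces[:, i], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norm, 1e-300)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def with_vertices(self, vertices: np.ndarray, landmarks: dict | None = None) -> "FaceMesh":
        """Same topology, new vertex positions (and optionally landmarks)."""
        return FaceMesh(np.asarray(vertices, dtype=float), self.faces,
                        landmarks if landmarks is not None else dict(self.landmarks))

    def landmark_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = tuple(names) if names is not None else tuple(self.landmarks)
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise LandmarkError(f"missing landmarks: {missing}")
        return np.stack([self.landmarks[n] for n in names])


@dataclass
class ReferenceTemplate:
    """Resampled reference face: the dense-correspondence index.

    The *order* of ``points`` is the correspondence contract — index ``i``
    on every registered face refers to the same reference point.
    """

    points: np.ndarray            # (n, 3)
    normals: np.ndarray           # (n, 3) outward unit normals
    landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.points.shape != self.normals.shape:
            raise ValueError("points and normals must have matching shapes")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @classmethod
    def from_mesh_vertices(cls, mesh: FaceMesh) -> "ReferenceTemplate":
        """Use the mesh's own vertices (with vertex normals) as the index."""
        return cls(mesh.vertices.copy(), mesh.vertex_normals(), dict(mesh.landmarks))


@dataclass
class DenseShape:
    """One individual's registered face: n corresponded 3D points (mm)."""

    points: np.ndarray            # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def vector(self) -> np.ndarray:
        """Flattened representation [x1, y1, z1, ..., xn, yn, zn]."""
        return self.points.reshape(-1)


class ThinPlateSpline:
    """3D thin-plate spline interpolant with kernel U(r) = r.

    Solves the exact-interpolation system (no smoothing): a radial part
    with coefficients orthogonal to the affine space, plus a full affine
    term, so translations and general affine maps are reproduced exactly.
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray):
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
            raise ValueError("src and dst must be matching (k, 3) arrays")
        k = len(src)
        if k < 5:
            raise ValueError("need at least 5 landmarks for a 3D TPS")
        K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
        P = np.hstack([np.ones((k, 1)), src])
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = dst
        cond = np.linalg.cond(L)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularLandmarksError(
                "TPS system is singular or ill-conditioned "
                f"(cond={cond:.2e}); landmarks are likely coplanar or duplicated"
            )
        coeffs = np.linalg.solve(L, rhs)
        self.src = src
        self.w = coeffs[:k]        # radial coefficients, (k, 3)
        self.a = coeffs[k:]        # affine coefficients, (4, 3)

    def __call__(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float))
        U = np.linalg.norm(q[:, None, :] - self.src[None, :, :], axis=2)
        out = U @ self.w + np.hstack([np.ones((len(q), 1)), q]) @ self.a
        return out.reshape(np.shape(query))


def tps_warp(src_landmarks: np.ndarray, dst_landmarks: np.ndarray,
             query_points: np.ndarray) -> np.ndarray:
    """Warp ``query_points`` by the TPS mapping src landmarks onto dst."""
    return ThinPlateSpline(src_landmarks, dst_landmarks)(query_points)


def resample_reference(mesh: FaceMesh, density: float = 1.0,
                       count: int | None = None, seed: int = 0) -> ReferenceTemplate:
    """Resample a reference mesh to an even point distribution.

    Points are drawn by area-weighted uniform sampling of the triangles;
    the expected count is ``area * density`` (points per mm^2) unless an
    explicit ``count`` is given.  Per-point normals come from the
    supporting triangle.  Deterministic for a fixed seed.
    """
    areas = mesh.triangle_areas()
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero total area")
    if count is None:
        if density <= 0:
            raise ValueError("density must be positive")
        count = max(1, int(round(total * density)))
    rng = np.random.default_rng(seed)
    tri = rng.choice(len(areas), size=count, p=areas / total)
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    a = mesh.vertices[mesh.faces[tri, 0]]
    b = mesh.vertices[mesh.faces[tri, 1]]
    c = mesh.vertices[mesh.faces[tri, 2]]
    pts = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c
    normals = mesh.face_normals()[tri]
    return ReferenceTemplate(pts, normals, dict(mesh.landmarks))


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                          c: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c); all (m, 3)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                                   # vertex a
    settle((d3 >= 0) & (d4 <= d3), b)                                  # vertex b
    settle((d6 >= 0) & (d5 <= d6), c)                                  # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))                                # edge bc
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v = vb / denom
    w = vc / denom
    settle(np.ones(len(a), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


def project_to_surface(points: np.ndarray, target: FaceMesh,
                       n_candidates: int = 32) -> np.ndarray:
    """Project each point to its globally closest point on the surface.

    Candidate triangles are pre-selected with KD-trees on triangle
    centroids and on mesh vertices (faces incident to the nearest
    vertices are always candidates, which covers elongated boundary
    triangles whose centroids lie far from their corners); the exact
    point-triangle distance is then minimised over the candidates.  With
    ``n_candidates >= number of faces`` this is an exhaustive search.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(target.faces) == 0:
        raise ValueError("target mesh has no faces")
    tris = target.vertices[target.faces]             # (f, 3, 3)
    centroids = tris.mean(axis=1)
    nf = len(centroids)
    k = min(n_candidates, nf)
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = cand.reshape(len(points), -1)
    if k < nf:
        # faces incident to the nearest vertices
        kv = min(4, len(target.vertices))
        _, near_v = cKDTree(target.vertices).query(points, k=kv)
        near_v = near_v.reshape(len(points), -1)
        incidence: dict[int, list[int]] = {}
        for fi, tri in enumerate(target.faces):
            for v in tri:
                incidence.setdefault(int(v), []).append(fi)
        extra = [sorted({fi for v in row for fi in incidence.get(int(v), ())})
                 for row in near_v]
        width = max(len(e) for e in extra)
        merged = np.empty((len(points), k + width), dtype=np.int64)
        merged[:, :k] = cand
        for i, e in enumerate(extra):
            pad = e + [e[-1]] * (width - len(e)) if e else [cand[i, 0]] * width
            merged[i, k:] = pad
        cand = merged
    kk = cand.shape[1]
    npts = len(points)
    rep = np.repeat(points, kk, axis=0)
    flat = cand.reshape(-1)
    closest = _closest_on_triangles(rep, tris[flat, 0], tris[flat, 1], tris[flat, 2])
    d2 = ((closest - rep) ** 2).sum(axis=1).reshape(npts, kk)
    best = d2.argmin(axis=1)
    return closest.reshape(npts, kk, 3)[np.arange(npts), best]


def register_face(reference: ReferenceTemplate, sample: FaceMesh,
                  landmark_names: tuple[str, ...] = LANDMARK_NAMES,
                  drop_landmarks: tuple[str, ...] = ()) -> DenseShape:
    """Register one sample face against the reference template.

    TPS-warps the reference points onto the sample using the shared
    landmarks, then projects each warped point to the closest point on the
    sample surface.  ``drop_landmarks`` supports sensitivity analyses in
    which a landmark (e.g. stomion) is withheld from the warp.
    """
    names = tuple(n for n in landmark_names if n not in set(drop_landmarks))
    missing = sorted(set(names) - set(sample.landmarks)) + \
        sorted(set(names) - set(reference.landmarks))
    if missing:
        raise LandmarkError(f"sample/reference missing landmarks: {sorted(set(missing))}")
    src = np.stack([reference.landmarks[n] for n in names])
    dst = np.stack([sample.landmarks[n] for n in names])
    warped = tps_warp(src, dst, reference.points)
    projected = project_to_surface(warped, sample)
    return DenseShape(projected)
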
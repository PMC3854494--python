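"""File formats: ASCII OBJ/PLY meshes, landmark/genotype TSVs, shape TSVs.

Meshes go through trimesh; tabular data through pandas.  Dense shapes are
stored as a TSV of n rows (x, y, z) with a comment header carrying the
reference ID and point count, so they stay human-readable and diffable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registration import DenseShape, FaceMesh

__all__ = [
    "save_mesh", "load_mesh",
    "save_landmarks", "load_landmarks",
    "save_dense_shape", "load_dense_shape",
    "save_genotype_table", "load_genotype_table",
    "save_scalar_map",
    "load_yaml_config",
]


def save_mesh(mesh: FaceMesh, path) -> None:
    """Write a mesh as ASCII OBJ or PLY (by extension)."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    elif path.suffix.lower() == ".obj":
        path.write_text(tm.export(file_type="obj"))
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use .obj or .ply)")


def load_mesh(path, landmarks_path=None) -> FaceMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False, force="mesh")
    lms = load_landmarks(landmarks_path) if landmarks_path else {}
    return FaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), lms)


def save_landmarks(landmarks: dict[str, np.ndarray], path) -> None:
    rows = [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in landmarks.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_landmarks(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {r["name"]: np.array([r.x, r.y, r.z], dtype=float)
            for _, r in df.iterrows()}


def save_dense_shape(shape: DenseShape, path, reference_id: str = "") -> None:
    header = f"# reference={reference_id} n={shape.n_points}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, shape.points, fmt="%.6f", delimiter="\t")


def load_dense_shape(path) -> DenseShape:
    return DenseShape(np.loadtxt(path, delimiter="\t", comments="#"))


def save_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_genotype_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_scalar_map(values: np.ndarray, path, name: str = "signed_distance_mm") -> None:
    """Per-point scalar map (e.g. signed distances) as a one-column TSV."""
    pd.DataFrame({name: np.asarray(values, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
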
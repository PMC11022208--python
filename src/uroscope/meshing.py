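"""Surface meshing: binary label map -> smoothed triangle mesh.

The binary collecting-system mask is smoothed with a small Gaussian kernel
(default σ = 0.8 voxels) and the 0.5 iso-surface of the smoothed field is
triangulated with marching cubes.  Vertices are returned in physical mm,
ordered (z, y, x) like the volumes, so downstream skeleton distances and
camera poses are metric.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volumes import LabelMap, Volume

__all__ = [
    "TriangleMesh",
    "smooth_binary",
    "marching_cubes",
    "read_mesh",
    "write_mesh",
]


@dataclasses.dataclass
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            if (np.diff(np.sort(self.faces, axis=1), axis=1) == 0).any():
                raise ValueError("degenerate face (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def is_closed_manifold(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        return bool((counts == 2).all())

    def area(self) -> float:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def smooth_binary(mask: LabelMap, sigma_vox: float = 0.8) -> Volume:
    """Gaussian-smooth a binary mask into a [0, 1] occupancy field.

    Reflective boundaries keep a full mask at 1.0 up to the volume edge, so
    no spurious surface appears at the bounding box.
    """
    if sigma_vox <= 0:
        raise ValueError(f"sigma_vox must be > 0, got {sigma_vox}")
    arr = np.asarray(mask.data)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("smooth_binary expects a binary mask")
    out = ndimage.gaussian_filter(arr.astype(np.float64), sigma=sigma_vox, mode="reflect")
    return Volume(np.clip(out, 0.0, 1.0), mask.spacing, mask.origin)


def marching_cubes(field: Volume, iso: float = 0.5, step_size: int = 1) -> TriangleMesh:
    """Triangulate the ``iso`` level set of a scalar field.

    Vertices are in physical mm, (z, y, x) order, offset by the field
    origin.  ``step_size > 1`` coarsens the marching grid (fewer faces).
    Raises when the field never crosses the iso level (empty surface).
    """
    data = np.asarray(field.data, dtype=np.float64)
    if not (data.min() < iso < data.max()):
        raise ValueError(
            f"field range [{data.min():.4g}, {data.max():.4g}] does not straddle "
            f"iso level {iso}: empty surface")
    verts, faces, normals, _ = measure.marching_cubes(
        data, level=iso, spacing=field.spacing, step_size=step_size)
    verts = verts + np.asarray(field.origin)
    return TriangleMesh(verts, faces, normals)


_EXTS = {".ply", ".obj"}


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write PLY (binary little-endian) or OBJ, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() not in _EXTS:
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .ply or .obj)")
    tm = mesh.to_trimesh()
    tm.export(str(path))


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a PLY/OBJ mesh without silent repair or vertex merging."""
    path = Path(path)
    if path.suffix.lower() not in _EXTS:
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .ply or .obj)")
    if not path.exists():
        raise FileNotFoundError(str(path))
    tm = trimesh.load(str(path), process=False, maintain_order=True)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
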
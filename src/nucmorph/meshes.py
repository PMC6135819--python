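"""Triangle-mesh container and validity checks.

Meshes produced by the reconstruction stage are closed, oriented, genus-zero
2-manifolds embedded in physical coordinates: every edge is shared by
exactly two faces, the Euler characteristic V - E + F equals 2, and the
winding is outward (positive signed volume).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) float points (x, y, z, in
    physical units) and ``faces`` (m, 3) vertex-index triplets with
    consistent outward orientation."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.vertices, dtype=float)
        f = np.ascontiguousarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {f.shape}")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return len(np.unique(e, axis=0))

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(),
                               process=False)

    @property
    def is_closed_manifold(self) -> bool:
        tm = self.as_trimesh()
        return bool(tm.is_watertight and tm.is_winding_consistent)

    def signed_volume(self) -> float:
        """Signed enclosed volume by summing signed (origin, triangle) tetrahedra."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    def area(self) -> float:
        tri = self.vertices[self.faces]
        return float(0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())

    def mean_edge_length(self) -> float:
        e = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        e = np.unique(np.sort(e, axis=1), axis=0)
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                                    axis=1).mean())

    def validate(self) -> None:
        """Raise ``ValueError`` unless the mesh is a closed, genus-zero,
        outward-oriented 2-manifold with no degenerate faces."""
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise ValueError("mesh is not closed (some edge not shared by exactly 2 faces)")
        if not tm.is_winding_consistent:
            raise ValueError("mesh winding is inconsistent")
        if self.euler_characteristic != 2:
            raise ValueError(
                f"mesh is not genus zero: Euler characteristic {self.euler_characteristic}"
            )
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]),
                                     axis=1)
        scale = self.mean_edge_length() ** 2
        if (areas < 1e-12 * scale).any():
            raise ValueError("mesh contains zero-area faces")
        if self.signed_volume() <= 0:
            raise ValueError("mesh winding is inward (non-positive signed volume)")

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(vertices, self.faces)

    def save(self, path: str | Path) -> Path:
        """Export as ASCII PLY or OFF, by file extension."""
        path = Path(path)
        ext = path.suffix.lower().lstrip(".")
        if ext not in ("ply", "off"):
            raise ValueError(f"unsupported mesh format {ext!r}; use .ply or .off")
        path.parent.mkdir(parents=True, exist_ok=True)
        data = trimesh.exchange.export.export_mesh(
            self.as_trimesh(), None, file_type=ext,
            **({"encoding": "ascii"} if ext == "ply" else {}),
        )
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
        return path


def load_mesh(path: str | Path) -> TriangleMesh:
    tm = trimesh.load_mesh(Path(path), process=False)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
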
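"""Labeled triangulated surface meshes.

The pipeline's central geometric container: a triangle soup with named,
disjoint face-label sets (chamber wall, appendage wall, device, inlet and
outlet caps), optional named polylines (the ostium contour) and landmark
points (LSPV endpoint, MV centre).  Lengths are millimetres throughout.

Backed by :mod:`trimesh` for area/normal/proximity computations; written to
disk as binary-free STL or legacy-ASCII VTK PolyData with the labels as a
cell array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ConfigurationError, GeometryError

__all__ = ["LabeledSurfaceMesh", "write_vtk_polydata"]


@dataclass
class LabeledSurfaceMesh:
    """Triangulated surface with disjoint named face regions.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array
    labels : mapping of region name to face-index array; regions must be
        pairwise disjoint.
    polylines : named closed/open polylines (k, 3), mm (e.g. ``ostium_contour``).
    points : named landmark points (3,), mm (e.g. ``lspv_endpoint``).
    metadata : free-form provenance (generator spec, device pose, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    polylines: dict[str, np.ndarray] = field(default_factory=dict)
    points: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3) triangles")
        self.labels = {k: np.asarray(v, dtype=np.int64) for k, v in self.labels.items()}
        seen: set[int] = set()
        for name, idx in self.labels.items():
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise GeometryError(f"label {name!r} overlaps another region")
            seen.update(idx.tolist())

    # ------------------------------------------------------------------ basic
    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self, label: str | None = None) -> trimesh.Trimesh:
        """Whole surface, or a single labeled region, as a ``trimesh.Trimesh``."""
        if label is None:
            faces = self.faces
        else:
            faces = self.faces[self.label_faces(label)]
        return trimesh.Trimesh(vertices=self.vertices, faces=faces, process=False)

    def label_faces(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise ConfigurationError(f"mesh has no label {label!r}; present: {sorted(self.labels)}")
        return self.labels[label]

    def label_of(self, face_index: int) -> str | None:
        for name, idx in self.labels.items():
            if face_index in idx:
                return name
        return None

    def face_centroids(self, label: str | None = None) -> np.ndarray:
        tri = self.vertices[self.faces if label is None else self.faces[self.label_faces(label)]]
        return tri.mean(axis=1)

    def face_normals(self, label: str | None = None) -> np.ndarray:
        tri = self.vertices[self.faces if label is None else self.faces[self.label_faces(label)]]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self, label: str | None = None) -> np.ndarray:
        tri = self.vertices[self.faces if label is None else self.faces[self.label_faces(label)]]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def area(self, label: str | None = None) -> float:
        return float(self.face_areas(label).sum())

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # ------------------------------------------------------------------ merge
    def merged_with(self, other: "LabeledSurfaceMesh", prefix: str = "") -> "LabeledSurfaceMesh":
        """Concatenate another labeled surface (e.g. a deployed device)."""
        off_v = len(self.vertices)
        off_f = len(self.faces)
        vertices = np.vstack([self.vertices, other.vertices])
        faces = np.vstack([self.faces, other.faces + off_v])
        labels = {k: v.copy() for k, v in self.labels.items()}
        for k, v in other.labels.items():
            labels[prefix + k] = v + off_f
        poly = dict(self.polylines)
        poly.update(other.polylines)
        pts = dict(self.points)
        pts.update(other.points)
        meta = dict(self.metadata)
        meta.update(other.metadata)
        return LabeledSurfaceMesh(vertices, faces, labels, poly, pts, meta)

    # --------------------------------------------------------------------- io
    def write_stl(self, path: str | Path) -> None:
        self.as_trimesh().export(str(path), file_type="stl_ascii")

    def write_vtk(self, path: str | Path) -> None:
        """Legacy-ASCII VTK PolyData with an integer ``region`` cell array."""
        region = np.zeros(self.n_faces, dtype=np.int64)
        key = {}
        for i, (name, idx) in enumerate(sorted(self.labels.items()), start=1):
            region[idx] = i
            key[name] = i
        write_vtk_polydata(path, self.vertices, self.faces, {"region": region})
        Path(str(path) + ".labels.json").write_text(json.dumps(key, indent=1))


def write_vtk_polydata(
    path: str | Path,
    vertices: np.ndarray,
    faces: np.ndarray,
    cell_arrays: dict[str, np.ndarray] | None = None,
    point_arrays: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal legacy-ASCII VTK PolyData writer (points, triangles, data arrays)."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "laao_dpm surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} double",
    ]
    lines += [" ".join(f"{c:.9g}" for c in v) for v in vertices]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]

    def _emit(kind: str, arrays: dict[str, np.ndarray], n: int) -> None:
        lines.append(f"{kind} {n}")
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                lines.append(f"SCALARS {name} {dtype} 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" if dtype == "double" else str(int(v))
                             for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{c:.9g}" for c in v) for v in arr)

    if cell_arrays:
        _emit("CELL_DATA", cell_arrays, len(faces))
    if point_arrays:
        _emit("POINT_DATA", point_arrays, len(vertices))
    Path(path).write_text("\n".join(lines) + "\n")
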
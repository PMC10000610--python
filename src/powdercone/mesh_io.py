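"""Reading, validating and writing triangulated surface meshes.

The pipeline consumes a lateral cone surface as a plain triangle soup:
an ``(n, 3)`` float array of vertices and an ``(m, 3)`` integer array of
faces.  OBJ, PLY and STL are supported through :mod:`trimesh`.  STL
stores three independent vertices per facet, so on load coincident
vertices are merged (tolerance 1e-8 distance units) to recover a
connected surface -- plane-intersection chaining relies on shared edges.
Coordinates are kept in whatever distance units the file uses; no
rescaling is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = ["TriangleMesh", "MeshFormatError", "MeshValidationError", "load_mesh", "save_mesh"]

_FORMATS = ("obj", "ply", "stl")

#: vertices closer than this (distance units) are considered coincident
MERGE_TOL = 1e-8


class MeshFormatError(ValueError):
    """Unknown or unsupported mesh file format."""


class MeshValidationError(ValueError):
    """Mesh violates a structural invariant (indices, degeneracy, extent)."""


@dataclass
class TriangleMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices
        ``(n, 3)`` array of xyz coordinates in arbitrary distance units.
    faces
        ``(m, 3)`` array of 0-based vertex indices, one row per triangle.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def z_range(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def validate(self) -> "TriangleMesh":
        """Check all invariants, raising :class:`MeshValidationError` on failure.

        Invariants: at least one vertex and face, every face index in
        range, no collinear (zero-area) triangle, positive vertical
        extent.  Returns ``self`` so calls can be chained.
        """
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshValidationError("mesh is empty")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshValidationError(
                f"face index out of range (have {self.n_vertices} vertices, "
                f"max index {self.faces.max()})"
            )
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        scale = np.abs(tri).max() or 1.0
        if np.any(area2 <= 1e-14 * scale * scale):
            bad = int(np.argmax(area2 <= 1e-14 * scale * scale))
            raise MeshValidationError(f"degenerate (collinear) face at index {bad}")
        z_min, z_max = self.z_range
        if not z_max > z_min:
            raise MeshValidationError("mesh has no vertical extent (z_max == z_min)")
        return self


def _detect_format(path: str, format: str | None) -> str:
    if format is not None:
        fmt = format.lower().lstrip(".")
    else:
        fmt = os.path.splitext(path)[1].lower().lstrip(".")
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def _merge_close_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float):
    """Merge vertices closer than ``tol`` by snapping to a grid of spacing ``tol``."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    remapped = inverse[faces]
    # drop faces collapsed by merging
    ok = (
        (remapped[:, 0] != remapped[:, 1])
        & (remapped[:, 1] != remapped[:, 2])
        & (remapped[:, 2] != remapped[:, 0])
    )
    return merged, remapped[ok]


def load_mesh(path: str, format: str | None = None) -> TriangleMesh:
    """Load a triangle mesh from OBJ, PLY or STL.

    The format is taken from ``format`` or the file extension.  Vertex
    order is preserved for OBJ and PLY; STL facets are welded into a
    connected surface by merging vertices within :data:`MERGE_TOL`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MeshFormatError
        If the format is not OBJ/PLY/STL.
    MeshValidationError
        If the parsed mesh violates an invariant (e.g. a face index
        beyond the vertex count, or an empty mesh).
    """
    fmt = _detect_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = trimesh.load(path, file_type=fmt, process=False, maintain_order=True)
    except MemoryError:
        raise
    except Exception as exc:  # trimesh raises a mixture of types
        raise MeshValidationError(f"could not parse {path!r} as {fmt}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshValidationError(f"{path!r} contains no geometry")
        raw = geoms[0]
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if faces.size and vertices.size and faces.max() >= len(vertices):
        raise MeshValidationError("face index out of range")
    if fmt == "stl" and len(vertices):
        vertices, faces = _merge_close_vertices(vertices, faces, MERGE_TOL)
    return TriangleMesh(vertices, faces).validate()


def save_mesh(mesh: TriangleMesh, path: str, format: str | None = None) -> None:
    """Write ``mesh`` to ``path`` in OBJ, ASCII PLY or binary STL.

    The written file round-trips through :func:`load_mesh` preserving
    face count exactly and coordinates to the format's write precision.
    """
    fmt = _detect_format(path, format)
    mesh.validate()
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type=fmt)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
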
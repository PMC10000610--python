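"""Horizontal plane slicing of cone meshes into closed boundary contours.

A mesh is cut at equally spaced interior altitudes; each cut produces
one line segment per crossing triangle, and the segments are chained
into closed loops through the mesh's shared edges.  Each intersection
point is computed once per unique mesh edge, so chaining is exact and
independent of face winding.  When a cut yields several loops (an
overhanging lump can pinch off a small satellite loop) only the
largest-area loop is kept, and every returned loop is normalised to
counterclockwise orientation so the angular unwrapping direction is
consistent across layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_io import TriangleMesh

__all__ = ["ContourSlice", "SliceError", "slice_heights", "extract_contour", "slice_mesh"]

#: consecutive contour points closer than this are collapsed
_POINT_TOL = 1e-9


class SliceError(ValueError):
    """Slicing failed: altitude out of range or no closed loop found."""


@dataclass
class ContourSlice:
    """Closed boundary polyline of one horizontal cut.

    ``points`` is an ordered ``(n, 2)`` array of (x, y) vertices; the
    last point connects implicitly back to the first.  Orientation is
    counterclockwise (positive signed area).
    """

    layer_index: int
    z: float
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        """Shoelace signed area of the closed polygon."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def slice_heights(mesh: TriangleMesh, n_layers: int) -> np.ndarray:
    """Equally spaced interior slicing altitudes, bottom to top.

    Altitudes are ``z_min + i*(z_max - z_min)/(n_layers + 1)`` for
    ``i = 1..n_layers``: strictly inside the z range, because the base
    and apex planes give degenerate or empty cuts.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    z_min, z_max = mesh.z_range
    if not z_max > z_min:
        raise SliceError("mesh is flat: z_max == z_min")
    i = np.arange(1, n_layers + 1, dtype=np.float64)
    return z_min + i * (z_max - z_min) / (n_layers + 1)


def _cross_section_segments(mesh: TriangleMesh, z: float):
    """Intersection segments of the plane at altitude ``z``.

    Returns ``(points, segments)``: unique intersection points, one per
    crossing mesh edge, and ``(s, 2)`` indices into them, one segment
    per crossing face.  Identifying points by their (sorted) edge makes
    endpoint matching exact.
    """
    vz = mesh.vertices[:, 2]
    d = vz - z
    if np.any(d == 0.0):
        # nudge the plane off coincident vertices; geometrically negligible
        z_min, z_max = mesh.z_range
        z = z + 1e-9 * (z_max - z_min)
        d = vz - z
    faces = mesh.faces
    df = d[faces]  # (m, 3)
    crossing = (df.min(axis=1) < 0.0) & (df.max(axis=1) > 0.0)
    faces = faces[crossing]
    df = df[crossing]
    if len(faces) == 0:
        return np.empty((0, 2)), np.empty((0, 2), dtype=np.int64)

    # per crossing face, the two edges whose endpoints straddle the plane
    edge_pairs = []
    for a, b in ((0, 1), (1, 2), (2, 0)):
        hit = df[:, a] * df[:, b] < 0.0
        e = np.sort(faces[:, (a, b)], axis=1)
        edge_pairs.append((hit, e))
    # stack into (m, 2) crossing-edge ids per face
    face_edges = np.full((len(faces), 2, 2), -1, dtype=np.int64)
    count = np.zeros(len(faces), dtype=np.int64)
    for hit, e in edge_pairs:
        idx = np.flatnonzero(hit)
        slot = count[idx]
        face_edges[idx, slot] = e[idx]
        count[idx] += 1
    assert np.all(count == 2)

    all_edges = face_edges.reshape(-1, 2)
    uniq_edges, inverse = np.unique(all_edges, axis=0, return_inverse=True)
    segments = inverse.reshape(-1, 2)

    vi = mesh.vertices[uniq_edges[:, 0]]
    vj = mesh.vertices[uniq_edges[:, 1]]
    di = d[uniq_edges[:, 0]]
    dj = d[uniq_edges[:, 1]]
    t = (di / (di - dj))[:, None]
    points = (vi + t * (vj - vi))[:, :2]
    return points, segments


def _chain_loops(segments: np.ndarray) -> list[list[int]]:
    """Chain segments (pairs of point ids) into closed loops."""
    neighbours: dict[int, list[int]] = {}
    for a, b in segments:
        neighbours.setdefault(int(a), []).append(int(b))
        neighbours.setdefault(int(b), []).append(int(a))
    visited: set[int] = set()
    loops = []
    for start in neighbours:
        if start in visited or len(neighbours[start]) != 2:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = start, neighbours[start][0]
        while cur != start:
            if cur in visited or len(neighbours[cur]) != 2:
                loop = None  # open or non-manifold chain
                break
            loop.append(cur)
            visited.add(cur)
            nxt = neighbours[cur][0] if neighbours[cur][0] != prev else neighbours[cur][1]
            prev, cur = cur, nxt
        if loop is not None and len(loop) >= 3:
            loops.append(loop)
    return loops


def extract_contour(mesh: TriangleMesh, z: float, layer_index: int = 0) -> ContourSlice:
    """Boundary contour of the mesh cut at altitude ``z``.

    Raises :class:`SliceError` if ``z`` is outside the mesh's open z
    interval or no closed loop exists at that altitude.  Of several
    loops, the one with the largest absolute signed area is returned,
    oriented counterclockwise.
    """
    z_min, z_max = mesh.z_range
    if not z_min < z < z_max:
        raise SliceError(f"altitude {z} outside the mesh z range ({z_min}, {z_max})")
    points, segments = _cross_section_segments(mesh, z)
    loops = _chain_loops(segments)
    if not loops:
        raise SliceError(f"no closed contour at altitude {z}")
    polys = [points[loop] for loop in loops]

    def shoelace(p: np.ndarray) -> float:
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    areas = [shoelace(p) for p in polys]
    best = int(np.argmax(np.abs(areas)))
    poly = polys[best]
    if areas[best] < 0.0:
        poly = poly[::-1]
    # collapse consecutive near-duplicate points (closed polyline)
    keep = np.linalg.norm(poly - np.roll(poly, 1, axis=0), axis=1) > _POINT_TOL
    poly = poly[keep]
    if len(poly) < 3:
        raise SliceError(f"degenerate contour at altitude {z}")
    return ContourSlice(layer_index=layer_index, z=float(z), points=poly)


def slice_mesh(mesh: TriangleMesh, n_layers: int = 40) -> list[ContourSlice | None]:
    """Slice at :func:`slice_heights` altitudes, bottom to top.

    Layers where no closed contour exists are returned as ``None``
    rather than fabricated.  Raises :class:`SliceError` only if every
    layer fails.
    """
    mesh.validate()
    slices: list[ContourSlice | None] = []
    for i, z in enumerate(slice_heights(mesh, n_layers)):
        try:
            slices.append(extract_contour(mesh, z, layer_index=i))
        except SliceError:
            slices.append(None)
    if all(s is None for s in slices):
        raise SliceError("no layer produced a closed contour")
    return slices
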
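"""Watertight triangle meshes: representation, I/O, validation, ray queries.

A :class:`TriangleMesh` is the boundary of a solid region of space, in the
right-handed PDB coordinate frame with Ångström units. Triangle corners are
enumerated counterclockwise when viewed from outside the solid, so the
cross-product normal of every face points outward. Point-in-solid queries use
the parity of ray/surface crossings: a point is inside exactly when a generic
ray from it crosses the boundary an odd number of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import GrazingRayError, MeshFormatError, OpenMeshError

__all__ = [
    "TriangleMesh",
    "ValidationReport",
    "load_mesh",
    "write_mesh",
    "validate",
    "ray_parity",
    "point_in_solid",
    "split_components",
]


@dataclass
class TriangleMesh:
    """Triangle boundary mesh of a solid region (coordinates in Å)."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) integer indices, CCW from outside

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic geometry -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) corners of the axis-aligned bbox."""
        if self.n_vertices == 0:
            raise ValueError("empty mesh has no bounds")
        used = self.vertices[np.unique(self.faces)] if self.n_faces else self.vertices
        return np.array([used.min(axis=0), used.max(axis=0)])

    def triangle_corners(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def triangle_areas(self) -> np.ndarray:
        t = self.triangle_corners()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    @property
    def area(self) -> float:
        """Total surface area in Å²."""
        return float(self.triangle_areas().sum()) if self.n_faces else 0.0

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, matrix: np.ndarray) -> "TriangleMesh":
        """Apply a 4x4 rigid (or affine) transform; returns a new mesh."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 transform")
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return TriangleMesh(v, self.faces.copy())

    def flipped(self) -> "TriangleMesh":
        """Reverse winding (turns the solid inside out)."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())

    @staticmethod
    def empty() -> "TriangleMesh":
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))


@dataclass
class ValidationReport:
    """Summary of watertightness and orientation checks for a mesh."""

    is_closed: bool
    is_consistently_oriented: bool
    boundary_edge_count: int
    component_count: int
    total_area: float  # Å²

    def __iter__(self):  # convenient field-for-field comparison in tests
        yield from (
            self.is_closed,
            self.is_consistently_oriented,
            self.boundary_edge_count,
            self.component_count,
            round(self.total_area, 9),
        )


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )


def validate(mesh: TriangleMesh) -> ValidationReport:
    """Check closedness, orientation consistency, components and area.

    A mesh is closed when every undirected edge is shared by exactly two
    triangles; it is consistently oriented when the two triangles sharing an
    edge traverse it in opposite directions (i.e. no directed edge repeats).
    """
    if mesh.is_empty:
        return ValidationReport(True, True, 0, 0, 0.0)
    de = _directed_edges(mesh.faces)
    und = np.sort(de, axis=1)
    _, und_counts = np.unique(und, axis=0, return_counts=True)
    boundary = int((und_counts == 1).sum())
    closed = bool(np.all(und_counts == 2))
    _, de_counts = np.unique(de, axis=0, return_counts=True)
    oriented = bool(np.all(de_counts == 1))

    used = np.unique(mesh.faces)
    remap = np.zeros(used.max() + 1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    e = remap[und]
    g = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(used), len(used))
    )
    n_comp, _ = connected_components(g, directed=False)
    return ValidationReport(closed, oriented, boundary, int(n_comp), mesh.area)


def is_closed(mesh: TriangleMesh) -> bool:
    """Fast region-boundary check: the boundary operator vanishes.

    Every directed edge must be cancelled by its reverse. This is the exact
    precondition for crossing-parity membership and the Surveyor's Formula.
    It is slightly weaker than 2-manifoldness: a surface may legitimately
    pinch along an edge (count 4, balanced) where a boolean result is
    tangent to itself; :func:`validate` still reports such edges as
    non-manifold (``is_closed`` False in the strict sense).
    """
    if mesh.is_empty:
        return True
    de = _directed_edges(mesh.faces)
    fwd, fwd_counts = np.unique(de, axis=0, return_counts=True)
    rev, rev_counts = np.unique(de[:, ::-1], axis=0, return_counts=True)
    if len(fwd) != len(rev):
        return False
    return bool(np.array_equal(fwd, rev) and np.array_equal(fwd_counts, rev_counts))


def split_components(mesh: TriangleMesh) -> list[TriangleMesh]:
    """Split a mesh into vertex-connected components (each with its own faces)."""
    if mesh.is_empty:
        return []
    und = np.sort(_directed_edges(mesh.faces), axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.ones(len(und)), (und[:, 0], und[:, 1])), shape=(n, n))
    _, labels = connected_components(g, directed=False)
    out = []
    for comp in np.unique(labels[mesh.faces[:, 0]]):
        fsel = mesh.faces[labels[mesh.faces[:, 0]] == comp]
        used = np.unique(fsel)
        remap = np.zeros(n, dtype=np.int64)
        remap[used] = np.arange(len(used))
        out.append(TriangleMesh(mesh.vertices[used], remap[fsel]))
    return out


# ----------------------------------------------------------------------
# I/O — ASCII OFF (canonical interchange) and PLY via trimesh
# ----------------------------------------------------------------------

def load_mesh(path, format: str | None = None) -> TriangleMesh:
    """Load a triangle mesh from an OFF or PLY file.

    Vertex coordinates and stored winding are preserved exactly. Polygonal
    OFF faces with more than three corners are fan-triangulated.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "off":
        return _load_off(path)
    if fmt == "ply":
        return _load_ply(path)
    raise MeshFormatError(f"unsupported mesh format {fmt!r} (use OFF or PLY)")


def write_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a mesh as ASCII OFF or PLY; coordinates at full double precision."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "off":
        _write_off(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (use OFF or PLY)")


def _off_tokens(lines):
    """Yield (lineno, tokens) for non-comment, non-empty OFF lines."""
    for i, raw in enumerate(lines, start=1):
        stripped = raw.split("#", 1)[0].strip()
        if stripped:
            yield i, stripped.split()


def _load_off(path: Path) -> TriangleMesh:
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise MeshFormatError(str(exc), path=path) from exc
    tok = _off_tokens(lines)
    try:
        lineno, first = next(tok)
    except StopIteration:
        raise MeshFormatError("empty file", path=path, line=1) from None
    if first == ["OFF"]:
        try:
            lineno, first = next(tok)
        except StopIteration:
            raise MeshFormatError("missing element counts", path=path, line=lineno)
    if len(first) != 3:
        raise MeshFormatError("expected 'nVertices nFaces nEdges'", path=path, line=lineno)
    try:
        nv, nf = int(first[0]), int(first[1])
    except ValueError:
        raise MeshFormatError("element counts are not integers", path=path, line=lineno)
    verts = np.zeros((nv, 3))
    for k in range(nv):
        try:
            lineno, t = next(tok)
        except StopIteration:
            raise MeshFormatError(
                f"file ends after {k} of {nv} vertices", path=path, line=len(lines)
            ) from None
        if len(t) < 3:
            raise MeshFormatError("vertex line needs 3 coordinates", path=path, line=lineno)
        try:
            verts[k] = [float(x) for x in t[:3]]
        except ValueError:
            raise MeshFormatError("bad vertex coordinate", path=path, line=lineno)
    faces: list[tuple[int, int, int]] = []
    for k in range(nf):
        try:
            lineno, t = next(tok)
        except StopIteration:
            raise MeshFormatError(
                f"file ends after {k} of {nf} faces", path=path, line=len(lines)
            ) from None
        try:
            cnt = int(t[0])
            idx = [int(x) for x in t[1 : 1 + cnt]]
        except (ValueError, IndexError):
            raise MeshFormatError("bad face line", path=path, line=lineno)
        if len(idx) != cnt or cnt < 3:
            raise MeshFormatError("face index count mismatch", path=path, line=lineno)
        if any(i < 0 or i >= nv for i in idx):
            raise MeshFormatError("face index out of range", path=path, line=lineno)
        for j in range(1, cnt - 1):  # fan triangulation preserves winding
            faces.append((idx[0], idx[j], idx[j + 1]))
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def _write_off(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _load_ply(path: Path) -> TriangleMesh:
    import trimesh

    try:
        tm = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises various types on malformed input
        raise MeshFormatError(f"PLY parse failure: {exc}", path=path) from exc
    if not hasattr(tm, "faces"):
        raise MeshFormatError("PLY file contains no faces", path=path)
    return TriangleMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type="ply", encoding="ascii")


# ----------------------------------------------------------------------
# Ray parity / point-in-solid
# ----------------------------------------------------------------------

_EPS = 1e-9
_MAX_REDRAWS = 32


def _ray_crossings(mesh: TriangleMesh, origin: np.ndarray, direction: np.ndarray) -> int:
    """Count ray/triangle crossings (Möller–Trumbore), vectorized.

    Raises GrazingRayError when the ray passes within a relative epsilon of a
    triangle edge/vertex, hits a triangle nearly edge-on, or originates on the
    surface — callers redraw a fresh random direction in those cases.
    """
    tri = mesh.triangle_corners()
    # bbox slab pruning along the ray
    lo = tri.min(axis=1) - 1e-12
    hi = tri.max(axis=1) + 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo - origin) / direction
        t1 = (hi - origin) / direction
    tmin = np.minimum(t0, t1)
    tmax = np.maximum(t0, t1)
    # axes where direction ~ 0: inside slab iff origin within bounds
    par = np.abs(direction) < 1e-300
    tmin[:, par] = np.where((lo[:, par] <= origin[par]) & (origin[par] <= hi[:, par]), -np.inf, np.inf)
    tmax[:, par] = np.where((lo[:, par] <= origin[par]) & (origin[par] <= hi[:, par]), np.inf, -np.inf)
    enter = np.nanmax(tmin, axis=1)
    leave = np.nanmin(tmax, axis=1)
    cand = tri[(enter <= leave) & (leave >= 0)]
    if len(cand) == 0:
        return 0

    a, b, c = cand[:, 0], cand[:, 1], cand[:, 2]
    e1, e2 = b - a, c - a
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1) + 1e-300
    edge_on = np.abs(det) < 1e-9 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        tvec = origin - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,j->i", qvec, direction) * inv
        t = np.einsum("ij,ij->i", qvec, e2) * inv
    w = 1.0 - u - v
    if np.any(edge_on):
        # A nearly edge-on triangle among the candidates makes the count
        # unreliable; treat the draw as degenerate and let the caller redraw.
        raise GrazingRayError("ray nearly parallel to a triangle")
    inside_strict = (u > _EPS) & (v > _EPS) & (w > _EPS) & (t > _EPS)
    near_edge = (
        (np.abs(u) <= _EPS) | (np.abs(v) <= _EPS) | (np.abs(w) <= _EPS) | (np.abs(t) <= _EPS)
    )
    plausible = (u > -_EPS) & (v > -_EPS) & (w > -_EPS) & (t > -_EPS)
    if np.any(near_edge & plausible):
        raise GrazingRayError("ray grazes a triangle edge/vertex")
    return int(np.count_nonzero(inside_strict))


def _require_closed(mesh: TriangleMesh) -> None:
    if not is_closed(mesh):
        raise OpenMeshError("operation requires a closed (watertight) mesh")


def ray_parity(
    mesh: TriangleMesh,
    point,
    direction=None,
    seed: int = 0,
) -> int:
    """Parity (0/1) of ray/surface crossings from ``point``.

    With an explicit ``direction`` a single ray is cast and a
    :class:`GrazingRayError` raised on a degenerate hit. With
    ``direction=None`` random unit directions are drawn from a seeded
    generator; degenerate draws are discarded and redrawn (max 32).
    """
    _require_closed(mesh)
    if mesh.is_empty:
        return 0
    point = np.asarray(point, dtype=float)
    if direction is not None:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return _ray_crossings(mesh, point, d) % 2
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REDRAWS):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        try:
            return _ray_crossings(mesh, point, d) % 2
        except GrazingRayError:
            continue
    raise GrazingRayError(
        f"no generic ray found in {_MAX_REDRAWS} draws; point may lie on the surface"
    )


def point_in_solid(mesh: TriangleMesh, point, rng_seed: int = 0) -> bool:
    """True iff ``point`` is inside the solid bounded by ``mesh`` (odd parity)."""
    return ray_parity(mesh, point, seed=rng_seed) == 1


def points_in_solid(mesh: TriangleMesh, points: np.ndarray, rng_seed: int = 0) -> np.ndarray:
    """Vectorized convenience wrapper over :func:`point_in_solid`."""
    return np.array([point_in_solid(mesh, p, rng_seed) for p in np.atleast_2d(points)])
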
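"""Marching-cubes constructive solid geometry on a cubic lattice.

Given two closed regions A and B (triangle meshes) and a boolean operation,
the engine:

1. builds an axis-aligned cubic lattice covering the operands (origin snapped
   to global multiples of the spacing so grids from different calls are
   commensurate);
2. labels every lattice point inside/outside the *output* region — inside A
   and inside B for an intersection, inside either for a union, inside A but
   not B for a difference. Membership is decided by crossing parity: lattice
   points share axis-parallel rays, so all points on a lattice line are
   classified from one sorted list of surface crossings (a watertight
   orientation-sign rasterization with a fixed tie rule);
3. finds, on every lattice segment whose endpoints straddle the output
   region, the crossing point p0 where the segment exits the region. When
   both surfaces cross the segment, the candidate that actually flips the
   output state is selected (equivalently: the crossing of one surface lying
   inside/outside the other solid, as the operation requires);
4. connects crossing points with triangles using the 256-case cube table,
   wound counterclockwise seen from outside the output solid.

The same lattice/table machinery extracts isosurfaces of scalar fields
(used for solvent-excluded surfaces and analytic sphere unions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .exceptions import CavCsgError, OpenMeshError, ResourceError
from .mctable import CORNERS, EDGE_AXIS, EDGE_BASE, TRI_TABLE
from .mesh import TriangleMesh, is_closed

__all__ = [
    "Lattice",
    "CsgOperation",
    "build_lattice",
    "classify_points",
    "find_crossing",
    "csg",
    "csg_many",
    "isosurface",
]

log = logging.getLogger(__name__)

DEFAULT_SPACING = 0.5  # Å — the resolution used throughout unless overridden
_MAX_LATTICE_POINTS = 2 * 10**8

_OPS = ("union", "intersection", "difference")
_EXACT_TOL = 1e-9  # lattice units: crossing considered exactly on a point


@dataclass(frozen=True)
class CsgOperation:
    """A boolean operation; ``difference`` is ordered (A minus B)."""

    kind: str

    def __post_init__(self):
        k = _canonical_op(self.kind)
        object.__setattr__(self, "kind", k)

    def combine(self, in_a, in_b):
        if self.kind == "union":
            return in_a | in_b
        if self.kind == "intersection":
            return in_a & in_b
        return in_a & ~in_b


def _canonical_op(op) -> str:
    if isinstance(op, CsgOperation):
        return op.kind
    k = str(op).lower()
    aliases = {
        "union": "union", "u": "union", "or": "union",
        "intersection": "intersection", "intersect": "intersection", "and": "intersection",
        "difference": "difference", "diff": "difference", "minus": "difference",
    }
    if k not in aliases:
        raise ValueError(f"unknown CSG operation {op!r}; use one of {_OPS}")
    return aliases[k]


@dataclass(frozen=True)
class Lattice:
    """Axis-aligned cubic lattice: origin (Å), spacing (Å), point counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("lattice needs at least 2 points per axis")
        if int(np.prod(self.dims)) > _MAX_LATTICE_POINTS:
            raise ResourceError(
                f"lattice of {np.prod(self.dims):.2e} points exceeds the memory "
                "budget; use a coarser spacing"
            )

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)

    def point(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(idx, dtype=float)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(
            o[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)
        )


def build_lattice(
    meshes: TriangleMesh | Sequence[TriangleMesh],
    spacing: float = DEFAULT_SPACING,
    padding: float | None = None,
    bounds: np.ndarray | None = None,
) -> Lattice:
    """Cubic lattice strictly containing the meshes, expanded by ``padding``.

    The origin is snapped down to an integer multiple of ``spacing`` in the
    global frame, so lattices built from different inputs are commensurate.
    Default padding is twice the spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if padding is None:
        padding = 2.0 * spacing
    if bounds is None:
        if isinstance(meshes, TriangleMesh):
            meshes = [meshes]
        meshes = [m for m in meshes if not m.is_empty]
        if not meshes:
            raise ValueError("cannot build a lattice over an empty mesh set")
        los = np.array([m.bounds[0] for m in meshes]).min(axis=0)
        his = np.array([m.bounds[1] for m in meshes]).max(axis=0)
    else:
        los, his = np.asarray(bounds, dtype=float)
    lo = np.floor((los - padding) / spacing) * spacing
    hi = np.ceil((his + padding) / spacing) * spacing
    dims = np.maximum(np.rint((hi - lo) / spacing).astype(int) + 1, 2)
    return Lattice(tuple(lo), float(spacing), tuple(int(d) for d in dims))


# ----------------------------------------------------------------------
# Lattice-line sweeps: crossings and point labels per input mesh
# ----------------------------------------------------------------------

def _uv_axes(axis: int) -> tuple[int, int]:
    return (axis + 1) % 3, (axis + 2) % 3


def _tie_rule(du: np.ndarray, dv: np.ndarray):
    """Fill rule for query points exactly on a projected edge (Pineda style)."""
    return (dv < 0) | ((dv == 0) & (du > 0))


def _rasterize_crossings(verts_lat: np.ndarray, faces: np.ndarray, axis: int, nu: int, nv: int):
    """All crossings of axis-parallel lattice lines with the mesh.

    ``verts_lat``: vertices in lattice units. Returns (iu, iv, t) arrays:
    line indices along the two other axes (in cyclic order) and the crossing
    coordinate t (lattice units) along ``axis``. Shared edges between
    consistently wound triangles are counted exactly once (opposite-side
    neighbours) or an even number of times (silhouette folds), so crossing
    parity along every line is correct.
    """
    u_ax, v_ax = _uv_axes(axis)
    tri = verts_lat[faces]
    out_iu, out_iv, out_t = [], [], []
    tu = tri[:, :, u_ax]
    tv = tri[:, :, v_ax]
    td = tri[:, :, axis]
    lo_u = np.ceil(tu.min(axis=1) - 1e-12).astype(int)
    hi_u = np.floor(tu.max(axis=1) + 1e-12).astype(int)
    lo_v = np.ceil(tv.min(axis=1) - 1e-12).astype(int)
    hi_v = np.floor(tv.max(axis=1) + 1e-12).astype(int)
    np.clip(lo_u, 0, None, out=lo_u)
    np.clip(hi_u, None, nu - 1, out=hi_u)
    np.clip(lo_v, 0, None, out=lo_v)
    np.clip(hi_v, None, nv - 1, out=hi_v)
    nonempty = (hi_u >= lo_u) & (hi_v >= lo_v)
    for i in np.nonzero(nonempty)[0]:
        au, bu, cu = tu[i]
        av, bv, cv = tv[i]
        area2 = (bu - au) * (cv - av) - (bv - av) * (cu - au)
        if area2 == 0.0:
            continue  # projects edge-on: contributes no generic crossings
        s = 1.0 if area2 > 0 else -1.0
        qu = np.arange(lo_u[i], hi_u[i] + 1, dtype=float)
        qv = np.arange(lo_v[i], hi_v[i] + 1, dtype=float)
        QU = qu[:, None]
        QV = qv[None, :]
        # Edge functions: w_a pairs with vertex a (edge b->c), etc.
        wa = (cu - bu) * (QV - bv) - (cv - bv) * (QU - bu)
        wb = (au - cu) * (QV - cv) - (av - cv) * (QU - cu)
        wc = (bu - au) * (QV - av) - (bv - av) * (QU - au)

        def edge_ok(w, p0u, p0v, p1u, p1v):
            sw = s * w
            return (sw > 0) | ((sw == 0) & _tie_rule(s * (p1u - p0u), s * (p1v - p0v)))

        ok = (
            edge_ok(wa, bu, bv, cu, cv)
            & edge_ok(wb, cu, cv, au, av)
            & edge_ok(wc, au, av, bu, bv)
        )
        if not ok.any():
            continue
        ad, bd, cd = td[i]
        t = (wa * ad + wb * bd + wc * cd) / area2
        sel = np.nonzero(ok)
        out_iu.append(sel[0] + lo_u[i])
        out_iv.append(sel[1] + lo_v[i])
        out_t.append(t[ok])
    if out_iu:
        return (
            np.concatenate(out_iu),
            np.concatenate(out_iv),
            np.concatenate(out_t),
        )
    return np.zeros(0, int), np.zeros(0, int), np.zeros(0)


class MeshOnLattice:
    """A closed mesh sampled on a lattice: point labels + segment crossings."""

    def __init__(self, mesh: TriangleMesh, lattice: Lattice, check: bool = True):
        if check and not is_closed(mesh):
            raise OpenMeshError("CSG inputs must be closed (watertight) meshes")
        self.mesh = mesh
        self.lattice = lattice
        self._cross: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._maps: dict[int, dict[tuple[int, int, int], list[float]]] = {}
        if mesh.is_empty:
            self.labels = np.zeros(lattice.dims, dtype=bool)
            self._verts_lat = np.zeros((0, 3))
        else:
            v = (mesh.vertices - np.asarray(lattice.origin)) / lattice.spacing
            # Meshes produced by earlier marching-cubes passes have vertices
            # lying exactly on lattice lines of any commensurate lattice.
            # Snap near-integer lattice-unit coordinates so the rasterizer's
            # tie rule sees exact zeros instead of rounding noise (which
            # would break crossing parity along those lines).
            r = np.rint(v)
            self._verts_lat = np.where(np.abs(v - r) < 1e-9, r, v)
            self.labels = self._labels_from_sweep(0)

    def _sweep(self, axis: int):
        if axis not in self._cross:
            u_ax, v_ax = _uv_axes(axis)
            self._cross[axis] = _rasterize_crossings(
                self._verts_lat,
                self.mesh.faces,
                axis,
                self.lattice.dims[u_ax],
                self.lattice.dims[v_ax],
            )
        return self._cross[axis]

    def _labels_from_sweep(self, axis: int) -> np.ndarray:
        iu, iv, t = self._sweep(axis)
        dims = self.lattice.dims
        counts = np.zeros(dims, dtype=np.int32)
        idx_d = np.floor(t).astype(int) + 1  # first lattice point strictly past t
        keep = (idx_d < dims[axis]) & (idx_d >= 0)
        below = idx_d < 0  # crossings before the lattice flip every point
        u_ax, v_ax = _uv_axes(axis)
        index = [None, None, None]
        index[axis] = idx_d[keep]
        index[u_ax] = iu[keep]
        index[v_ax] = iv[keep]
        np.add.at(counts, tuple(index), 1)
        if below.any():
            index0 = [None, None, None]
            index0[axis] = np.zeros(int(below.sum()), dtype=int)
            index0[u_ax] = iu[below]
            index0[v_ax] = iv[below]
            np.add.at(counts, tuple(index0), 1)
        labels = (np.cumsum(counts, axis=axis) % 2).astype(bool)
        # Closed-solid convention: a lattice point carrying a surface crossing
        # exactly on it (input face coincides with a lattice plane) is inside.
        exact = np.abs(t - np.rint(t)) < _EXACT_TOL
        if exact.any():
            k = np.rint(t[exact]).astype(int)
            ok = (k >= 0) & (k < dims[axis])
            idx = [None, None, None]
            idx[axis] = k[ok]
            idx[u_ax] = iu[exact][ok]
            idx[v_ax] = iv[exact][ok]
            labels[tuple(idx)] = True
        return labels

    def segment_crossings(self, axis: int, base: tuple[int, int, int]) -> list[float]:
        """Crossing offsets t in [0, 1] on the unit lattice segment at ``base``."""
        if axis not in self._maps:
            iu, iv, t = self._sweep(axis)
            m: dict[tuple[int, int, int], list[float]] = {}
            k = np.floor(t).astype(int)
            exact = np.abs(t - np.rint(t)) < _EXACT_TOL
            for a, b, kk, tt, ex in zip(
                iu.tolist(), iv.tolist(), k.tolist(), t.tolist(), exact.tolist()
            ):
                if ex:
                    # A crossing exactly on a lattice point belongs to both
                    # adjacent segments (as offset 1 below, offset 0 above).
                    kk = int(round(tt))
                    m.setdefault((a, b, kk - 1), []).append(float(kk))
                    m.setdefault((a, b, kk), []).append(float(kk))
                else:
                    m.setdefault((a, b, kk), []).append(tt)
            self._maps[axis] = m
        u_ax, v_ax = _uv_axes(axis)
        key = (base[u_ax], base[v_ax], base[axis])
        return [t - base[axis] for t in self._maps[axis].get(key, [])]


def classify_points(
    lattice: Lattice,
    a: TriangleMesh,
    b: TriangleMesh,
    op: CsgOperation | str,
) -> np.ndarray:
    """Inside/outside labels of every lattice point for the *output* region."""
    operation = CsgOperation(_canonical_op(op))
    la = MeshOnLattice(a, lattice).labels
    lb = MeshOnLattice(b, lattice).labels
    return operation.combine(la, lb)


# ----------------------------------------------------------------------
# Crossing-point selection
# ----------------------------------------------------------------------

_CLAMP = 1e-6


def _select_crossing(
    t_a: Iterable[float],
    t_b: Iterable[float],
    in_a: bool,
    in_b: bool,
    op: CsgOperation,
) -> float | None:
    """Offset in [0,1] where the output region's boundary crosses a segment.

    Walks the candidate surface crossings in order, toggling membership in A
    and B, and returns the first candidate at which the output state flips —
    the paper's rule (pick p_A if p_A is inside B, else p_B, for an
    intersection) generalized to all three operations and to repeated
    crossings.
    """
    cands = sorted([(t, 0) for t in t_a] + [(t, 1) for t in t_b])
    state = [in_a, in_b]
    out0 = bool(op.combine(state[0], state[1]))
    for t, src in cands:
        state[src] = not state[src]
        if bool(op.combine(state[0], state[1])) != out0:
            return min(max(t, _CLAMP), 1.0 - _CLAMP)
    return None


def find_crossing(
    p_lo,
    p_hi,
    a: TriangleMesh,
    b: TriangleMesh,
    op: CsgOperation | str,
    seed: int = 0,
) -> np.ndarray:
    """Crossing point p0 on a single lattice segment (standalone contract).

    ``p_lo``/``p_hi`` are the two co-axial segment endpoints, which must lie
    on opposite sides of the output region. Surface crossings are computed by
    exact segment/triangle intersection; endpoint membership by seeded
    ray parity.
    """
    from .mesh import point_in_solid

    p_lo = np.asarray(p_lo, dtype=float)
    p_hi = np.asarray(p_hi, dtype=float)
    operation = CsgOperation(_canonical_op(op))
    in_a, in_b = point_in_solid(a, p_lo, seed), point_in_solid(b, p_lo, seed)
    end_a, end_b = point_in_solid(a, p_hi, seed), point_in_solid(b, p_hi, seed)
    if operation.combine(in_a, in_b) == operation.combine(end_a, end_b):
        raise CavCsgError("segment endpoints do not straddle the output region")
    t_a = _segment_surface_hits(a, p_lo, p_hi)
    t_b = _segment_surface_hits(b, p_lo, p_hi)
    t = _select_crossing(t_a, t_b, in_a, in_b, operation)
    if t is None:
        log.warning("no surface crossing found on a straddling segment; using midpoint")
        t = 0.5
    return p_lo + t * (p_hi - p_lo)


def _segment_surface_hits(mesh: TriangleMesh, p_lo, p_hi) -> list[float]:
    if mesh.is_empty:
        return []
    d = p_hi - p_lo
    tri = mesh.triangle_corners()
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        tvec = p_lo - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,j->i", qvec, d) * inv
        t = np.einsum("ij,ij->i", qvec, e2) * inv
    with np.errstate(invalid="ignore"):
        ok = (
            (np.abs(det) > 1e-300)
            & (u >= 0) & (v >= 0) & (u + v <= 1)
            & (t >= 0) & (t <= 1)
        )
    return sorted(t[ok].tolist())


# ----------------------------------------------------------------------
# Cube triangulation
# ----------------------------------------------------------------------

def _triangulate(
    labels: np.ndarray,
    lattice: Lattice,
    crossing_at: Callable[[int, int, int, int], float],
) -> TriangleMesh:
    """Connect crossing points with the 256-case table into a closed mesh.

    ``crossing_at(axis, i, j, k)`` returns the fractional crossing offset in
    (0, 1) along the lattice segment with base point (i, j, k).
    """
    nx, ny, nz = labels.shape
    case = np.zeros((nx - 1, ny - 1, nz - 1), dtype=np.uint16)
    lab = labels.astype(np.uint16)
    for ci, (dx, dy, dz) in enumerate(CORNERS):
        case |= lab[dx : dx + nx - 1, dy : dy + ny - 1, dz : dz + nz - 1] << ci
    mixed = np.argwhere((case > 0) & (case < 255))
    if len(mixed) == 0:
        return TriangleMesh.empty()
    verts: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    vid: dict[tuple[int, int, int, int], int] = {}
    origin = np.asarray(lattice.origin)
    sp = lattice.spacing
    for ix, iy, iz in mixed:
        tris = TRI_TABLE[case[ix, iy, iz]]
        for tri in tris:
            idxs = []
            for e in tri:
                ax = int(EDGE_AXIS[e])
                bx, by, bz = EDGE_BASE[e]
                key = (ax, int(ix + bx), int(iy + by), int(iz + bz))
                if key not in vid:
                    t = crossing_at(*key)
                    pos = origin + sp * np.array(key[1:], dtype=float)
                    pos[ax] += sp * t
                    vid[key] = len(verts)
                    verts.append(tuple(pos))
                idxs.append(vid[key])
            faces.append(tuple(idxs))
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


# ----------------------------------------------------------------------
# Public entry points
# ----------------------------------------------------------------------

def _clamp_border(labels: np.ndarray, context: str = "") -> np.ndarray:
    """Force the outermost lattice shell outside (the padded bounds contain
    the output region, so an inside border label is a parity artifact from a
    degenerate sweep line; clamping keeps the extracted surface closed)."""
    border = labels.copy()
    border[1:-1, 1:-1, 1:-1] = False
    n_bad = int(np.count_nonzero(border))
    if n_bad:
        log.warning("%s: cleared %d inside label(s) on the lattice border", context, n_bad)
        labels = labels.copy()
        labels[0, :, :] = labels[-1, :, :] = False
        labels[:, 0, :] = labels[:, -1, :] = False
        labels[:, :, 0] = labels[:, :, -1] = False
    return labels


def _op_bounds(a: TriangleMesh, b: TriangleMesh, op: str) -> np.ndarray:
    ba, bb = a.bounds, b.bounds
    if op == "union":
        return np.array([np.minimum(ba[0], bb[0]), np.maximum(ba[1], bb[1])])
    if op == "difference":
        return ba
    return np.array([np.maximum(ba[0], bb[0]), np.minimum(ba[1], bb[1])])


def csg(
    a: TriangleMesh,
    b: TriangleMesh,
    op: CsgOperation | str,
    spacing: float = DEFAULT_SPACING,
    padding: float | None = None,
) -> TriangleMesh:
    """Boolean combination of two closed regions on a cubic lattice.

    Returns a closed, consistently oriented triangle mesh approximating the
    result at the given resolution; an empty mesh when the result is empty.
    """
    kind = _canonical_op(op)
    operation = CsgOperation(kind)
    if a.is_empty or b.is_empty:
        if kind == "union":
            return (b if a.is_empty else a).copy()
        if kind == "difference":
            return TriangleMesh.empty() if a.is_empty else a.copy()
        return TriangleMesh.empty()
    bounds = _op_bounds(a, b, kind)
    if np.any(bounds[0] > bounds[1]):  # disjoint bounding boxes
        if kind == "intersection":
            return TriangleMesh.empty()
        if kind == "difference":
            return a.copy()
        bounds = _op_bounds(a, b, "union")
    lattice = build_lattice([a, b], spacing, padding, bounds=bounds)
    on_a = MeshOnLattice(a, lattice)
    on_b = MeshOnLattice(b, lattice)
    out = operation.combine(on_a.labels, on_b.labels)
    out = _clamp_border(out, kind)

    fallback_count = [0]

    def crossing_at(axis: int, i: int, j: int, k: int) -> float:
        base = (i, j, k)
        t_a = on_a.segment_crossings(axis, base)
        t_b = on_b.segment_crossings(axis, base)
        in_a = bool(on_a.labels[base])
        in_b = bool(on_b.labels[base])
        t = _select_crossing(t_a, t_b, in_a, in_b, operation)
        if t is None:
            fallback_count[0] += 1
            t = 0.5
        return t

    result = _triangulate(out, lattice, crossing_at)
    if fallback_count[0]:
        log.warning(
            "csg(%s): %d straddling segment(s) had no surface crossing; "
            "used segment midpoints",
            kind,
            fallback_count[0],
        )
    return result


def isosurface(field: np.ndarray, lattice: Lattice, level: float = 0.0) -> TriangleMesh:
    """Extract the ``field > level`` boundary with the same cube table.

    Crossing points are placed by linear interpolation of the field along
    lattice segments. Used for solvent-excluded surfaces and sphere unions.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != tuple(lattice.dims):
        raise ValueError("field shape does not match lattice dims")
    labels = _clamp_border(field > level, "isosurface")

    def crossing_at(axis: int, i: int, j: int, k: int) -> float:
        f0 = field[i, j, k]
        nxt = [i, j, k]
        nxt[axis] += 1
        f1 = field[tuple(nxt)]
        t = (f0 - level) / (f0 - f1)
        return min(max(t, _CLAMP), 1.0 - _CLAMP)

    return _triangulate(labels, lattice, crossing_at)


# ----------------------------------------------------------------------
# Multi-region composition
# ----------------------------------------------------------------------

def _fold(meshes: Sequence[TriangleMesh], kind: str, spacing: float) -> TriangleMesh:
    acc = meshes[0]
    for m in meshes[1:]:
        acc = csg(acc, m, kind, spacing)
        if acc.is_empty and kind == "intersection":
            break
    return acc if acc is not meshes[0] else acc.copy()


def csg_many(
    regions: Sequence[TriangleMesh] | dict[str, TriangleMesh],
    ops: str | CsgOperation = "intersection",
    spacing: float = DEFAULT_SPACING,
) -> TriangleMesh:
    """Left-fold CSG over several regions, or evaluate a named expression.

    With a list, ``ops`` is a single operation folded left-to-right
    (``intersection`` reproduces repeated cavity intersection; ``union`` the
    occupied-by-any region). With a dict, ``ops`` is an expression over the
    region names using ``&`` (intersection), ``|`` (union), ``-``
    (difference) and parentheses, e.g. ``"(t1 & t2 & t3) - (e1 | e2)"``.
    """
    if isinstance(regions, dict):
        if not isinstance(ops, str):
            raise ValueError("expression form requires a string expression")
        return _eval_expression(ops, regions, spacing)
    regions = list(regions)
    if not regions:
        raise ValueError("csg_many needs at least one region")
    return _fold(regions, _canonical_op(ops), spacing)


def _tokenize(expr: str) -> list[str]:
    tokens, i = [], 0
    while i < len(expr):
        ch = expr[i]
        if ch.isspace():
            i += 1
        elif ch in "()&|-":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < len(expr) and (expr[j].isalnum() or expr[j] in "_."):
                j += 1
            if j == i:
                raise ValueError(f"bad character {ch!r} in CSG expression")
            tokens.append(expr[i:j])
            i = j
    return tokens


def _eval_expression(expr: str, env: dict[str, TriangleMesh], spacing: float) -> TriangleMesh:
    tokens = _tokenize(expr)
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def take():
        tok = peek()
        pos[0] += 1
        return tok

    def factor() -> TriangleMesh:
        tok = take()
        if tok == "(":
            val = expr_rule()
            if take() != ")":
                raise ValueError("unbalanced parentheses in CSG expression")
            return val
        if tok is None or tok in "()&|-":
            raise ValueError("malformed CSG expression")
        if tok not in env:
            raise KeyError(f"unknown region name {tok!r} in CSG expression")
        return env[tok]

    def term() -> TriangleMesh:
        val = factor()
        while peek() == "&":
            take()
            val = csg(val, factor(), "intersection", spacing)
        return val

    def expr_rule() -> TriangleMesh:
        val = term()
        while peek() in ("|", "-"):
            op = take()
            rhs = term()
            val = csg(val, rhs, "union" if op == "|" else "difference", spacing)
        return val

    out = expr_rule()
    if pos[0] != len(tokens):
        raise ValueError("trailing tokens in CSG expression")
    return out
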
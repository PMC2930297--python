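"""Independent brute-force oracles for geometric results.

Nothing here shares a code path with the CSG engine, the Surveyor's-Formula
volume, or the ray-parity classifier: membership is decided by the
generalized winding number (summed signed solid angles), volumes by counting
grid points, and overlaps by closed forms. These are the references the
test suite holds the engine against.
"""

from __future__ import annotations

import numpy as np

from .mesh import TriangleMesh

__all__ = [
    "winding_number_inside",
    "voxel_volume_oracle",
    "sphere_volume",
    "sphere_sphere_lens",
    "sphere_in_sphere_overlap",
    "box_box_overlap",
    "capsule_volume",
]


def winding_numbers(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Generalized winding number of each point (≈1 inside, ≈0 outside).

    Van Oosterom–Strackee signed solid angles, accumulated over triangles in
    chunks. Independent of any ray casting.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangle_corners()
    total = np.zeros(len(points))
    point_chunk = 512
    for pstart in range(0, len(points), point_chunk):
        psl = slice(pstart, pstart + point_chunk)
        total[psl] = _winding_chunk(tri, points[psl])
    return total / (4.0 * np.pi)


try:  # optional acceleration; the numpy path below is the reference
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _winding_total_numba(tri, points):  # pragma: no cover - numerics identical
        n = points.shape[0]
        m = tri.shape[0]
        out = np.zeros(n)
        for p in range(n):
            px, py, pz = points[p, 0], points[p, 1], points[p, 2]
            acc = 0.0
            for t in range(m):
                ax = tri[t, 0, 0] - px; ay = tri[t, 0, 1] - py; az = tri[t, 0, 2] - pz
                bx = tri[t, 1, 0] - px; by = tri[t, 1, 1] - py; bz = tri[t, 1, 2] - pz
                cx = tri[t, 2, 0] - px; cy = tri[t, 2, 1] - py; cz = tri[t, 2, 2] - pz
                la = (ax * ax + ay * ay + az * az) ** 0.5
                lb = (bx * bx + by * by + bz * bz) ** 0.5
                lc = (cx * cx + cy * cy + cz * cz) ** 0.5
                # a . (b x c)
                num = (
                    ax * (by * cz - bz * cy)
                    + ay * (bz * cx - bx * cz)
                    + az * (bx * cy - by * cx)
                )
                den = (
                    la * lb * lc
                    + (ax * bx + ay * by + az * bz) * lc
                    + (bx * cx + by * cy + bz * cz) * la
                    + (cx * ax + cy * ay + cz * az) * lb
                )
                acc += 2.0 * np.arctan2(num, den)
            out[p] = acc
        return out

except Exception:  # numba unavailable: pure-numpy chunked path only
    _winding_total_numba = None


def _winding_chunk(tri: np.ndarray, points: np.ndarray) -> np.ndarray:
    if _winding_total_numba is not None:
        return _winding_total_numba(
            np.ascontiguousarray(tri), np.ascontiguousarray(points)
        )
    total = np.zeros(len(points))
    tri_chunk = 1280  # keeps working arrays cache-friendly
    for start in range(0, len(tri), tri_chunk):
        t = tri[start : start + tri_chunk]
        a = t[None, :, 0, :] - points[:, None, :]
        b = t[None, :, 1, :] - points[:, None, :]
        c = t[None, :, 2, :] - points[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pij,pij->pi", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("pij,pij->pi", a, b) * lc
            + np.einsum("pij,pij->pi", b, c) * la
            + np.einsum("pij,pij->pi", c, a) * lb
        )
        total += 2.0 * np.arctan2(num, den).sum(axis=1)
    return total


def winding_number_inside(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Boolean membership: winding number > 1/2."""
    return winding_numbers(mesh, points) > 0.5


def voxel_volume_oracle(
    a: TriangleMesh,
    b: TriangleMesh | None,
    op: str = "intersection",
    spacing: float = 0.25,
) -> float:
    """Boolean-result volume by counting grid-point membership × spacing³.

    Uses its own grid (offset half a step from multiples of the spacing so
    points are voxel centers) and winding-number membership — no marching
    cubes, no Surveyor's Formula.
    """
    op = op.lower()
    if op not in ("union", "intersection", "difference"):
        raise ValueError(f"unknown op {op!r}")
    b_empty = b is None or b.is_empty
    if a.is_empty:
        if op == "union" and not b_empty:
            return voxel_volume_oracle(b, None, "union", spacing)
        return 0.0
    if op == "intersection" and not b_empty:
        lo = np.maximum(a.bounds[0], b.bounds[0]) - spacing
        hi = np.minimum(a.bounds[1], b.bounds[1]) + spacing
        if np.any(lo > hi):
            return 0.0
    elif op == "union" and not b_empty:
        lo = np.minimum(a.bounds[0], b.bounds[0]) - spacing
        hi = np.maximum(a.bounds[1], b.bounds[1]) + spacing
    else:  # difference, or single mesh
        lo, hi = a.bounds[0] - spacing, a.bounds[1] + spacing
    axes = [
        (np.floor(lo[k] / spacing) + 0.5) * spacing
        + spacing * np.arange(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1)
        for k in range(3)
    ]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    in_a = winding_number_inside(a, pts)
    if b_empty:
        return int(np.count_nonzero(in_a)) * spacing**3
    if op == "union":
        # only points outside A need a test against B
        out_a = ~in_a
        in_b = winding_number_inside(b, pts[out_a])
        count = int(np.count_nonzero(in_a)) + int(np.count_nonzero(in_b))
    else:
        # intersection / difference: only points inside A matter
        in_b = winding_number_inside(b, pts[in_a])
        hits = int(np.count_nonzero(in_b))
        count = hits if op == "intersection" else int(np.count_nonzero(in_a)) - hits
    return count * spacing**3


# ----------------------------------------------------------------------
# Closed forms
# ----------------------------------------------------------------------

def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r**3


def sphere_sphere_lens(r1: float, r2: float, d: float) -> float:
    """Overlap volume of two spheres with center distance d (spherical caps)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume(min(r1, r2))
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


def sphere_in_sphere_overlap(r_small: float, r_big: float, d: float) -> float:
    """Overlap when the small sphere may be nested: just the general lens."""
    return sphere_sphere_lens(r_small, r_big, d)


def box_box_overlap(lo1, hi1, lo2, hi2) -> float:
    ext = np.minimum(hi1, hi2) - np.maximum(lo1, lo2)
    ext = np.clip(ext, 0.0, None)
    return float(np.prod(ext))


def capsule_volume(r: float, length: float) -> float:
    """Convex hull of two equal spheres at center distance ``length``."""
    return sphere_volume(r) + np.pi * r**2 * length
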
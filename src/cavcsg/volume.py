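"""Enclosed volume via the Surveyor's Formula; volumetric similarity.

The volume of a closed, outward-oriented triangle mesh is accumulated as a
signed sum of tetrahedra: each boundary triangle t forms a tetrahedron with
the global corner centroid c; its (unsigned) volume v(T) — evaluated with
Tartaglia's rule, the three-dimensional analogue of Heron's formula — is
added when the outward normal of t faces away from c (positive dot product
between the normal and t_c − c) and subtracted when it faces towards c.
The signed bookkeeping is algebraically identical to the divergence-theorem
sum Σ det(v1, v2, v3)/6 and is exact for polyhedra.

Volumetric similarity between two aligned cavities x, y is the proportion of
intersecting volume relative to the maximum theoretically attainable — the
volume of the smaller cavity: V(x∩y) / min(V(x), V(y)). The complement
(1 − similarity) is the dissimilarity used for UPGMA clustering.
"""

from __future__ import annotations

import logging

import numpy as np

from .csg import DEFAULT_SPACING, csg
from .exceptions import OpenMeshError, UndefinedSimilarityError
from .mesh import TriangleMesh, is_closed

__all__ = [
    "tetrahedron_volume",
    "tetrahedron_volume_cayley_menger",
    "enclosed_volume",
    "volumetric_similarity",
    "volumetric_distance",
]

log = logging.getLogger(__name__)


def tetrahedron_volume(a, b, c, d) -> float:
    """Unsigned volume of the tetrahedron (a, b, c, d) in Å³.

    Evaluated as |det(b−a, c−a, d−a)| / 6 — algebraically equal to the
    edge-length (Tartaglia / Cayley–Menger) form but cheaper and free of
    square roots. Coplanar corners give 0.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    return float(abs(np.linalg.det(np.stack([b - a, c - a, d - a])))) / 6.0


def tetrahedron_volume_cayley_menger(a, b, c, d) -> float:
    """Tetrahedron volume from the six pairwise corner distances.

    Tartaglia's rule: 288 V² equals the Cayley–Menger determinant of the
    squared distances d_xy². Used as the independent cross-check of the
    determinant form.
    """
    pts = np.array([a, b, c, d], dtype=np.longdouble)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    cm = np.ones((5, 5), dtype=np.longdouble)
    cm[0, 0] = 0.0
    cm[1:, 1:] = d2
    det = _det_longdouble(cm)
    return float(np.sqrt(max(det, 0.0) / np.longdouble(288.0)))


def _det_longdouble(m: np.ndarray) -> np.longdouble:
    """Determinant by partial-pivot elimination in extended precision.

    The Cayley–Menger determinant cancels heavily for thin tetrahedra;
    extended precision keeps the distance form within 1e-9 of the
    determinant form across random inputs.
    """
    m = m.astype(np.longdouble).copy()
    n = len(m)
    det = np.longdouble(1.0)
    for i in range(n):
        p = i + int(np.argmax(np.abs(m[i:, i])))
        if m[p, i] == 0:
            return np.longdouble(0.0)
        if p != i:
            m[[i, p]] = m[[p, i]]
            det = -det
        det *= m[i, i]
        m[i + 1 :] -= (m[i + 1 :, i : i + 1] / m[i, i]) * m[i : i + 1]
    return det


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume (Å³) enclosed by a closed, consistently oriented mesh.

    Empty meshes have volume 0. A mesh with inverted winding yields the
    negative of the true volume, which makes orientation bugs visible.
    """
    if mesh.is_empty:
        return 0.0
    if not is_closed(mesh):
        raise OpenMeshError("enclosed_volume requires a closed mesh")
    tri = mesh.triangle_corners()
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    centroid = tri.reshape(-1, 3).mean(axis=0)
    normal = np.cross(b - a, c - a)  # outward for CCW-from-outside winding
    t_c = (a + b + c) / 3.0
    dot = np.einsum("ij,ij->i", normal, t_c - centroid)
    ra, rb, rc = a - centroid, b - centroid, c - centroid
    v = np.abs(np.einsum("ij,ij->i", ra, np.cross(rb, rc))) / 6.0
    return float(np.sum(np.sign(dot) * v))


def volumetric_similarity(
    x: TriangleMesh,
    y: TriangleMesh,
    spacing: float = DEFAULT_SPACING,
) -> float:
    """V(x∩y) / min(V(x), V(y)) ∈ [0, 1] for two aligned closed regions."""
    vx, vy = enclosed_volume(x), enclosed_volume(y)
    if min(vx, vy) <= 0.0:
        raise UndefinedSimilarityError(
            "volumetric similarity is undefined for a zero-volume region"
        )
    vi = enclosed_volume(csg(x, y, "intersection", spacing))
    sim = vi / min(vx, vy)
    if sim > 1.0 + 1e-3 or sim < -1e-3:
        log.warning("volumetric similarity %.6f clipped to [0, 1]", sim)
    return float(min(max(sim, 0.0), 1.0))


def volumetric_distance(
    x: TriangleMesh,
    y: TriangleMesh,
    spacing: float = DEFAULT_SPACING,
) -> float:
    """1 − similarity: a symmetric dissimilarity, 0 for identical regions."""
    return 1.0 - volumetric_similarity(x, y, spacing)
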
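"""Geodesic subdivision of the icosahedron.

Shared helper for the icosphere fixture and for sampling sphere surfaces
(convex hulls of van der Waals spheres). Kept free of any engine code.
"""

from __future__ import annotations

import numpy as np

# Regular icosahedron with outward counterclockwise winding.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_VERTS /= np.linalg.norm(_ICO_VERTS[0])

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def unit_icosphere(subdivisions: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/faces of a unit geodesic sphere with consistent outward winding.

    Vertex count is ``10 * 4**subdivisions + 2``.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    verts = [tuple(v) for v in _ICO_VERTS]
    faces = [tuple(f) for f in _ICO_FACES]
    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                p = np.asarray(verts[i]) + np.asarray(verts[j])
                p /= np.linalg.norm(p)
                midpoint[key] = len(verts)
                verts.append(tuple(p))
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def unit_sphere_points(subdivisions: int = 3) -> np.ndarray:
    """Evenly distributed unit directions (geodesic vertices).

    subdivisions=2 gives 162 points, 3 gives 642.
    """
    return unit_icosphere(subdivisions)[0]
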
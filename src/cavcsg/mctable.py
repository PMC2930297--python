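"""The 256-case marching-cubes lookup table, generated from first principles.

Each lattice cube has 8 corners, each inside or outside the output region,
giving 2**8 = 256 corner-state cases. For every case this module derives a
triangulation of the boundary patch inside the cube:

1. On each of the six cube faces, the inside/outside states of the four face
   corners determine contour segments joining the crossed face edges. A face
   with four crossed edges is ambiguous (two diagonal corners inside); the
   fixed convention here always *separates* the inside corners. Because the
   rule depends only on the shared face's corner states, the two cubes
   adjacent to a face always agree — meshes assembled from the table are
   watertight by construction.
2. Segments are oriented so that the inside region lies to the left when the
   face is viewed from outside the cube; following them yields closed cycles
   on the cube surface.
3. Each cycle is fan-triangulated. A global orientation convention makes
   every triangle wind counterclockwise when viewed from outside the solid.

The table maps case index -> tuple of triangles, each a triple of cube-edge
indices (0..11). Crossing points on those edges supply the vertex positions.
"""

from __future__ import annotations

import numpy as np

# Corner i sits at (i & 1, i >> 1 & 1, i >> 2 & 1).
CORNERS = np.array([(i & 1, (i >> 1) & 1, (i >> 2) & 1) for i in range(8)])

# Cube edges grouped by axis; EDGE_AXIS/EDGE_BASE drive the lattice lookup.
EDGES: list[tuple[int, int]] = [
    (0, 1), (2, 3), (4, 5), (6, 7),   # x-parallel
    (0, 2), (1, 3), (4, 6), (5, 7),   # y-parallel
    (0, 4), (1, 5), (2, 6), (3, 7),   # z-parallel
]
EDGE_AXIS = np.array([0] * 4 + [1] * 4 + [2] * 4)
EDGE_BASE = np.array([CORNERS[a] for a, _ in EDGES])  # lower corner offset

_EDGE_OF_PAIR = {}
for _e, (_a, _b) in enumerate(EDGES):
    _EDGE_OF_PAIR[(_a, _b)] = _e
    _EDGE_OF_PAIR[(_b, _a)] = _e


def _face_cycles() -> list[list[int]]:
    """Corner cycles of the six faces, counterclockwise seen from outside."""
    faces = []
    for axis in range(3):
        for side in (0, 1):
            corners = [c for c in range(8) if CORNERS[c][axis] == side]
            normal = np.zeros(3)
            normal[axis] = 1.0 if side == 1 else -1.0
            u_ax, v_ax = [a for a in range(3) if a != axis]
            u_vec = np.zeros(3)
            u_vec[u_ax] = 1.0
            v_vec = np.cross(normal, u_vec)
            center = CORNERS[corners].mean(axis=0)
            ang = []
            for c in corners:
                rel = CORNERS[c] - center
                ang.append(np.arctan2(rel @ v_vec, rel @ u_vec))
            cyc = [c for _, c in sorted(zip(ang, corners))]
            faces.append(cyc)
    return faces


_FACES = _face_cycles()

# 2D face-plane coordinates of each face's corners, consistent with the CCW
# cycle above (used for orienting contour segments).
def _face_uv() -> list[np.ndarray]:
    uv = []
    for f_idx, cyc in enumerate(_FACES):
        axis, side = divmod(f_idx, 2)
        normal = np.zeros(3)
        normal[axis] = 1.0 if side == 1 else -1.0
        u_ax = [a for a in range(3) if a != axis][0]
        u_vec = np.zeros(3)
        u_vec[u_ax] = 1.0
        v_vec = np.cross(normal, u_vec)
        uv.append(np.array([[CORNERS[c] @ u_vec, CORNERS[c] @ v_vec] for c in cyc]))
    return uv


_FACE_UV = _face_uv()


def _segments_for_case(inside: np.ndarray) -> list[tuple[int, int]]:
    """Directed contour segments (from_edge, to_edge) over all six faces."""
    segs: list[tuple[int, int]] = []
    for cyc, uv in zip(_FACES, _FACE_UV):
        ins = [bool(inside[c]) for c in cyc]
        crossed = [k for k in range(4) if ins[k] != ins[(k + 1) % 4]]
        if not crossed:
            continue
        mids = {k: (uv[k] + uv[(k + 1) % 4]) / 2.0 for k in crossed}

        def directed(ka: int, kb: int, ref: np.ndarray) -> tuple[int, int]:
            # Orient the segment so the inside reference point is on its left.
            a, b = mids[ka], mids[kb]
            d = b - a
            left = np.array([-d[1], d[0]])
            if (ref - (a + b) / 2.0) @ left < 0:
                ka, kb = kb, ka
            ea = _EDGE_OF_PAIR[(cyc[ka], cyc[(ka + 1) % 4])]
            eb = _EDGE_OF_PAIR[(cyc[kb], cyc[(kb + 1) % 4])]
            return ea, eb

        if len(crossed) == 2:
            ref = np.mean([uv[k] for k in range(4) if ins[k]], axis=0)
            segs.append(directed(crossed[0], crossed[1], ref))
        else:
            # Ambiguous face: two diagonal inside corners, kept separated —
            # one corner-cutting segment around each inside corner.
            for k in range(4):
                if ins[k]:
                    segs.append(directed((k - 1) % 4, k, uv[k]))
    return segs


def _build_table() -> tuple[tuple[tuple[int, int, int], ...], ...]:
    table: list[tuple[tuple[int, int, int], ...]] = []
    for case in range(256):
        inside = np.array([(case >> i) & 1 for i in range(8)], dtype=bool)
        segs = _segments_for_case(inside)
        nxt: dict[int, int] = {}
        for a, b in segs:
            assert a not in nxt, "non-manifold contour"
            nxt[a] = b
        tris: list[tuple[int, int, int]] = []
        seen: set[int] = set()
        for start in list(nxt):
            if start in seen:
                continue
            cycle = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                cycle.append(cur)
                seen.add(cur)
                cur = nxt[cur]
            for i in range(1, len(cycle) - 1):
                tris.append((cycle[0], cycle[i], cycle[i + 1]))
        table.append(tuple(tris))
    return tuple(table)


def _orient_table(table):
    """Fix the global winding so triangles face away from the solid."""
    # Case 1: only corner 0 inside; its single triangle must point away
    # from corner 0, i.e. its normal must have positive sum of components.
    (tri,) = table[1]
    mids = (CORNERS[[EDGES[e][0] for e in tri]] + CORNERS[[EDGES[e][1] for e in tri]]) / 2.0
    n = np.cross(mids[1] - mids[0], mids[2] - mids[0])
    if n.sum() < 0:
        return tuple(tuple(t[::-1] for t in tris) for tris in table)
    return table


TRI_TABLE: tuple[tuple[tuple[int, int, int], ...], ...] = _orient_table(_build_table())


def table_is_complete() -> bool:
    """All 256 corner states present; empty patches only for uniform states."""
    return (
        len(TRI_TABLE) == 256
        and TRI_TABLE[0] == ()
        and TRI_TABLE[255] == ()
        and all(len(TRI_TABLE[c]) > 0 for c in range(1, 255))
    )
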
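"""Deterministic analytic solids and toy sphere-atom "proteins".

These stand in for downloaded structures in every test: icospheres and boxes
with known volumes, and parametric toy proteins — grids of 1.7 Å pseudo-atoms
packed into a ball, with cylindrical pockets bored in and ground truth
recorded (mouth position, depth, approximate volume, lining residues).
Everything is reproducible from (recipe, parameters, seed) alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._icosa import unit_icosphere
from .mesh import TriangleMesh
from .structure import Structure

__all__ = ["icosphere", "box_mesh", "ToyProtein", "toy_protein"]


def icosphere(center=(0.0, 0.0, 0.0), radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Geodesic sphere mesh with outward winding; 10·4^s + 2 vertices."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    v, f = unit_icosphere(subdivisions)
    return TriangleMesh(np.asarray(center, dtype=float) + radius * v, f)


def box_mesh(min_corner, max_corner) -> TriangleMesh:
    """Axis-aligned box as 12 outward-wound triangles."""
    lo = np.asarray(min_corner, dtype=float)
    hi = np.asarray(max_corner, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("max_corner must exceed min_corner on every axis")
    verts = np.array(
        [
            (lo[0], lo[1], lo[2]), (hi[0], lo[1], lo[2]),
            (lo[0], hi[1], lo[2]), (hi[0], hi[1], lo[2]),
            (lo[0], lo[1], hi[2]), (hi[0], lo[1], hi[2]),
            (lo[0], hi[1], hi[2]), (hi[0], hi[1], hi[2]),
        ]
    )
    faces = np.array(
        [
            (0, 2, 1), (1, 2, 3),  # z = lo
            (4, 5, 6), (5, 7, 6),  # z = hi
            (0, 1, 4), (1, 5, 4),  # y = lo
            (2, 6, 3), (3, 6, 7),  # y = hi
            (0, 4, 2), (2, 4, 6),  # x = lo
            (1, 3, 5), (3, 7, 5),  # x = hi
        ],
        dtype=np.int64,
    )
    return TriangleMesh(verts, faces)


@dataclass
class ToyProtein:
    """A sphere-atom structure with engineered pockets and ground truth."""

    structure: Structure
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def truth_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(self.ground_truth, indent=2, default=default, sort_keys=True)


_RECIPES = ("cup", "two-pockets", "channel")


def toy_protein(
    recipe: str = "cup",
    seed: int = 0,
    radius: float = 8.0,
    pocket_radius: float = 3.0,
    pocket_depth: float = 6.0,
    atom_radius: float = 1.7,
    packing: float = 1.6,
    jitter: float = 0.05,
) -> ToyProtein:
    """Build a toy protein: a ball of pseudo-atoms with pocket(s) bored in.

    ``cup``: one cylindrical pocket opening along +z.
    ``two-pockets``: opposed pockets along +z and −z (disjoint patches).
    ``channel``: a cylinder bored straight through the ball.

    Atoms are packed on a cubic grid (spacing < 2·r_atom/√3, so the interior
    has no voids), jittered deterministically by ``seed``. Atoms whose sphere
    would enter a pocket cylinder are removed. Pocket-wall and pocket-floor
    atoms get singleton residues so lining-residue ground truth is exact;
    bulk atoms are grouped five per residue.
    """
    if recipe not in _RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose one of {_RECIPES}")
    rng = np.random.default_rng(seed)
    grid = np.arange(-radius, radius + packing / 2, packing)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    centers = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    centers = centers[np.linalg.norm(centers, axis=1) <= radius]
    centers = centers + rng.uniform(-jitter, jitter, size=centers.shape)

    r_excl = pocket_radius + atom_radius
    z_floor = radius - pocket_depth
    radial = np.linalg.norm(centers[:, :2], axis=1)
    z = centers[:, 2]

    if recipe == "cup":
        in_pocket = (radial < r_excl) & (z > z_floor)
    elif recipe == "two-pockets":
        in_pocket = (radial < r_excl) & ((z > z_floor) | (z < -z_floor))
    else:  # channel
        in_pocket = radial < r_excl
    keep = centers[~in_pocket]
    radial = np.linalg.norm(keep[:, :2], axis=1)
    z = keep[:, 2]

    wall_band = packing * 1.25
    if recipe == "cup":
        lining_mask = (radial < r_excl + wall_band) & (z > z_floor - wall_band)
    elif recipe == "two-pockets":
        lining_mask = (radial < r_excl + wall_band) & (np.abs(z) > z_floor - wall_band)
    else:
        lining_mask = radial < r_excl + wall_band

    # Stable ordering: lining atoms first (singleton residues), then bulk.
    order = np.argsort(~lining_mask, kind="stable")
    keep = keep[order]
    lining_mask = lining_mask[order]
    n_lining = int(lining_mask.sum())
    resseq = np.empty(len(keep), dtype=int)
    resseq[:n_lining] = np.arange(1, n_lining + 1)
    resseq[n_lining:] = n_lining + 1 + np.arange(len(keep) - n_lining) // 5

    structure = Structure(
        coords=keep,
        radii=np.full(len(keep), atom_radius),
        element=np.array(["C"] * len(keep), dtype=object),
        chain=np.array(["A"] * len(keep), dtype=object),
        resseq=resseq,
        icode=np.array([""] * len(keep), dtype=object),
        resname=np.array(["TOY"] * len(keep), dtype=object),
        atom_name=np.array([f"C{i % 999}" for i in range(len(keep))], dtype=object),
        source_id=f"toy-{recipe}-{seed}",
    )
    # Guaranteed-lining core: residues whose atoms form the pocket floor (or,
    # for the channel, the mid-height wall ring). The extraction pipeline's
    # lining list must contain all of these; the surrounding wall-band atoms
    # (singleton residues above) may or may not be picked up depending on
    # where the 2 Å patch ends.
    radial_k = np.linalg.norm(keep[:, :2], axis=1)
    z_k = keep[:, 2]
    if recipe == "cup":
        core = (radial_k < pocket_radius) & (z_k > z_floor - 1.2 * packing) & (z_k < z_floor)
    elif recipe == "two-pockets":
        core = (radial_k < pocket_radius) & (np.abs(z_k) > z_floor - 1.2 * packing) & (
            np.abs(z_k) < z_floor
        )
    else:  # channel: innermost wall ring near the middle
        core = (radial_k < r_excl + packing) & (np.abs(z_k) < packing)
    core_residues = sorted({("A", int(s)) for s in resseq[core]})

    n_pockets = {"cup": 1, "two-pockets": 2, "channel": 1}[recipe]
    truth = {
        "recipe": recipe,
        "seed": seed,
        "pocket_radius": pocket_radius,
        "pocket_depth": pocket_depth,
        "mouth_centers": {
            "cup": [[0.0, 0.0, radius]],
            "two-pockets": [[0.0, 0.0, radius], [0.0, 0.0, -radius]],
            "channel": [[0.0, 0.0, radius], [0.0, 0.0, -radius]],
        }[recipe],
        "n_pockets": n_pockets,
        "approx_pocket_volume": float(np.pi * pocket_radius**2 * pocket_depth) * n_pockets,
        "lining_residues": core_residues,
        "wall_band_residues": [("A", int(s)) for s in resseq[:n_lining]],
    }
    return ToyProtein(structure=structure, ground_truth=truth)
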
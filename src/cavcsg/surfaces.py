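"""Watertight molecular (solvent-excluded) and envelope surfaces.

The solvent-excluded solid is the morphological closing of the union of
van der Waals spheres by a probe ball: dilate the union by the probe radius
(exact — inflate every atom radius), then erode by the probe (an exact
Euclidean distance transform of the accessible region). The boundary is
extracted by marching cubes on the resulting signed field. A 1.4 Å probe
gives the molecular surface; a 5.0 Å probe gives the "envelope" surface
that spans cavity mouths. Surfaces of single residues use the same
construction on the residue's atoms alone.

Because the closing of a union of balls contains the union itself, the
field is the pointwise maximum of the exact sphere-union field and the
probe-eroded distance field; single isolated atoms therefore reproduce
their van der Waals sphere exactly (up to lattice interpolation).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .csg import DEFAULT_SPACING, Lattice, build_lattice, isosurface
from .exceptions import CavCsgError
from .mesh import TriangleMesh
from .structure import Structure

__all__ = [
    "molecular_surface",
    "envelope_surface",
    "residue_surface",
    "sphere_union_mesh",
    "sphere_union_field",
]

DEFAULT_PROBE = 1.4  # Å, water-sized probe for the molecular surface
ENVELOPE_PROBE = 5.0  # Å, large probe spanning cavity mouths


def sphere_union_field(
    centers: np.ndarray,
    radii: np.ndarray,
    lattice: Lattice,
    inflate: float = 0.0,
) -> np.ndarray:
    """Signed field max_i(r_i + inflate − |p − c_i|), positive inside the union.

    Evaluated exactly on local blocks around each sphere; far from every
    sphere the value saturates at a large negative constant (only the sign
    matters there).
    """
    centers = np.atleast_2d(centers)
    radii = np.asarray(radii, dtype=float) + inflate
    dims = lattice.dims
    sp = lattice.spacing
    origin = np.asarray(lattice.origin)
    field = np.full(dims, -1e6)
    margin = 2.5 * sp
    ax = lattice.axes()
    for c, r in zip(centers, radii):
        lo_i = np.maximum(np.ceil((c - r - margin - origin) / sp).astype(int), 0)
        hi_i = np.minimum(np.floor((c + r + margin - origin) / sp).astype(int), np.array(dims) - 1)
        if np.any(hi_i < lo_i):
            continue
        sl = tuple(slice(lo_i[k], hi_i[k] + 1) for k in range(3))
        dx = ax[0][sl[0]] - c[0]
        dy = ax[1][sl[1]] - c[1]
        dz = ax[2][sl[2]] - c[2]
        dist = np.sqrt(
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        np.maximum(field[sl], r - dist, out=field[sl])
    return field


def _ses_field(structure: Structure, probe: float, lattice: Lattice) -> np.ndarray:
    vdw = sphere_union_field(structure.coords, structure.radii, lattice)
    if probe <= 0.0:
        return vdw
    accessible = (
        sphere_union_field(structure.coords, structure.radii, lattice, inflate=probe) > 0
    )
    # Erode the accessible solid by the probe: distance (to the nearest
    # non-accessible voxel) minus the probe radius. The half-spacing offset
    # compensates the grid-sampled complement (distances are measured to
    # voxel centers, overshooting the true interface by ~spacing/2).
    dist_in = ndimage.distance_transform_edt(accessible, sampling=lattice.spacing)
    eroded = dist_in - 0.5 * lattice.spacing - probe
    return np.maximum(vdw, eroded)


def _surface_lattice(structure: Structure, probe: float, spacing: float) -> Lattice:
    if structure.n_atoms == 0:
        raise CavCsgError("cannot build a surface for an empty structure")
    pad = float(structure.radii.max()) + probe + 3.0 * spacing
    bounds = np.array([structure.coords.min(axis=0), structure.coords.max(axis=0)])
    return build_lattice([], spacing=spacing, padding=pad, bounds=bounds)


def molecular_surface(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    spacing: float = DEFAULT_SPACING,
) -> TriangleMesh:
    """Watertight solvent-excluded surface of all atoms (default 1.4 Å probe)."""
    lattice = _surface_lattice(structure, probe, spacing)
    return isosurface(_ses_field(structure, probe, lattice), lattice)


def envelope_surface(
    structure: Structure,
    probe: float = ENVELOPE_PROBE,
    spacing: float = DEFAULT_SPACING,
) -> TriangleMesh:
    """Large-probe (default 5.0 Å) surface that spans pocket mouths."""
    return molecular_surface(structure, probe=probe, spacing=spacing)


def residue_surface(
    structure: Structure,
    residue_id,
    probe: float = DEFAULT_PROBE,
    spacing: float = DEFAULT_SPACING,
) -> TriangleMesh:
    """Solvent-excluded surface of one residue's atoms in isolation."""
    return molecular_surface(structure.select_residues([residue_id]), probe, spacing)


def sphere_union_mesh(
    centers,
    radii,
    spacing: float = DEFAULT_SPACING,
) -> TriangleMesh:
    """Watertight boundary of a union of spheres (e.g. subsite spheres)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(centers),))
    if len(centers) == 0:
        raise CavCsgError("sphere union needs at least one sphere")
    bounds = np.array(
        [(centers - radii[:, None]).min(axis=0), (centers + radii[:, None]).max(axis=0)]
    )
    lattice = build_lattice([], spacing=spacing, padding=3.0 * spacing, bounds=bounds)
    return isosurface(sphere_union_field(centers, radii, lattice), lattice)
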
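# cavcsg — constructive solid geometry on protein binding cavities

Protein binding sites with similar shapes bind similar ligands, but
comparing cavity *shapes* quantitatively is harder than comparing sequences
or backbones: a cavity is a three-dimensional solid, not a string. `cavcsg`
is a toolkit for structural bioinformaticians who want to treat binding
cavities as first-class geometric objects. It represents cavities (and
proteins, residues, and probe spheres) as watertight triangle-mesh solids,
combines them with boolean operations — union, intersection, difference —
on a cubic lattice via marching cubes, and measures the enclosed volumes.
On top of those primitives it builds the comparative analyses: clustering
cavities by shape, profiling which residues force two aligned cavities to
differ, and isolating subregions conserved across (or distinguishing
between) protein families.

## The method

**Regions and membership.** A region A is the solid bounded by a closed,
consistently oriented triangle mesh S_A (triangle corners counterclockwise
seen from outside). A point p is inside A iff a generic ray from p crosses
S_A an odd number of times.

**Boolean operations.** To combine regions A and B, an axis-aligned cubic
lattice (default spacing 0.5 Å) is laid over them. Every lattice point is
labelled inside or outside the *output* region (inside A ∧ inside B for
intersection, ∨ for union, ∧¬ for difference). Each lattice segment whose
endpoints straddle the output region exits it at a crossing point p₀ on
S_A or S_B; when both surfaces cross, the crossing that actually bounds the
output is selected (for an intersection: the crossing of one surface lying
inside the other solid). A 256-case lookup table — one entry per
inside/outside state of a cube's 8 corners — connects the crossing points
of each lattice cube into outward-oriented triangles. The result is a
closed mesh approximating the boolean result at lattice resolution.

**Volume.** The volume of a closed region is computed with the Surveyor's
Formula: each boundary triangle t forms a tetrahedron with the global
corner centroid c; its volume v(T) (Tartaglia's rule — the 3-D analogue of
Heron's formula) is added when t faces away from c and subtracted when it
faces towards c. The signed sum is exact for polyhedra.

**Cavity extraction.** From a structure, a solvent-excluded surface
(1.4 Å probe) and an "envelope" surface (5.0 Å probe) are generated as
morphological closings of the van der Waals sphere union. Patches of the
molecular surface lying more than 2 Å beneath the envelope mark cavity
bases; the patch nearest user-supplied seed evidence is chosen, its lining
residues collected, and the cavity carved as

    cavity = (convex hull of lining-residue spheres − protein) ∩ envelope.

Subsites (e.g. the S1 specificity pocket of serine proteases) are cut out
by intersecting a cavity with a union of 5 Å spheres placed on ligand
atoms or conserved waters.

**Comparison.** Aligned cavities x, y are compared by volumetric
similarity V(x∩y) / min(V(x), V(y)) — the overlap relative to its maximum
attainable value — and clustered by UPGMA on the complementary distance.
Per-residue profiles measure V(S_a ∩ y) for every residue surface S_a of
one structure against the cavities of others; residues with large overlap
are the ones that reshape the binding site. Conserved and varying regions
across sets come from folds of intersection, union and difference, e.g.
`(∩ family1) − (∪ family2)`.

## Worked example

`python examples/boolean_volumes.py` — two 6 Å spheres, 6 Å apart, at
0.5 Å resolution:

```
V(A) = 902.8 Å³, V(B) = 902.8 Å³
V(A∪B) = 1519.4, V(A∩B) = 280.3, V(A−B) = 617.5 Å³
closed-form lens volume       = 282.7 Å³
inclusion–exclusion residual  = -6.0 Å³
difference decomposition      = -5.1 Å³
```

The lattice intersection is within ~1% of the analytic lens volume, and
union + intersection balances V(A) + V(B) to well under 1%.

`python examples/extract_cavity.py` — the full pipeline on a toy protein
with an engineered cylindrical pocket (radius 3 Å, depth 6 Å):

```
toy protein: 439 atoms, pocket r=3 Å, depth 6 Å
molecular surface: 6868 triangles, 2788 Å³
envelope surface:  6568 triangles, 2954 Å³
patches > 2 Å under the envelope: 1 (area 41.9 Å²)
lining residues: 48 (e.g. A:16 …)
hull volume   = 783.3 Å³
cavity volume = 113.6 Å³ (3 fragment(s) removed)
```

The extracted cavity volume agrees with an independent voxel-counting
oracle of the same construction to ~2%. The other examples cluster
synthetic cavity families (`cluster_cavities.py`), profile per-residue
overlaps (`residue_profile.py`), and compose conserved/varying regions
(`conserved_regions.py`).

A thin CLI mirrors the library (`cavcsg csg|volume|simdist|surface|cavity|
subsite|compare|profile|conserved|union|carve|fixtures`); run
`cavcsg --help`.

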
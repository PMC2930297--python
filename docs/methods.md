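# Methods

This note documents the models, algorithms, parameters and numerical
conventions behind `cavcsg`, and what the synthetic fixtures do and do not
establish about behaviour on real structures.

## Solid regions and membership

A region is the solid bounded by a `TriangleMesh`: coordinates in Å in the
right-handed PDB frame, triangle corners counterclockwise when viewed from
outside, so cross-product normals point outward. The operative
watertightness condition used as a precondition throughout is that the
boundary operator vanishes — every directed edge is cancelled by its
reverse. This is what crossing-parity membership and the Surveyor's
Formula actually require. It is slightly weaker than 2-manifoldness:
boolean results that are tangent to themselves can pinch along an edge
shared by four triangles (balanced two-and-two in direction). `validate`
reports the strict picture (an edge shared by exactly two triangles,
consistent winding, boundary-edge and component counts, area) so such
pinches remain visible.

Point-in-solid queries cast a ray in a random direction from a seeded
generator (default seed 0) and take crossing parity. A hit within 1e−9
(relative) of a triangle edge or vertex, a nearly edge-on triangle among
the candidates, or an origin on the surface makes the draw degenerate; the
direction is redrawn, up to 32 times, then an error is raised. Candidate
triangles are pruned by a vectorized ray/bounding-box slab test; the bulk
classifier below never casts per-point rays, so no hierarchical index is
built for single queries.

## Boolean operations on a cubic lattice

`csg(A, B, op, spacing)` proceeds in four steps.

**Lattice.** Axis-aligned, cubic, default spacing 0.5 Å (the working
resolution for all cavity-scale results; 0.7 Å is used for the toy-protein
pipeline in tests to keep runtimes short, with accuracy verified against
oracles at that spacing). The origin is snapped down to integer multiples
of the spacing in the global frame, so lattices built by different calls
are commensurate and n-ary folds do not depend on operand order beyond
lattice tolerance. Padding defaults to twice the spacing. Bounds cover
only what the operation needs (the bounding-box intersection for ∩, A's
box for −, the union of boxes for ∪). A lattice above 2·10⁸ points raises
a resource error advising coarser spacing.

**Classification.** All lattice points on one axis-parallel line share a
ray, so membership for the whole grid is computed per line: every triangle
is rasterized over the lines crossing its projection, each accepted line
receives the crossing coordinate by barycentric interpolation, and parity
along the line labels the points. Acceptance uses exact orientation-sign
edge functions with a Pineda-style tie rule (equivalent to a consistent
virtual perturbation of the line), so a shared edge between consistently
wound triangles is counted exactly once on the sheet and an even number of
times at silhouette folds — parity is watertight. Because meshes produced
by earlier marching-cubes passes have vertices lying *exactly* on lattice
lines of any commensurate lattice, vertex coordinates in lattice units are
snapped to integers when within 1e−9, making ties exact rather than
rounding noise. A lattice point carrying a surface crossing exactly on it
is labelled inside (closed-solid convention), and such a crossing is
registered on both adjacent segments; this keeps inputs whose planar faces
coincide with lattice planes (axis-aligned boxes, previous CSG outputs)
both closed and metrically correct. As a final guard, output labels on the
outermost lattice shell are cleared (the padded bounds always contain the
true output region, so an inside border label could only be a degenerate
sweep artifact; occurrences are logged).

**Crossing points.** On each straddling segment the candidate crossings of
S_A and S_B are walked in order, toggling membership in A and B; the first
candidate at which the output state flips is p₀. For an intersection this
reduces to the rule "take p_A if p_A is inside B, else p_B"; re-labelling
makes the same walk serve union and difference, and it handles repeated
crossings. If floating-point gaps leave no candidate (a few per million
segments, logged), p₀ falls back to the segment midpoint. Offsets are
clamped to [1e−6, 1−1e−6] of the segment so vertices are never emitted on
lattice points.

**Triangulation.** The 256-case cube table is *generated at import*, not
copied: for each corner state, contour segments are derived per face (an
ambiguous face with four crossed edges always *separates* its two diagonal
inside corners), oriented with the inside on the left viewed from outside,
traced into closed cycles, and fan-triangulated; a single global
orientation convention (fixed by the one-corner case) makes every triangle
wind counterclockwise from outside. Because the per-face rule depends only
on the shared face's corner states, adjacent cubes always agree and the
assembled surface is closed by construction — this is verified
exhaustively for all 256 cases embedded among complement neighbours, and
on randomized sphere batteries. The same label/table machinery extracts
isosurfaces of scalar fields, with crossings placed by linear
interpolation.

Resolution behaviour: volume error is second order in the spacing. Sharp
creases (box edges, lens rims) chamfer at lattice scale, so thin features
need a spacing a few times smaller than the feature; the box-overlap tests
run at 0.05 Å for 0.5 Å features, and sphere batteries use radii ≥ 3 Å at
0.5 Å. Empty results are empty meshes, volume 0.

## Volumes

`enclosed_volume` implements the centroid bookkeeping: per triangle, the
outward normal (from winding), the dot product with (t_c − c) for the
corner centroid c, and the tetrahedron volume by the determinant form
|det(b−a, c−a, d−a)|/6, added or subtracted by the sign. The distance-only
Tartaglia/Cayley–Menger form is provided separately as a cross-check; its
5×5 determinant is evaluated by partial-pivot elimination in extended
precision because the cancellation for thin tetrahedra would otherwise
cost ~8 digits. Inverted winding yields the negative volume by design.

Volumetric similarity is V(x∩y)/min(V(x),V(y)), clipped to [0,1] (clips
beyond 1e−3 are logged); the clustering distance is 1 − similarity, the
complement demanded by an agglomerative method that needs a dissimilarity.

## Molecular and envelope surfaces

The solvent-excluded solid is the morphological closing of the van der
Waals sphere union U by the probe ball (1.4 Å molecular, 5.0 Å envelope).
Dilation is exact — inflate every atomic radius by the probe; erosion uses
the Euclidean distance transform of the accessible occupancy grid, with a
half-spacing offset compensating the voxel-centre sampling of the
interface. The final field is max(exact sphere-union field, eroded
distance field): the closing always contains U, so isolated atoms
reproduce their van der Waals spheres exactly up to interpolation, while
the EDT term fills probe-inaccessible necks and pocket mouths. Marching
cubes on this field (same table, commensurate lattice) yields the surface.
Closing is monotone in probe radius, so the envelope solid contains the
molecular solid up to lattice tolerance.

Default radii (Å): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, default 1.70,
overridable by a two-column config. Hydrogens are always dropped on
parsing; waters and HETATM records are excluded unless requested; altloc
sites resolve to the highest-occupancy alternate by default.

## Cavity extraction

The 2 Å patch rule uses *exact* point-to-triangle distances from molecular
surface vertices to the envelope (nearest-centroid kd-tree candidates,
k = 24, then exact distances — vertex-to-vertex distances would
overestimate). Qualifying triangles (all three corners beyond the
threshold) are grouped into edge-connected patches, sorted by area. Patch
selection is deterministic: smallest mean distance from patch triangle
centroids to the seed atoms/point, ties to the larger patch; a
`patch_index` override exists. Lining residues take, for each patch
triangle centroid, the atom minimizing centre distance minus radius
(surface distance), ties to the lower chain/residue number; the list is
de-duplicated and sorted. The convex hull of the lining residues' spheres
is the qhull hull of geodesic surface samples — 642 per sphere by default
(an inscribed approximation with ~0.3% volume deficit; 162 samples leave
~1–2%, too close to the 3% test bands, hence the denser default; density
is configurable). Facets are oriented outward via the hull plane
equations. The cavity is (hull − molecular) ∩ envelope; disconnected
fragments are removed keeping the largest by *surface area*, and the count
removed is recorded. Subsites intersect a cavity with a sphere-union
isosurface (default radius 5 Å per sphere).

## Comparative analyses

Pairwise distances are computed once per unordered pair (symmetry is
structural). UPGMA is implemented directly: unweighted average linkage
with cluster-size weights, merge height d/2, ties broken by the
lexicographically smallest pair of cluster leader labels; heights are
non-decreasing, ultrametric inputs are recovered exactly (cophenetic
round-trip), and agreement with scipy's average linkage is asserted in
tests. Trees serialize to Newick with branch lengths. Per-residue overlap
profiles build each residue's surface in isolation and intersect it with
each target cavity; the per-residue mean and *population* standard
deviation across targets are tabulated (TSV: chain, resnum, icode,
resname, per-target Å³, mean, sd). Conserved/union/set-difference regions
are left folds of the binary operation in input order; thanks to the
global origin snapping, fold order moves results only within lattice
tolerance.

Structures are consumed pre-aligned, or carry user-supplied 4×4 rigid
transforms (`Structure.transformed` / `TriangleMesh.transformed`);
reproducing any particular external alignment tool is out of scope.

## Synthetic fixtures and what they show

The fixtures module generates geodesic spheres (volume → 4πr³/3 with
subdivision), boxes, and toy proteins: 1.7 Å pseudo-atoms on a jittered
1.6 Å cubic grid (dense enough that the interior has no voids) packed into
an 8 Å ball, with cylindrical pockets (default radius 3 Å, depth 6 Å)
bored along ±z ("cup", "two-pockets", "channel"). Pocket-floor atoms carry
singleton residues whose ids are recorded as the guaranteed lining core;
wall-band atoms are singletons too, bulk atoms are grouped five per
residue. Ground truth (mouth centres, depth, π r² h volume estimate, core
lining) is derived from the generating parameters, and every fixture is a
pure function of (recipe, parameters, seed).

These fixtures exercise the full pipeline with known answers, but they are
idealized: atoms are uniform carbons, pockets are convex cylinders, and
there is no conformational noise, no heteroatoms, no surface roughness at
sub-atomic scale. Passing tests demonstrate geometric correctness of the
machinery, not biological accuracy of cavity definitions on real PDB
entries — on real structures the quality of the input alignment and of the
seed evidence dominates.

The independent oracles share no code with the engine: membership by
generalized winding numbers (van Oosterom–Strackee solid angles, optional
numba acceleration), volumes by counting grid points, overlaps by closed
forms (sphere–sphere lens, box overlap, capsule hulls). Oracle grids use
voxel centres offset half a step from lattice multiples so the two
discretizations are unrelated.

## Problem sizes and tolerances in the shipped checks

Sphere batteries use radii 4–6 Å (cavity-scale volumes of 270–900 Å³) at
0.5 Å; lens accuracy is checked for r = 6 Å at separations 2–10 Å (≤ 3%);
box overlaps at 0.05 Å (≤ 3%); volume laws over 50 random pairs (≤ 3% of
the larger operand); Surveyor volumes to 0.5% of closed forms and 1e−9
under rigid motion; Tartaglia forms agree to 1e−9 over 1000 random
tetrahedra; engine-vs-oracle deviations stay within 2·spacing·min(area);
the cup cavity volume matches its voxel oracle within 10% and recovers
the full lining core. The acceptance script reruns all of these from
scratch with a user-supplied seed.

## Known limitations

- Booleans are lattice approximations, not exact mesh arithmetic; features
  thinner than ~2 spacings are not resolved, and sharp creases chamfer.
- Tangencies can produce non-manifold pinch edges (watertight in the
  boundary-operator sense; reported by `validate`).
- The SES erosion uses a grid EDT, so neck geometry carries O(spacing)
  error even though isolated-atom surfaces are exact.
- Self-intersecting input meshes and mesh repair are unsupported: inputs
  must be watertight (validate reports defects; repair is out of scope).
- UPGMA tie-breaking is deterministic but need not match other
  implementations' ordering of equivalent subtrees.
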
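"""Comparative cavity analysis.

All-pairs volumetric distances with UPGMA (average-linkage) clustering;
per-residue overlap profiles that locate the amino acids responsible for
shape differences between aligned cavities; and composition of conserved /
varying subregions by repeated CSG intersection, union and difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cavity import CavityRegion
from .csg import DEFAULT_SPACING, csg, csg_many
from .exceptions import CavCsgError
from .mesh import TriangleMesh
from .structure import Structure, residue_id_str
from .surfaces import residue_surface
from .volume import enclosed_volume, volumetric_distance

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "OverlapProfile",
    "pairwise_distances",
    "upgma",
    "residue_overlap_profile",
    "conserved_region",
    "union_region",
    "set_difference_region",
]


def _mesh_of(region) -> TriangleMesh:
    return region.mesh if isinstance(region, CavityRegion) else region


def _label_of(region, i: int) -> str:
    if isinstance(region, CavityRegion) and region.source_id:
        return region.source_id
    return f"region{i}"


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix of volumetric distances, zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6f"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy())


@dataclass
class DendrogramNode:
    """Node of a rooted ultrametric tree (leaf when children is empty)."""

    height: float
    label: str | None = None
    children: list["DendrogramNode"] = field(default_factory=list)
    size: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for ch in self.children for l in ch.leaves()]


@dataclass
class Dendrogram:
    """Rooted UPGMA tree; merge heights are non-decreasing toward the root."""

    root: DendrogramNode
    labels: list[str]

    def to_newick(self) -> str:
        def emit(node: DendrogramNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:.10g}"
            inner = ",".join(emit(ch, node.height) for ch in node.children)
            return f"({inner}):{blen:.10g}"

        inner = ",".join(emit(ch, self.root.height) for ch in self.root.children)
        return f"({inner});"

    def merge_heights(self) -> list[float]:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node.height)
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return sorted(out)

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (2 × height of the lowest common
        ancestor), for round-trip checks against the input matrix."""
        n = len(self.labels)
        pos = {l: i for i, l in enumerate(self.labels)}
        vals = np.zeros((n, n))

        def walk(node):
            if node.is_leaf:
                return [node.label]
            groups = [walk(ch) for ch in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            vals[pos[a], pos[b]] = vals[pos[b], pos[a]] = 2.0 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return DistanceMatrix(labels=list(self.labels), values=vals)


def pairwise_distances(
    cavities: Sequence,
    spacing: float = DEFAULT_SPACING,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Volumetric distance 1 − V(x∩y)/min(V(x), V(y)) for all cavity pairs."""
    meshes = [_mesh_of(c) for c in cavities]
    if len(meshes) < 2:
        raise CavCsgError("pairwise distances need at least two cavities")
    if labels is None:
        labels = [_label_of(c, i) for i, c in enumerate(cavities)]
    n = len(meshes)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = volumetric_distance(meshes[i], meshes[j], spacing)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=list(labels), values=vals)


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a dissimilarity matrix.

    Cluster-pair distances are the unweighted means over member pairs;
    merge height is half the merge distance, so cophenetic distances of an
    ultrametric input are recovered exactly. Ties are broken by the
    lexicographically smallest pair of cluster leader labels.
    """
    if np.any(~np.isfinite(matrix.values)):
        raise CavCsgError("distance matrix contains NaN/inf entries")
    n = len(matrix.labels)
    if n < 2:
        raise CavCsgError("UPGMA needs at least two items")
    d = {(i, j): float(matrix.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    nodes = {i: DendrogramNode(height=0.0, label=matrix.labels[i]) for i in range(n)}
    leader = {i: matrix.labels[i] for i in range(n)}  # smallest member label
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = tuple(sorted((leader[i], leader[j])))
                cand = (d[(min(i, j), max(i, j))], key)
                if best is None or cand < best[0:2]:
                    best = (cand[0], cand[1], i, j)
        dist, _, i, j = best
        merged = DendrogramNode(
            height=dist / 2.0,
            children=[nodes[i], nodes[j]],
            size=nodes[i].size + nodes[j].size,
        )
        nodes[next_id] = merged
        leader[next_id] = min(leader[i], leader[j])
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            ni, nj = nodes[i].size, nodes[j].size
            d[(min(k, next_id), max(k, next_id))] = (ni * dik + nj * djk) / (ni + nj)
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1
    root = nodes[next_id - 1]
    return Dendrogram(root=root, labels=list(matrix.labels))


@dataclass
class OverlapProfile:
    """Per-residue intersection volumes of one structure against target cavities.

    The table has one row per residue of the probe structure and one column
    per target cavity (Å³), plus the mean and population standard deviation
    across targets. Residues with large mean overlap are the ones forcing
    the probe's own cavity to differ in shape from the targets.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.3f")

    @property
    def target_columns(self) -> list[str]:
        fixed = {"chain", "resnum", "icode", "resname", "mean", "sd"}
        return [c for c in self.table.columns if c not in fixed]

    def mean_overlap(self, residue_ids) -> float:
        """Mean of the per-residue means over the given residues."""
        sel = self.table.set_index(
            self.table.apply(lambda r: (r["chain"], int(r["resnum"]), r["icode"]), axis=1)
        )
        keys = [(str(c), int(n), str(i)) for c, n, i in residue_ids]
        return float(sel.loc[keys]["mean"].mean())


def residue_overlap_profile(
    structure: Structure,
    targets: Sequence,
    spacing: float = DEFAULT_SPACING,
    probe: float = 1.4,
) -> OverlapProfile:
    """V(S_a ∩ y) for every residue a and every target cavity y.

    The residue surface S_a is built for each amino acid in isolation; its
    CSG intersection with each aligned target cavity is measured with the
    Surveyor's Formula. Mean and population SD are taken across targets.
    """
    if structure.n_atoms == 0:
        raise CavCsgError("empty structure")
    if not targets:
        raise CavCsgError("no target cavities")
    target_meshes = [_mesh_of(t) for t in targets]
    names = [_label_of(t, i) for i, t in enumerate(targets)]
    rows = []
    for rid in structure.residue_ids():
        surf = residue_surface(structure, rid, probe=probe, spacing=spacing)
        vols = []
        for y in target_meshes:
            inter = csg(surf, y, "intersection", spacing)
            vols.append(enclosed_volume(inter))
        vols = np.array(vols)
        rows.append(
            {
                "chain": rid[0],
                "resnum": rid[1],
                "icode": rid[2],
                "resname": structure.residue_name(rid),
                **{nm: v for nm, v in zip(names, vols)},
                "mean": float(vols.mean()),
                "sd": float(vols.std()),  # population SD across targets
            }
        )
    return OverlapProfile(table=pd.DataFrame(rows))


def conserved_region(cavities: Sequence, spacing: float = DEFAULT_SPACING) -> TriangleMesh:
    """Region shared by all cavities: repeated CSG intersection (left fold)."""
    meshes = [_mesh_of(c) for c in cavities]
    if len(meshes) < 1:
        raise CavCsgError("conserved_region needs at least one cavity")
    return csg_many(meshes, "intersection", spacing)


def union_region(cavities: Sequence, spacing: float = DEFAULT_SPACING) -> TriangleMesh:
    """Region occupied by at least one cavity: repeated CSG union."""
    meshes = [_mesh_of(c) for c in cavities]
    if len(meshes) < 1:
        raise CavCsgError("union_region needs at least one cavity")
    return csg_many(meshes, "union", spacing)


def set_difference_region(
    conserved: Sequence,
    excluded: Sequence,
    spacing: float = DEFAULT_SPACING,
) -> TriangleMesh:
    """(∩ conserved) − (∪ excluded): conserved in one set, absent from the other.

    This is the construction that isolates, e.g., a substrate-specificity
    protrusion present in every member of one protease subfamily and no
    member of another.
    """
    if not conserved or not excluded:
        raise CavCsgError("both cavity sets must be nonempty")
    inter = conserved_region(conserved, spacing)
    union = union_region(excluded, spacing)
    return csg(inter, union, "difference", spacing)
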
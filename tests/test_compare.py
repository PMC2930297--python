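"""Distance matrices, UPGMA clustering, overlap profiles, region composition."""

import numpy as np
import pytest

import cavcsg
from cavcsg import (
    DistanceMatrix,
    conserved_region,
    pairwise_distances,
    residue_overlap_profile,
    set_difference_region,
    union_region,
    upgma,
)
from cavcsg.exceptions import CavCsgError
from cavcsg.fixtures import icosphere
from cavcsg.oracles import sphere_volume, voxel_volume_oracle
from cavcsg.structure import Structure
from cavcsg.volume import enclosed_volume


def _atoms(coords, radius=1.7):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return Structure(
        coords=coords,
        radii=np.full(n, radius),
        element=np.array(["C"] * n, dtype=object),
        chain=np.array(["A"] * n, dtype=object),
        resseq=np.arange(1, n + 1),
        icode=np.array([""] * n, dtype=object),
        resname=np.array(["TOY"] * n, dtype=object),
        atom_name=np.array([f"C{i}" for i in range(n)], dtype=object),
        source_id="synthetic",
    )


class TestPairwiseDistances:
    def test_identical_cavities_near_zero(self):
        s = icosphere(radius=3.0, subdivisions=3)
        dm = pairwise_distances([s, s.copy(), s.copy()], 0.5)
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.03)
        assert np.all(np.diag(dm.values) == 0)

    def test_disjoint_cavities_distance_one(self):
        cs = [
            icosphere(center=(12 * i, 0, 0), radius=2.5, subdivisions=2) for i in range(3)
        ]
        dm = pairwise_distances(cs, 0.5)
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_nested_spheres_match_containment_ratio(self):
        # fully nested: similarity 1, distance 0 irrespective of radii
        small = icosphere(radius=2.0, subdivisions=3)
        big = icosphere(radius=5.0, subdivisions=3)
        dm = pairwise_distances([small, big], 0.25)
        assert dm.values[0, 1] < 0.03

    def test_symmetry_and_tsv_round_trip(self, tmp_path):
        a = icosphere(radius=3.0, subdivisions=2)
        b = icosphere(center=(2, 0, 0), radius=3.0, subdivisions=2)
        c = icosphere(center=(0, 2.5, 0), radius=2.0, subdivisions=2)
        dm = pairwise_distances([a, b, c], 0.5, labels=["a", "b", "c"])
        np.testing.assert_allclose(dm.values, dm.values.T)
        path = tmp_path / "d.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values, atol=1e-6)


class TestUpgma:
    def test_two_leaves_join_at_half_distance(self):
        dm = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 3.0], [3.0, 0]]))
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(1.5)
        assert sorted(tree.root.leaves()) == ["a", "b"]

    def test_four_taxon_hand_example(self):
        # hand-worked UPGMA: AB merge at 1, then (AB)C at 2, then ((AB)C)D at 3
        labels = ["A", "B", "C", "D"]
        vals = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        tree = upgma(DistanceMatrix(labels=labels, values=vals))
        assert tree.merge_heights() == pytest.approx([1.0, 2.0, 3.0])
        # topology ((A,B),C),D: find each internal clade anywhere in the tree
        def clades(node, acc):
            if not node.is_leaf:
                acc[tuple(sorted(node.leaves()))] = node.height
                for ch in node.children:
                    clades(ch, acc)
            return acc

        found = clades(tree.root, {})
        assert found[("A", "B")] == pytest.approx(1.0)
        assert found[("A", "B", "C")] == pytest.approx(2.0)
        assert found[("A", "B", "C", "D")] == pytest.approx(3.0)

    def test_ultrametric_input_recovered_exactly(self):
        labels = ["A", "B", "C", "D"]
        vals = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(labels=labels, values=vals)
        coph = upgma(dm).cophenetic()
        np.testing.assert_allclose(coph.values, vals)

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 10, (7, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(labels=[f"t{i}" for i in range(7)], values=d)
        mine = upgma(dm).merge_heights()
        scipy_heights = sorted(average(squareform(d))[:, 2] / 2.0)
        np.testing.assert_allclose(mine, scipy_heights, rtol=1e-9)

    def test_heights_monotone(self):
        rng = np.random.default_rng(23)
        d = rng.uniform(1, 9, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(DistanceMatrix(labels=list("abcdef"), values=d))

        def check(node):
            for ch in node.children:
                assert ch.height <= node.height + 1e-12
                check(ch)

        check(tree.root)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        labels = ["A", "B", "C", "D"]
        vals = np.array(
            [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]], dtype=float
        )
        newick = upgma(DistanceMatrix(labels=labels, values=vals)).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(labels)
        # root-to-leaf path lengths are all equal (ultrametric)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_nan_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(CavCsgError):
            upgma(DistanceMatrix(labels=["a", "b"], values=vals))


class TestOverlapProfile:
    def test_distant_residue_zero_everywhere(self):
        st = _atoms([[0, 0, 0], [40, 0, 0]])
        target = icosphere(center=(40, 0, 0), radius=4.0, subdivisions=3)
        prof = residue_overlap_profile(st, [target], spacing=0.5)
        row_far = prof.table[prof.table.resnum == 1].iloc[0]
        assert row_far["mean"] == 0.0

    def test_buried_residue_overlap_equals_its_volume(self):
        st = _atoms([[0, 0, 0]])
        target = icosphere(radius=6.0, subdivisions=3)  # plug wholly inside
        prof = residue_overlap_profile(st, [target], spacing=0.25)
        v_res = enclosed_volume(
            cavcsg.residue_surface(st, ("A", 1, ""), spacing=0.25)
        )
        assert prof.table.iloc[0]["mean"] == pytest.approx(v_res, rel=0.03)

    def test_mean_and_sd_consistent_with_columns(self):
        st = _atoms([[0, 0, 0]])
        t1 = icosphere(radius=6.0, subdivisions=2)
        t2 = icosphere(center=(1.0, 0, 0), radius=3.0, subdivisions=2)
        prof = residue_overlap_profile(st, [t1, t2], spacing=0.5)
        row = prof.table.iloc[0]
        per_target = np.array([row[c] for c in prof.target_columns])
        assert row["mean"] == pytest.approx(per_target.mean())
        assert row["sd"] == pytest.approx(per_target.std())  # population SD

    def test_tsv_output(self, tmp_path):
        st = _atoms([[0, 0, 0]])
        prof = residue_overlap_profile(
            st, [icosphere(radius=3.0, subdivisions=2)], spacing=0.5
        )
        path = tmp_path / "prof.tsv"
        prof.to_tsv(path)
        assert "chain" in path.read_text().splitlines()[0]

    def test_empty_inputs_rejected(self):
        st = _atoms([[0, 0, 0]])
        with pytest.raises(CavCsgError):
            residue_overlap_profile(st, [], spacing=0.5)


class TestRegionComposition:
    def test_identical_copies_conserved_equals_original(self):
        s = icosphere(radius=3.0, subdivisions=3)
        v = enclosed_volume(conserved_region([s, s.copy(), s.copy()], 0.5))
        assert abs(v / enclosed_volume(s) - 1) < 0.03

    def test_conserved_bounded_by_min_union_by_max(self):
        a = icosphere(radius=3.0, subdivisions=3)
        b = icosphere(center=(1.5, 0, 0), radius=2.5, subdivisions=3)
        c = icosphere(center=(-1.0, 1.0, 0), radius=3.5, subdivisions=3)
        vols = [enclosed_volume(m) for m in (a, b, c)]
        v_int = enclosed_volume(conserved_region([a, b, c], 0.5))
        v_uni = enclosed_volume(union_region([a, b, c], 0.5))
        assert v_int <= min(vols) * 1.03
        assert v_uni >= max(vols) * 0.97

    def test_shifted_chain_matches_voxel_oracle(self):
        chain = [
            icosphere(center=(0.8 * i, 0, 0), radius=3.0, subdivisions=3) for i in range(3)
        ]
        mine = enclosed_volume(conserved_region(chain, 0.5))
        # n-way intersection of the chain equals first ∩ last (nested x-shifts)
        oracle = voxel_volume_oracle(chain[0], chain[2], "intersection", 0.3)
        assert abs(mine - oracle) < 0.05 * sphere_volume(3)

    def test_union_of_disjoint_is_additive(self):
        a = icosphere(radius=2.5, subdivisions=3)
        b = icosphere(center=(10, 0, 0), radius=2.0, subdivisions=3)
        v = enclosed_volume(union_region([a, b], 0.5))
        assert abs(v / (enclosed_volume(a) + enclosed_volume(b)) - 1) < 0.03

    def test_set_difference_excluded_covering_gives_empty(self):
        small = icosphere(radius=2.0, subdivisions=2)
        cover = icosphere(radius=5.0, subdivisions=2)
        out = set_difference_region([small, small.copy()], [cover], 0.5)
        assert enclosed_volume(out) < 0.05 * enclosed_volume(small)

    def test_set_difference_disjoint_excluded_changes_nothing(self):
        s = icosphere(radius=3.0, subdivisions=3)
        far = icosphere(center=(20, 0, 0), radius=3.0, subdivisions=2)
        v = enclosed_volume(set_difference_region([s, s.copy()], [far], 0.5))
        assert abs(v / enclosed_volume(s) - 1) < 0.03

    def test_difference_plus_retained_overlap_is_conserved_volume(self):
        a = icosphere(radius=3.0, subdivisions=3)
        b = icosphere(center=(2.0, 0, 0), radius=2.5, subdivisions=3)
        inter = conserved_region([a, a.copy()], 0.5)
        diff = set_difference_region([a, a.copy()], [b], 0.5)
        overlap = enclosed_volume(cavcsg.csg(inter, b, "intersection", 0.5))
        v = enclosed_volume(diff) + overlap
        assert abs(v / enclosed_volume(inter) - 1) < 0.03

    def test_fold_order_insensitive_within_tolerance(self):
        a = icosphere(radius=3.0, subdivisions=2)
        b = icosphere(center=(1, 0, 0), radius=3.0, subdivisions=2)
        c = icosphere(center=(0, 1, 0), radius=3.0, subdivisions=2)
        v1 = enclosed_volume(conserved_region([a, b, c], 0.5))
        v2 = enclosed_volume(conserved_region([c, a, b], 0.5))
        assert abs(v1 - v2) < 0.03 * enclosed_volume(a)
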
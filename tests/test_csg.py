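"""CSG engine: lattices, classification, crossing points, boolean results."""

import numpy as np
import pytest

from cavcsg import build_lattice, classify_points, csg, csg_many, find_crossing, validate
from cavcsg.csg import DEFAULT_SPACING, Lattice, isosurface
from cavcsg.exceptions import OpenMeshError, ResourceError
from cavcsg.fixtures import box_mesh, icosphere
from cavcsg.mesh import TriangleMesh
from cavcsg.oracles import sphere_sphere_lens, sphere_volume
from cavcsg.volume import enclosed_volume


class TestLattice:
    def test_unit_cube_example(self, unit_box):
        lat = build_lattice(unit_box, spacing=0.5, padding=1.0)
        assert all(d >= 7 for d in lat.dims)
        assert np.all(np.asarray(lat.origin) <= -1.0 + 1e-12)
        assert np.all(lat.upper >= 2.0 - 1e-12)

    def test_default_spacing_is_half_angstrom(self):
        assert DEFAULT_SPACING == 0.5

    def test_contains_both_meshes(self, sphere6):
        other = icosphere(center=(10, -3, 2), radius=2.0, subdivisions=2)
        lat = build_lattice([sphere6, other], spacing=0.5)
        for m in (sphere6, other):
            assert np.all(np.asarray(lat.origin) < m.bounds[0])
            assert np.all(lat.upper > m.bounds[1])

    def test_origin_snapped_to_spacing(self, sphere6):
        lat = build_lattice(sphere6, spacing=0.5)
        frac = np.asarray(lat.origin) / 0.5
        np.testing.assert_allclose(frac, np.rint(frac), atol=1e-9)

    def test_empty_mesh_set_rejected(self):
        with pytest.raises(ValueError):
            build_lattice([], spacing=0.5)

    def test_memory_budget_enforced(self):
        with pytest.raises(ResourceError):
            Lattice(origin=(0, 0, 0), spacing=0.01, dims=(1000, 1000, 1000))


class TestClassify:
    def test_disjoint_intersection_all_outside(self):
        a = icosphere(radius=2.0, subdivisions=2)
        b = icosphere(center=(10, 0, 0), radius=2.0, subdivisions=2)
        lat = build_lattice([a, b], spacing=0.5)
        labels = classify_points(lat, a, b, "intersection")
        assert not labels.any()

    def test_self_union_equals_self_intersection(self, sphere6):
        lat = build_lattice(sphere6, spacing=1.0)
        u = classify_points(lat, sphere6, sphere6, "union")
        i = classify_points(lat, sphere6, sphere6, "intersection")
        np.testing.assert_array_equal(u, i)

    def test_nested_difference_matches_analytic_shell(self):
        big = icosphere(radius=6.0, subdivisions=3)
        small = icosphere(radius=3.0, subdivisions=3)
        lat = build_lattice([big], spacing=0.5)
        labels = classify_points(lat, big, small, "difference")
        ax = lat.axes()
        r = np.sqrt(
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        clear = (np.abs(r - 6.0) > 0.5) & (np.abs(r - 3.0) > 0.5)
        expected = (r < 6.0) & (r > 3.0)
        np.testing.assert_array_equal(labels[clear], expected[clear])

    def test_open_mesh_rejected(self, sphere6):
        broken = TriangleMesh(sphere6.vertices.copy(), sphere6.faces[1:].copy())
        lat = build_lattice(sphere6, spacing=1.0)
        with pytest.raises(OpenMeshError):
            classify_points(lat, sphere6, broken, "union")


class TestFindCrossing:
    def test_single_sphere_crossing_matches_quadratic_root(self):
        s = icosphere(radius=5.0, subdivisions=4)
        big = icosphere(radius=20.0, subdivisions=1)  # B irrelevant but inside
        p_lo = np.array([4.2, 1.3, 0.7])
        p_hi = np.array([6.2, 1.3, 0.7])
        p0 = find_crossing(p_lo, p_hi, s, big, "intersection")
        # analytic root of |p|² = r² along the segment (mesh is faceted:
        # allow the chord sag of the subdivided icosphere)
        root_x = np.sqrt(5.0**2 - 1.3**2 - 0.7**2)
        assert abs(p0[0] - root_x) < 0.01
        np.testing.assert_allclose(p0[1:], [1.3, 0.7])

    def test_coincident_surfaces_pick_that_point(self):
        s = icosphere(radius=5.0, subdivisions=3)
        p0 = find_crossing((0, 0, 4.0), (0, 0, 5.5), s, s, "intersection")
        assert abs(p0[2] - 5.0) < 0.05

    def test_non_straddling_segment_rejected(self):
        s = icosphere(radius=5.0, subdivisions=2)
        with pytest.raises(Exception):
            find_crossing((0, 0, 0), (0, 0, 1.0), s, s, "intersection")


class TestCsg:
    def test_disjoint_spheres_intersection_empty(self):
        a = icosphere(radius=6.0, subdivisions=2)
        b = icosphere(center=(20, 0, 0), radius=6.0, subdivisions=2)
        out = csg(a, b, "intersection", 0.5)
        assert out.is_empty
        assert enclosed_volume(out) == 0.0

    def test_self_intersection_idempotent(self, sphere6):
        out = csg(sphere6, sphere6, "intersection", 0.5)
        assert abs(enclosed_volume(out) / enclosed_volume(sphere6) - 1) < 0.02

    def test_lens_volume_matches_closed_form(self, sphere6_fine):
        b = icosphere(center=(6.0, 0, 0), radius=6.0, subdivisions=4)
        v = enclosed_volume(csg(sphere6_fine, b, "intersection", 0.5))
        assert abs(v / sphere_sphere_lens(6, 6, 6) - 1) < 0.03

    def test_box_corner_overlap(self):
        # generic placement: faces off the lattice planes
        off = 0.131
        a = box_mesh((off,) * 3, (1 + off,) * 3)
        b = box_mesh((0.5 + off,) * 3, (1.5 + off,) * 3)
        v = enclosed_volume(csg(a, b, "intersection", 0.05))
        assert abs(v / 0.125 - 1) < 0.03

    def test_lattice_aligned_boxes_still_work(self):
        # faces exactly on lattice planes exercise the on-surface convention
        a = box_mesh((0, 0, 0), (1, 1, 1))
        b = box_mesh((0.5, 0.5, 0.5), (1.5, 1.5, 1.5))
        v = enclosed_volume(csg(a, b, "intersection", 0.05))
        assert abs(v / 0.125 - 1) < 0.03

    def test_outputs_always_validate(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            c1 = rng.uniform(-2, 2, 3)
            c2 = rng.uniform(-2, 2, 3)
            r1, r2 = rng.uniform(2, 4, 2)
            a = icosphere(center=c1, radius=r1, subdivisions=2)
            b = icosphere(center=c2, radius=r2, subdivisions=2)
            for op in ("union", "intersection", "difference"):
                out = csg(a, b, op, 0.5)
                if out.is_empty:
                    continue
                rep = validate(out)
                assert rep.is_closed and rep.is_consistently_oriented, (op, c1, c2)

    def test_volume_laws_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            c = rng.uniform(-1.5, 1.5, 3)
            r1, r2 = rng.uniform(2.5, 4, 2)
            a = icosphere(radius=r1, subdivisions=3)
            b = icosphere(center=c, radius=r2, subdivisions=3)
            va, vb = enclosed_volume(a), enclosed_volume(b)
            vu = enclosed_volume(csg(a, b, "union", 0.5))
            vi = enclosed_volume(csg(a, b, "intersection", 0.5))
            vd = enclosed_volume(csg(a, b, "difference", 0.5))
            tol = 0.03 * max(va, vb)
            assert abs((vu + vi) - (va + vb)) < tol
            assert abs((vd + vi) - va) < tol
            assert vi <= min(va, vb) + tol
            assert vu >= max(va, vb) - tol

    def test_convergence_with_finer_spacing(self):
        a = icosphere(radius=6.0, subdivisions=4)
        b = icosphere(center=(6, 0, 0), radius=6.0, subdivisions=4)
        exact = sphere_sphere_lens(6, 6, 6)
        err = {
            sp: abs(enclosed_volume(csg(a, b, "intersection", sp)) - exact)
            for sp in (1.0, 0.5)
        }
        assert err[0.5] < err[1.0]

    def test_difference_is_ordered(self):
        big = icosphere(radius=5.0, subdivisions=3)
        small = icosphere(radius=2.5, subdivisions=3)
        shell = enclosed_volume(csg(big, small, "difference", 0.5))
        nothing = enclosed_volume(csg(small, big, "difference", 0.5))
        assert abs(shell - (sphere_volume(5) - sphere_volume(2.5))) < 0.04 * sphere_volume(5)
        assert nothing < 0.03 * sphere_volume(2.5)

    def test_empty_operands(self, sphere6):
        empty = TriangleMesh.empty()
        assert csg(sphere6, empty, "union", 0.5).n_faces == sphere6.n_faces
        assert csg(sphere6, empty, "intersection", 0.5).is_empty
        assert csg(empty, sphere6, "difference", 0.5).is_empty


class TestCsgMany:
    def test_intersection_of_identical_copies(self):
        s = icosphere(radius=4.0, subdivisions=3)
        out = csg_many([s] * 5, "intersection", 0.5)
        assert abs(enclosed_volume(out) / enclosed_volume(s) - 1) < 0.03

    def test_union_of_disjoint_spheres_is_additive(self):
        a = icosphere(radius=3.0, subdivisions=3)
        b = icosphere(center=(10, 0, 0), radius=3.0, subdivisions=3)
        out = csg_many([a, b], "union", 0.5)
        total = enclosed_volume(a) + enclosed_volume(b)
        assert abs(enclosed_volume(out) / total - 1) < 0.03

    def test_expression_composition(self):
        t1 = icosphere(radius=4.0, subdivisions=2)
        t2 = icosphere(center=(1, 0, 0), radius=4.0, subdivisions=2)
        e1 = icosphere(center=(0, 3.0, 0), radius=2.0, subdivisions=2)
        out = csg_many({"t1": t1, "t2": t2, "e1": e1}, "(t1 & t2) - e1", 0.5)
        direct = csg(csg(t1, t2, "intersection", 0.5), e1, "difference", 0.5)
        assert abs(enclosed_volume(out) - enclosed_volume(direct)) < 1e-9

    def test_expression_errors(self):
        s = icosphere(radius=2.0, subdivisions=1)
        with pytest.raises(KeyError):
            csg_many({"a": s}, "a & missing", 1.0)
        with pytest.raises(ValueError):
            csg_many({"a": s}, "a &", 1.0)


class TestIsosurface:
    def test_sphere_field_volume(self):
        lat = build_lattice(
            [], spacing=0.25, padding=1.0, bounds=np.array([[-3.0] * 3, [3.0] * 3])
        )
        ax = lat.axes()
        field = 2.5 - np.sqrt(
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        mesh = isosurface(field, lat)
        rep = validate(mesh)
        assert rep.is_closed and rep.is_consistently_oriented
        assert abs(enclosed_volume(mesh) / sphere_volume(2.5) - 1) < 0.01

    def test_matches_reference_marching_cubes_volume(self):
        """Cross-check the extractor against scikit-image's marching cubes."""
        from skimage import measure

        lat = build_lattice(
            [], spacing=0.25, padding=1.0, bounds=np.array([[-3.0] * 3, [3.0] * 3])
        )
        ax = lat.axes()
        field = 2.5 - np.sqrt(
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        mine = enclosed_volume(isosurface(field, lat))
        verts, faces, _, _ = measure.marching_cubes(field, level=0.0, spacing=(0.25,) * 3)
        ref = abs(
            np.einsum(
                "ij,ij->i", verts[faces[:, 0]], np.cross(verts[faces[:, 1]], verts[faces[:, 2]])
            ).sum()
            / 6.0
        )
        assert abs(mine / ref - 1) < 0.005
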
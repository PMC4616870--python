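"""Sphere fitting, mirroring, ICP registration, and scalar measures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import femurdisp as fd
from femurdisp.errors import DegenerateGeometryError, ValidationError
from femurdisp.geometry import _algebraic_sphere, _radial_residuals


def finite_triples(lo=-100.0, hi=100.0):
    return st.tuples(*[st.floats(lo, hi) for _ in range(3)])


class TestSphereFit:
    def test_noiseless_exact_recovery(self, sphere_points):
        pts = np.array([1.0, 2.0, 3.0]) + 10.0 * sphere_points
        rep = fd.fit_sphere(pts)
        np.testing.assert_allclose(rep.sphere.center, [1, 2, 3], atol=1e-9)
        assert rep.sphere.radius == pytest.approx(10.0, abs=1e-9)
        assert rep.rms_residual < 1e-9
        assert rep.n_points_used == 500

    def test_noisy_fit_close_to_truth(self, sphere_points):
        rng = np.random.default_rng(1)
        pts = np.array([1.0, 2.0, 3.0]) + 10.0 * sphere_points
        pts = pts + rng.normal(0, 0.1, pts.shape)
        rep = fd.fit_sphere(pts)
        assert np.linalg.norm(rep.sphere.center - [1, 2, 3]) < 0.05
        assert rep.sphere.radius == pytest.approx(10.0, abs=0.05)

    def test_refinement_not_worse_than_algebraic(self, sphere_points):
        rng = np.random.default_rng(2)
        # strongly anisotropic coverage (a cap) makes the algebraic fit biased
        cap = sphere_points[sphere_points[:, 2] > 0.3]
        pts = 10.0 * cap + rng.normal(0, 0.2, (len(cap), 3))
        c0, r0 = _algebraic_sphere(pts)
        rms_alg = np.sqrt(np.mean(_radial_residuals(np.r_[c0, r0], pts) ** 2))
        rep = fd.fit_sphere(pts)
        assert rep.rms_residual <= rms_alg + 1e-12

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(DegenerateGeometryError):
            fd.fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fd.fit_sphere(np.zeros((3, 3)))

    def test_robust_excludes_inward_pit(self, sphere_points):
        pts = 22.0 * sphere_points
        # pull a cluster of points 3 mm inward: a synthetic fovea pit
        pit = np.argsort(sphere_points @ np.array([1.0, 0, 0]))[-25:]
        pts[pit] *= (22.0 - 3.0) / 22.0
        plain = fd.fit_sphere(pts, robust=False)
        robust = fd.fit_sphere(pts, robust=True)
        assert robust.n_excluded >= 20
        assert abs(robust.sphere.radius - 22.0) < abs(plain.sphere.radius - 22.0)
        assert abs(robust.sphere.radius - 22.0) < 1e-6
        assert robust.iterations <= 5


class TestMirror:
    def test_vertex_reflection(self, tetrahedron):
        model = fd.FemurModel(tetrahedron, "left", np.zeros(4, dtype=int))
        mirrored = fd.mirror_mesh(model)
        np.testing.assert_allclose(mirrored.mesh.vertices[1], [-1, 0, 0], atol=1e-15)
        assert mirrored.side == "right"

    def test_involution(self, coarse_pair):
        healthy = coarse_pair[1]
        twice = fd.mirror_mesh(fd.mirror_mesh(healthy))
        np.testing.assert_allclose(twice.mesh.vertices, healthy.mesh.vertices, atol=1e-12)
        np.testing.assert_array_equal(twice.mesh.faces, healthy.mesh.faces)
        assert twice.side == healthy.side

    def test_isometry_area_and_distances(self, coarse_pair):
        healthy = coarse_pair[1]
        mirrored = fd.mirror_mesh(healthy)
        a0 = healthy.mesh.surface_area()
        a1 = mirrored.mesh.surface_area()
        assert abs(a1 - a0) / a0 < 1e-9
        rng = np.random.default_rng(0)
        idx = rng.integers(0, healthy.mesh.n_vertices, size=(50, 2))
        d0 = np.linalg.norm(healthy.mesh.vertices[idx[:, 0]] - healthy.mesh.vertices[idx[:, 1]], axis=1)
        d1 = np.linalg.norm(mirrored.mesh.vertices[idx[:, 0]] - mirrored.mesh.vertices[idx[:, 1]], axis=1)
        np.testing.assert_allclose(d1, d0, rtol=1e-12)

    def test_arbitrary_plane(self, tetrahedron):
        model = fd.FemurModel(tetrahedron, "left", np.zeros(4, dtype=int))
        plane = fd.MirrorPlane(point=(1.0, 0.0, 0.0), normal=(2.0, 0.0, 0.0))  # normalized inside
        mirrored = fd.mirror_mesh(model, plane)
        np.testing.assert_allclose(mirrored.mesh.vertices[0], [2, 0, 0], atol=1e-15)

    def test_zero_normal_rejected(self, tetrahedron):
        model = fd.FemurModel(tetrahedron, "left", np.zeros(4, dtype=int))
        with pytest.raises(ValidationError):
            fd.mirror_mesh(model, fd.MirrorPlane(normal=(0.0, 0.0, 0.0)))


class TestRegistration:
    def test_identity_on_identical_models(self, coarse_pair):
        healthy = coarse_pair[1]
        rep = fd.register_rigid(healthy, healthy)
        assert rep.rms_error < 1e-9
        assert rep.converged
        np.testing.assert_allclose(rep.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(rep.transform.translation, 0, atol=1e-9)

    def test_recovers_known_transform(self, coarse_pair):
        healthy = coarse_pair[1]
        t = fd.RigidTransform.from_axis_angle([1, 1, 0], 8.0, translation=[4.0, -2.0, 7.0])
        moved = fd.FemurModel(
            fd.TriangleMesh(t.apply(healthy.mesh.vertices), healthy.mesh.faces.copy()),
            healthy.side,
            healthy.region_mask.copy(),
        )
        rep = fd.register_rigid(moved, healthy)
        recovered = rep.transform
        expected = t.inverse()
        assert np.linalg.norm(recovered.translation - expected.translation) < 1e-3
        gap = recovered.compose(t)
        assert gap.rotation_angle_deg() < 0.01

    def test_invariant_to_common_rigid_motion(self, coarse_pair):
        fractured, healthy, _ = coarse_pair
        mirrored = fd.mirror_mesh(fractured)
        rel0 = fd.register_rigid(mirrored, healthy).transform
        g = fd.RigidTransform.from_axis_angle([3, -1, 2], 25.0, translation=[30.0, 5.0, -12.0])

        def move(m):
            return fd.FemurModel(
                fd.TriangleMesh(g.apply(m.mesh.vertices), m.mesh.faces.copy()), m.side, m.region_mask.copy()
            )

        rep1 = fd.register_rigid(fd.mirror_mesh(move(fractured)), move(healthy))
        rel1 = rep1.transform
        # equivariance: aligning the moved pair then undoing the common motion
        # lands the source exactly where aligning the original pair does
        aligned0 = rel0.apply(mirrored.mesh.vertices)
        aligned1 = g.inverse().apply(rel1.apply(fd.mirror_mesh(move(fractured)).mesh.vertices))
        np.testing.assert_allclose(aligned1, aligned0, atol=1e-6)
        # and the registration residual is unchanged
        rms0 = fd.register_rigid(mirrored, healthy).rms_error
        assert abs(rms0 - rep1.rms_error) < 1e-6

    def test_empty_region_selection_rejected(self, coarse_pair):
        healthy = coarse_pair[1]
        neckless = fd.FemurModel(healthy.mesh, healthy.side, np.full(healthy.mesh.n_vertices, 2))
        with pytest.raises(ValidationError, match="empty region"):
            fd.register_rigid(neckless, neckless, regions=("shaft",))

    def test_trim_fraction_bounds(self, coarse_pair):
        healthy = coarse_pair[1]
        with pytest.raises(ValidationError):
            fd.register_rigid(healthy, healthy, trim_fraction=0.5)

    def test_sanity_bound_sets_converged_false(self, coarse_pair):
        healthy = coarse_pair[1]
        far = fd.RigidTransform(np.eye(3), np.array([500.0, 0, 0]))
        moved = fd.FemurModel(
            fd.TriangleMesh(far.apply(healthy.mesh.vertices), healthy.mesh.faces.copy()),
            healthy.side,
            healthy.region_mask.copy(),
        )
        # scaled source cannot match: break symmetry so ICP cannot succeed
        squashed = fd.FemurModel(
            fd.TriangleMesh(moved.mesh.vertices * np.array([1.0, 0.4, 0.4]), moved.mesh.faces.copy()),
            moved.side,
            moved.region_mask.copy(),
        )
        with pytest.warns(RuntimeWarning, match="sanity"):
            rep = fd.register_rigid(squashed, healthy, max_iterations=5, sanity_rms_mm=0.5)
        assert not rep.converged


class TestScalars:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            (([0, 0, 0], [1, 0, 0]), ([0, 0, 0], [1, 0, 0]), 0.0),
            (([0, 0, 0], [1, 0, 0]), ([0, 0, 0], [0, 1, 0]), 90.0),
            (([0, 0, 0], [1, 0, 0]), ([0, 0, 0], [1, 1, 0]), 45.0),
            (([0, 0, 0], [1, 0, 0]), ([5, 5, 5], [4, 5, 5]), 180.0),
        ],
    )
    def test_angle_examples(self, u, v, expected):
        assert fd.angle_between_lines(u[0], u[1], v[0], v[1]) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValidationError):
            fd.angle_between_lines([0, 0, 0], [0, 0, 0], [0, 0, 0], [1, 0, 0])

    @given(
        p=finite_triples(), q=finite_triples(), r=finite_triples(), s=finite_triples(),
        angle=st.floats(-180, 180), shift=finite_triples(),
    )
    def test_angle_rigid_invariance(self, p, q, r, s, angle, shift):
        p, q, r, s = map(np.asarray, (p, q, r, s))
        if np.linalg.norm(q - p) < 1e-6 or np.linalg.norm(s - r) < 1e-6:
            return
        t = fd.RigidTransform.from_axis_angle([1.0, 2.0, -0.5], angle, np.asarray(shift))
        a0 = fd.angle_between_lines(p, q, r, s)
        a1 = fd.angle_between_lines(*(t.apply(np.array([x])).ravel() for x in (p, q, r, s)))
        assert a1 == pytest.approx(a0, abs=1e-5)

    def test_point_distance(self):
        assert fd.point_distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)
        assert fd.point_distance([1, 1, 1], [1, 1, 1]) == 0.0
        assert fd.point_distance([1, 2, 3], [-4, 0, 2]) == fd.point_distance([-4, 0, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            fd.point_distance([np.nan, 0, 0], [0, 0, 0])
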
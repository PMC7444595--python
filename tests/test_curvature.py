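"""Curvature tensor voting: votes, tensors, decomposition, measures."""

import numpy as np
import pytest

import curvomesh as cm
from curvomesh.curvature import normal_curvature, principal_from_tensor, tangent_direction
from curvomesh.graph import NeighborhoodParams

from conftest import analytic_sphere_mesh


class TestTangentDirection:
    def test_projection_closed_form(self):
        t = tangent_direction(np.zeros(3), np.array([0.0, 0, 1]), np.array([1.0, 0, 1]))
        np.testing.assert_allclose(t, [1, 0, 0], atol=1e-12)

    def test_in_plane_direction_is_normalized_offset(self):
        d = np.array([3.0, 4.0, 0.0])
        t = tangent_direction(np.zeros(3), np.array([0.0, 0, 1]), d)
        np.testing.assert_allclose(t, d / 5.0)

    def test_offset_parallel_to_normal_is_skipped(self):
        t = tangent_direction(np.zeros(3), np.array([0.0, 0, 1]), np.array([0.0, 0, 2]))
        assert t is None

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            tangent_direction(np.zeros(3), np.array([0.0, 0, 1]), np.zeros(3))


class TestNormalCurvature:
    def test_flat_patch_gives_zero(self):
        n = np.array([0.0, 0, 1])
        k = normal_curvature(np.zeros(3), n, np.array([1.0, 0, 0]), n)
        assert k == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 2.0])
    def test_sphere_arc_gives_exactly_one_over_r(self, alpha):
        # two points on a sphere of radius r with inward normals: the arc
        # construction recovers kappa = +1/r for any angular separation
        r = 7.0
        v = r * np.array([1.0, 0, 0])
        vi = r * np.array([np.cos(alpha), np.sin(alpha), 0.0])
        k = normal_curvature(v, -v / r, vi, -vi / r)
        assert k == pytest.approx(1.0 / r, rel=1e-12)

    def test_torus_inner_rim_ring_direction_is_negative(self):
        # inner equator of a torus (rr=25, csr=10): moving along the ring
        # the surface bends away from the inward normal, kappa_2 = -1/15
        rr, csr = 25.0, 10.0
        rho = rr - csr  # inner equator radius
        v = np.array([rho, 0.0, 0.0])
        n_v = np.array([1.0, 0.0, 0.0])  # inward = away from torus axis here
        a = 0.2
        vi = np.array([rho * np.cos(a), rho * np.sin(a), 0.0])
        n_vi = np.array([np.cos(a), np.sin(a), 0.0])
        k = normal_curvature(v, n_v, vi, n_vi)
        assert k == pytest.approx(-1.0 / rho, rel=1e-12)


class TestVoteCollection:
    def test_plane_gives_zero_tensor(self):
        bench = cm.make_noisy_plane(half_size=6, noise_fraction=0.0, seed=0)
        graph = cm.build_surface_graph(bench.mesh)
        B = cm.collect_curvature_votes(
            bench.mesh, graph, bench.mesh.n_triangles // 2,
            NeighborhoodParams(3.0), variant="RVV",
        )
        np.testing.assert_allclose(B, 0.0, atol=1e-12)

    @pytest.mark.parametrize("variant", ["RVV", "AVV"])
    def test_sphere_tensor_matches_integral_oracle(self, variant, icosphere10):
        # independent oracle: with exact per-vote curvature 1/r and weights
        # summing to 2pi, B = (1/2pi) \oint kappa t t^T dpsi has in-plane
        # eigenvalues kappa/2 and a null normal direction
        r = 10.0
        mesh = icosphere10
        graph = cm.build_surface_graph(mesh)
        truth_n = -mesh.centroids / np.linalg.norm(mesh.centroids, axis=1, keepdims=True)
        v = 0
        B = cm.collect_curvature_votes(
            mesh, graph, v, NeighborhoodParams(6.0), variant=variant,
            normals=truth_n,
        )
        eigvals = np.sort(np.linalg.eigvalsh(B))
        assert eigvals[0] == pytest.approx(0.0, abs=2e-4)
        np.testing.assert_allclose(eigvals[1:], 1.0 / (2 * r), rtol=0.02)

    def test_cylinder_tensor_oracle(self):
        # uniform tangents on a cylinder: kappa_1 = 1/r, kappa_2 = 0, the
        # minimum-curvature direction along the axis
        bench = cm.make_cylinder(r=10.0, h=25.0)
        graph = cm.build_surface_graph(bench.mesh)
        v = bench.mesh.n_triangles // 2  # mid-height triangle
        B = cm.collect_curvature_votes(
            bench.mesh, graph, v, NeighborhoodParams(5.0), variant="AVV",
            normals=bench.true_normals,
        )
        t1, t2, k1, k2, b3, ang = principal_from_tensor(B, bench.true_normals[v])
        assert k1 == pytest.approx(0.1, rel=0.03)
        assert k2 == pytest.approx(0.0, abs=0.005)
        assert abs(np.dot(t2, [0, 0, 1])) > 0.99

    def test_unknown_variant_rejected(self, icosphere10):
        graph = cm.build_surface_graph(icosphere10)
        with pytest.raises(ValueError, match="variant"):
            cm.collect_curvature_votes(
                icosphere10, graph, 0, NeighborhoodParams(4.0), variant="XXX"
            )


class TestSSVV:
    def test_sphere_votes_are_exactly_one_over_r(self):
        # fine icosphere: the osculating-circle construction gives 1/r up to
        # the chord error of the faceting
        r = 10.0
        mesh = analytic_sphere_mesh(r=r, subdivisions=4)
        truth_n = -mesh.centroids / np.linalg.norm(mesh.centroids, axis=1, keepdims=True)
        for v in (0, 100, 1000):
            B = cm.ssvv_votes(mesh, v, truth_n[v], rh=5.0)
            _, _, k1, k2, _, _ = principal_from_tensor(B, truth_n[v])
            assert k1 == pytest.approx(1.0 / r, rel=5e-3)
            assert k2 == pytest.approx(1.0 / r, rel=5e-3)

    def test_plane_gives_zero(self):
        bench = cm.make_noisy_plane(half_size=10, noise_fraction=0.0, seed=0)
        v = bench.mesh.n_triangles // 2
        B = cm.ssvv_votes(bench.mesh, v, np.array([0.0, 0, 1]), rh=3.0)
        np.testing.assert_allclose(B, 0.0, atol=1e-9)

    def test_too_few_intersections_raises(self):
        # a single isolated triangle cannot be sampled
        mesh = cm.TriangleMesh(
            np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0)], dtype=float),
            np.array([(0, 1, 2)]),
        )
        with pytest.raises(ValueError, match="intersections"):
            cm.ssvv_votes(mesh, 0, np.array([0.0, 0, 1.0]), rh=2.0)


class TestPrincipalFromTensor:
    def test_zero_tensor_gives_zero_curvatures(self):
        _, _, k1, k2, b3, _ = principal_from_tensor(np.zeros((3, 3)), np.array([0.0, 0, 1]))
        assert k1 == 0.0 and k2 == 0.0 and b3 == 0.0

    def test_sphere_tensor_identity(self):
        # b1 = b2 = 1/(2r), b3 = 0  ->  kappa_1 = kappa_2 = 1/r (= 2 b1)
        r = 10.0
        n = np.array([0.0, 0, 1.0])
        B = np.diag([1 / (2 * r), 1 / (2 * r), 0.0])
        _, _, k1, k2, _, _ = principal_from_tensor(B, n)
        assert k1 == pytest.approx(1.0 / r)
        assert k2 == pytest.approx(1.0 / r)

    def test_saddle_tensor_recovered_via_normal_matching(self):
        # torus inner rim: in-plane eigenvalues (3k1+k2)/8 and (k1+3k2)/8
        # with k2 < 0; the near-zero normal eigenvalue lies between them,
        # so selection must match eigenvectors against the normal
        k1t, k2t = 0.1, -1.0 / 15.0
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        n, t1, t2 = q[:, 0], q[:, 1], q[:, 2]
        B = (3 * k1t + k2t) / 8 * np.outer(t1, t1) + (k1t + 3 * k2t) / 8 * np.outer(t2, t2)
        out_t1, out_t2, k1, k2, b3, ang = principal_from_tensor(B, n)
        assert k1 == pytest.approx(k1t, rel=1e-12)
        assert k2 == pytest.approx(k2t, rel=1e-12)
        assert abs(np.dot(out_t1, t1)) == pytest.approx(1.0)
        assert abs(np.dot(out_t2, t2)) == pytest.approx(1.0)
        assert b3 == pytest.approx(0.0, abs=1e-15)
        assert ang == pytest.approx(0.0, abs=1e-7)


class TestCombinedMeasures:
    def test_closed_form_example(self):
        H, K, C, SI = cm.combined_measures(0.1, 0.0)
        assert H == pytest.approx(0.05)
        assert K == pytest.approx(0.0)
        assert C == pytest.approx(0.070711, rel=1e-4)
        assert SI == pytest.approx(0.5)

    def test_umbilic_limits(self):
        assert cm.combined_measures(0.2, 0.2)[3] == pytest.approx(1.0)
        assert cm.combined_measures(-0.2, -0.2)[3] == pytest.approx(-1.0)
        assert cm.combined_measures(0.0, 0.0)[3] == 0.0

    def test_symmetric_saddle(self):
        H, K, C, SI = cm.combined_measures(0.3, -0.3)
        assert H == 0.0
        assert K == pytest.approx(-0.09)
        assert SI == 0.0

    def test_vectorized_matches_scalar(self):
        k1 = np.array([0.1, 0.2, 0.0])
        k2 = np.array([0.0, 0.2, -0.1])
        H, K, C, SI = cm.combined_measures(k1, k2)
        for i in range(3):
            h, k, c, si = cm.combined_measures(k1[i], k2[i])
            assert (H[i], K[i], C[i], SI[i]) == (h, k, c, si)


class TestWholeMesh:
    def test_convex_sphere_all_curvatures_positive(self, icosphere10):
        mesh = icosphere10
        graph = cm.build_surface_graph(mesh)
        res = cm.estimate_curvatures(mesh, graph, 6.0, algorithm="AVV")
        assert not res.flagged.any()
        assert np.all(res.kappa_1 > 0) and np.all(res.kappa_2 > 0)
        assert np.all(res.kappa_1 >= res.kappa_2)

    def test_rotation_equivariance(self):
        bench = cm.make_cylinder(r=6.0, h=12.0, edge_length=2.0)
        graph = cm.build_surface_graph(bench.mesh)
        res = cm.estimate_curvatures(bench.mesh, graph, 4.0, algorithm="AVV")

        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        rot = cm.TriangleMesh(bench.mesh.vertices @ q.T, bench.mesh.faces)
        res_r = cm.estimate_curvatures(
            rot, cm.build_surface_graph(rot), 4.0, algorithm="AVV"
        )
        np.testing.assert_allclose(res_r.kappa_1, res.kappa_1, atol=1e-8)
        np.testing.assert_allclose(res_r.kappa_2, res.kappa_2, atol=1e-8)
        dots = np.abs((res_r.t_1 * (res.t_1 @ q.T)).sum(axis=1))
        assert np.all(dots > 1 - 1e-6)

    def test_unit_scaling_consistency(self):
        bench = cm.make_cylinder(r=6.0, h=12.0, edge_length=2.0)
        graph = cm.build_surface_graph(bench.mesh)
        res = cm.estimate_curvatures(bench.mesh, graph, 4.0, algorithm="AVV")
        voxel_size = 1.5
        scaled = bench.mesh.scaled(voxel_size)
        res_nm = cm.estimate_curvatures(
            scaled, cm.build_surface_graph(scaled), 4.0 * voxel_size, algorithm="AVV"
        )
        np.testing.assert_allclose(
            res_nm.kappa_1, res.kappa_1 / voxel_size, rtol=1e-9, atol=1e-12
        )
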
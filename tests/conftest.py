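"""Shared fixtures: benchmark surfaces and their graphs/neighborhoods.

The expensive pipelines (quantization-noise sphere, smooth sphere, torus)
are session-scoped and shared between the unit tests and the acceptance
suite, so each surface is generated and traversed once.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import curvomesh as cm
from curvomesh.graph import NeighborhoodParams


def analytic_sphere_mesh(r: float = 10.0, subdivisions: int = 3) -> cm.TriangleMesh:
    """Icosphere with inward orientation (analytic benchmark helper)."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
    mesh = cm.TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    inward = -mesh.centroids / np.linalg.norm(mesh.centroids, axis=1, keepdims=True)
    if (mesh.normals * inward).sum() < 0:
        mesh = mesh.flip_orientation()
    return mesh


def neighborhoods_at(nb_max, rh: float):
    """Restrict precomputed neighborhoods to the g_max of a smaller rh."""
    g_max = NeighborhoodParams(rh).g_max
    return [(idx[d <= g_max], d[d <= g_max]) for idx, d in nb_max]


@pytest.fixture(scope="session")
def voxel_sphere():
    """Quantization-noise sphere r=10 in 25^3 with graph and rh<=16 reach."""
    bench = cm.make_voxel_sphere(r=10.0, box=25)
    graph = cm.SurfaceGraph(bench.mesh)
    nb16 = graph.geodesic_neighborhoods(NeighborhoodParams(16.0).g_max)
    return bench, graph, nb16


@pytest.fixture(scope="session")
def smooth_sphere():
    """Smooth non-uniformly tessellated sphere r=10 (Gaussian sigma=3.3)."""
    bench = cm.make_smooth_sphere(r=10.0, gauss_sigma=3.3)
    graph = cm.SurfaceGraph(bench.mesh)
    nb10 = graph.geodesic_neighborhoods(NeighborhoodParams(10.0).g_max)
    return bench, graph, nb10


@pytest.fixture(scope="session")
def torus():
    """Smooth torus rr=25, csr=10 (coarsened tessellation for speed)."""
    bench = cm.make_torus(rr=25.0, csr=10.0, edge_length=2.0)
    graph = cm.SurfaceGraph(bench.mesh)
    nb8 = graph.geodesic_neighborhoods(NeighborhoodParams(8.0).g_max)
    return bench, graph, nb8


@pytest.fixture(scope="session")
def torus_normals(torus):
    bench, graph, nb8 = torus
    normals, _ = cm.estimate_normals(
        bench.mesh, graph, NeighborhoodParams(8.0), neighborhoods=nb8
    )
    return normals


@pytest.fixture(scope="session")
def cylinder():
    """Open cylinder r=10, h=25 with graph."""
    bench = cm.make_cylinder(r=10.0, h=25.0)
    graph = cm.SurfaceGraph(bench.mesh)
    return bench, graph


@pytest.fixture(scope="session")
def noisy_plane_10pct():
    """10%-noise plane (> 10^4 triangles) with graph."""
    bench = cm.make_noisy_plane(half_size=36, noise_fraction=0.1, seed=7)
    graph = cm.SurfaceGraph(bench.mesh)
    return bench, graph


@pytest.fixture(scope="session")
def icosphere10():
    return analytic_sphere_mesh(r=10.0, subdivisions=3)
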
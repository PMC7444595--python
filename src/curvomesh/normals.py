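"""Robust surface-normal estimation by vector voting (VV).

Normals computed directly from triangle winding are corrupted by
quantization noise.  Each triangle center v collects *normal votes* from all
triangles within its geodesic neighborhood: a neighbor at c_i with unit
normal n_ci casts

    n_i = n_ci + 2 cos(theta_i) * u,     u = (c_i - v)/||c_i - v||,
    cos(theta_i) = -n_ci . u,

which is the Householder reflection of n_ci across the plane perpendicular
to u — the normal transported along the shortest circular arc from c_i to v.
Votes are unit vectors by construction.  They are accumulated into the
weighted covariance sum

    V_v = sum_i w_i n_i n_i^T,    w_i = (a_i / a_max) exp(-g_i / sigma),

where a_i is the neighbor's triangle area, a_max the largest triangle area on
the surface and g_i the geodesic distance.  The eigenvector of the largest
eigenvalue of V_v gives the estimated normal direction; its sign is taken
from the original (oriented) surface normal.
"""

from __future__ import annotations

import numpy as np

from .graph import NeighborhoodParams, SurfaceGraph
from .mesh import TriangleMesh

_EPS = 1e-12


def normal_vote(n_ci: np.ndarray, v: np.ndarray, c_i: np.ndarray) -> np.ndarray:
    """Normal vote cast at ``v`` by a neighbor at ``c_i`` with normal ``n_ci``."""
    vc = np.asarray(c_i, dtype=float) - np.asarray(v, dtype=float)
    norm = np.linalg.norm(vc)
    if norm < _EPS:
        raise ValueError("coincident centroids")
    u = vc / norm
    cos_theta = -float(np.dot(n_ci, u))
    return np.asarray(n_ci, dtype=float) + 2.0 * cos_theta * u


def _votes_batch(
    normals_nb: np.ndarray, v: np.ndarray, centroids_nb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized normal votes; returns (votes, valid mask)."""
    vc = centroids_nb - v
    norm = np.linalg.norm(vc, axis=1)
    valid = norm >= _EPS
    u = np.zeros_like(vc)
    u[valid] = vc[valid] / norm[valid, None]
    cos_theta = -(normals_nb * u).sum(axis=1)
    votes = normals_nb + 2.0 * cos_theta[:, None] * u
    return votes, valid


def collect_normal_votes(
    mesh: TriangleMesh,
    graph: SurfaceGraph,
    v: int,
    params: NeighborhoodParams,
    neighborhood: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Weighted vote covariance matrix ``V_v`` (3x3) for triangle ``v``.

    ``neighborhood`` may pass a precomputed ``(indices, geodesic distances)``
    pair; otherwise it is computed from the graph.
    """
    if neighborhood is None:
        neighborhood = graph.geodesic_neighborhood(v, params.g_max)
    idx, g = neighborhood
    voting = ~mesh.degenerate[idx]
    idx, g = idx[voting], g[voting]
    if len(idx) == 0:
        raise ValueError("isolated vertex: empty geodesic neighborhood")
    votes, valid = _votes_batch(
        mesh.normals[idx], mesh.centroids[v], mesh.centroids[idx]
    )
    a_max = mesh.areas.max()
    w = (mesh.areas[idx] / a_max) * np.exp(-g / params.sigma)
    w = np.where(valid, w, 0.0)
    return (votes * w[:, None]).T @ votes


def estimate_normal(V_v: np.ndarray, original_normal: np.ndarray) -> np.ndarray:
    """Estimated normal: dominant eigenvector of ``V_v``, sign from the
    original oriented normal."""
    if not np.any(np.abs(V_v) > 0):
        raise ValueError("zero vote matrix")
    eigvals, eigvecs = np.linalg.eigh(V_v)
    e1 = eigvecs[:, -1]
    if np.dot(e1, original_normal) < 0:
        e1 = -e1
    return e1


def estimate_normals(
    mesh: TriangleMesh,
    graph: SurfaceGraph,
    params: NeighborhoodParams,
    neighborhoods: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vector-voting normals for every triangle.

    Returns ``(n_v, flagged)`` where ``n_v`` is (m, 3) and ``flagged`` marks
    triangles with an empty neighborhood (they keep their original normal).
    """
    m = mesh.n_triangles
    if neighborhoods is None:
        neighborhoods = graph.geodesic_neighborhoods(params.g_max)
    original = mesh.normals
    centroids = mesh.centroids
    areas = mesh.areas
    a_max = areas.max()
    degenerate = mesh.degenerate
    n_v = original.copy()
    flagged = np.zeros(m, dtype=bool)
    for v in range(m):
        idx, g = neighborhoods[v]
        voting = ~degenerate[idx]
        idx, g = idx[voting], g[voting]
        if len(idx) == 0:
            flagged[v] = True
            continue
        votes, valid = _votes_batch(original[idx], centroids[v], centroids[idx])
        w = (areas[idx] / a_max) * np.exp(-g / params.sigma)
        w = np.where(valid, w, 0.0)
        if not w.any():
            flagged[v] = True
            continue
        V_v = (votes * w[:, None]).T @ votes
        n_v[v] = estimate_normal(V_v, original[v])
    return n_v, flagged
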
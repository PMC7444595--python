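"""Principal curvature/direction estimation by curvature tensor voting.

Every triangle center v with estimated normal n_v collects *curvature votes*
from neighbors and accumulates them into a 3x3 symmetric tensor

    B_v = (1/2pi) sum_i w_i kappa_i t_i t_i^T,      sum_i w_i = 2pi,

where t_i is the unit tangent at v toward neighbor v_i and kappa_i the
normal curvature of the circular arc through v and v_i.  Under the inward-
normal convention kappa_i is positive where the patch bends toward the
normal.  The eigenvector of B_v most parallel to n_v is the (diagnostic)
near-zero direction b_3; the remaining eigenvalues b_1 >= b_2 give the
principal directions t_1, t_2 and curvatures

    kappa_1 = 3 b_1 - b_2,      kappa_2 = 3 b_2 - b_1

(the averaging of Euler's formula over tangent directions contracts the
spectrum; this linear map undoes it exactly for isotropic vote coverage).

Algorithm variants
------------------
RVV   geodesic-distance weights ``exp(-g_i/sigma)``.
AVV   RVV weights additionally scaled by relative triangle area
      ``a_i/a_max`` (default; robust to non-uniform tessellation).
NVV   arc curvature replaced by turning angle / geodesic distance
      (``kappa_i = phi_i/g_i``); retained only because its sign estimation
      fails on non-convex surfaces, which the tests document.
SSVV  no geodesic neighborhood: eight surface points are sampled by
      shooting lines parallel to n_v from the tips of tangent vectors of
      length rh; each sample contributes the curvature of the osculating
      circle through v, equally weighted, ``B_v = (1/8) sum kappa_i t t^T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import NeighborhoodParams, SurfaceGraph
from .mesh import TriangleMesh
from .normals import estimate_normals

_EPS = 1e-12

ALGORITHMS = ("AVV", "RVV", "NVV", "SSVV")


# ----------------------------------------------------------------------
# single-vote primitives
# ----------------------------------------------------------------------
def tangent_direction(
    v: np.ndarray, n_v: np.ndarray, v_i: np.ndarray
) -> np.ndarray | None:
    """Unit tangent at ``v`` toward ``v_i`` (projection onto tangent plane).

    Returns None (skip signal) when ``v_i - v`` is parallel to the normal.
    """
    vv = np.asarray(v_i, dtype=float) - np.asarray(v, dtype=float)
    if np.linalg.norm(vv) < _EPS:
        raise ValueError("coincident points")
    proj = vv - np.dot(n_v, vv) * np.asarray(n_v, dtype=float)
    norm = np.linalg.norm(proj)
    if norm < _EPS:
        return None
    return proj / norm


def normal_curvature(
    v: np.ndarray, n_v: np.ndarray, v_i: np.ndarray, n_vi: np.ndarray
) -> float | None:
    """Signed normal curvature of the arc through ``v`` and ``v_i``.

    |kappa| = 2 sin(phi/2) / ||v_i - v|| with phi the turning angle between
    n_v and the projection of n_vi onto the arc plane; the sign is positive
    when the patch bends toward the normal.  Returns None on degenerate
    geometry (skip signal).
    """
    t = tangent_direction(v, n_v, v_i)
    if t is None:
        return None
    vv = np.asarray(v_i, dtype=float) - np.asarray(v, dtype=float)
    p = np.cross(n_v, t)
    n_vip = np.asarray(n_vi, dtype=float) - np.dot(p, n_vi) * p
    norm = np.linalg.norm(n_vip)
    if norm < _EPS:
        return None
    u = n_vip / norm
    phi = np.arctan2(np.linalg.norm(np.cross(n_v, u)), np.dot(n_v, u))
    kappa = 2.0 * np.sin(phi / 2.0) / np.linalg.norm(vv)
    return -np.sign(np.dot(t, n_vip)) * kappa


# ----------------------------------------------------------------------
# vote collection (vectorized per center)
# ----------------------------------------------------------------------
def _curvature_votes_batch(
    c_v: np.ndarray,
    n_v: np.ndarray,
    c_nb: np.ndarray,
    n_nb: np.ndarray,
    g: np.ndarray,
    use_turning_angle: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangents, signed curvatures and validity for one neighborhood."""
    vv = c_nb - c_v
    proj = vv - np.outer(vv @ n_v, n_v)
    tnorm = np.linalg.norm(proj, axis=1)
    valid = tnorm >= _EPS
    t = np.zeros_like(proj)
    t[valid] = proj[valid] / tnorm[valid, None]

    p = np.cross(np.broadcast_to(n_v, t.shape), t)
    n_vip = n_nb - p * (p * n_nb).sum(axis=1)[:, None]
    nnorm = np.linalg.norm(n_vip, axis=1)
    valid &= nnorm >= _EPS
    u = np.zeros_like(n_vip)
    ok = nnorm >= _EPS
    u[ok] = n_vip[ok] / nnorm[ok, None]
    sin_phi = np.linalg.norm(np.cross(np.broadcast_to(n_v, u.shape), u), axis=1)
    cos_phi = u @ n_v
    phi = np.arctan2(sin_phi, cos_phi)
    if use_turning_angle:
        # NVV: curvature = turning angle / arc length, *unsigned* as in the
        # original vertex-voting formulation; this is what makes NVV unable
        # to recover negative curvature on non-convex surfaces.
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa = np.where(g > _EPS, phi / np.maximum(g, _EPS), 0.0)
    else:
        mag = 2.0 * np.sin(phi / 2.0) / np.linalg.norm(vv, axis=1)
        kappa = -np.sign((t * n_vip).sum(axis=1)) * mag
    return t, kappa, valid


def collect_curvature_votes(
    mesh: TriangleMesh,
    graph: SurfaceGraph,
    v: int,
    params: NeighborhoodParams,
    variant: str = "AVV",
    normals: np.ndarray | None = None,
    neighborhood: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Curvature tensor ``B_v`` (3x3) for triangle ``v``.

    ``normals`` are the VV-estimated normals for the whole mesh (falls back
    to the raw mesh normals).  Raises on an empty neighborhood.
    """
    if variant not in ("RVV", "AVV", "NVV"):
        raise ValueError(f"unknown variant {variant!r}")
    if normals is None:
        normals = mesh.normals
    if neighborhood is None:
        neighborhood = graph.geodesic_neighborhood(v, params.g_max)
    idx, g = neighborhood
    voting = ~mesh.degenerate[idx]
    idx, g = idx[voting], g[voting]
    if len(idx) == 0:
        raise ValueError("isolated vertex: empty geodesic neighborhood")
    t, kappa, valid = _curvature_votes_batch(
        mesh.centroids[v],
        normals[v],
        mesh.centroids[idx],
        normals[idx],
        g,
        use_turning_angle=(variant == "NVV"),
    )
    w = np.exp(-g / params.sigma)
    if variant == "AVV":
        w = w * (mesh.areas[idx] / mesh.areas.max())
    w = np.where(valid, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no valid curvature votes")
    w = w * (2.0 * np.pi / total)
    return (t * (w * kappa)[:, None]).T @ t / (2.0 * np.pi)


# ----------------------------------------------------------------------
# SSVV: surface sampling
# ----------------------------------------------------------------------
def _line_mesh_intersections(
    origins: np.ndarray,
    direction: np.ndarray,
    tri_pts: np.ndarray,
    exclude_tri: np.ndarray,
    max_offset: float,
    tri_chunk: int = 4096,
    line_chunk: int = 128,
) -> np.ndarray:
    """Signed line parameter of the nearest mesh intersection per line.

    For each line ``origins[k] + s * direction[k]`` returns the ``s`` of the
    intersection minimizing ``|s|`` subject to ``|s| <= max_offset``,
    ignoring triangle ``exclude_tri[k]``; NaN when there is none.
    Moller-Trumbore, vectorized over (lines x triangles) in chunks.
    """
    n_all = len(origins)
    result = np.full(n_all, np.nan)
    for lstart in range(0, n_all, line_chunk):
        lsl = slice(lstart, lstart + line_chunk)
        result[lsl] = _line_mesh_chunk(
            origins[lsl], direction[lsl], tri_pts, exclude_tri[lsl],
            max_offset, tri_chunk,
        )
    return result


def _line_mesh_chunk(
    origins: np.ndarray,
    direction: np.ndarray,
    tri_pts: np.ndarray,
    exclude_tri: np.ndarray,
    max_offset: float,
    tri_chunk: int,
) -> np.ndarray:
    n_lines = len(origins)
    best = np.full(n_lines, np.nan)
    best_abs = np.full(n_lines, np.inf)
    A = tri_pts[:, 0]
    e1 = tri_pts[:, 1] - A
    e2 = tri_pts[:, 2] - A
    for start in range(0, len(tri_pts), tri_chunk):
        sl = slice(start, start + tri_chunk)
        a, b, c = A[sl], e1[sl], e2[sl]
        # (n_lines, n_tri, 3) broadcasting
        h = np.cross(direction[:, None, :], c[None, :, :])
        det = (b[None, :, :] * h).sum(-1)
        ok = np.abs(det) > _EPS
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s_vec = origins[:, None, :] - a[None, :, :]
        u = inv * (s_vec * h).sum(-1)
        ok &= (u >= -1e-9) & (u <= 1 + 1e-9)
        q = np.cross(s_vec, b[None, :, :])
        w = inv * (direction[:, None, :] * q).sum(-1)
        ok &= (w >= -1e-9) & (u + w <= 1 + 1e-9)
        s = inv * (c[None, :, :] * q).sum(-1)
        ok &= np.abs(s) <= max_offset
        tri_idx = np.arange(start, start + len(a))
        ok &= tri_idx[None, :] != exclude_tri[:, None]
        s = np.where(ok, s, np.inf)
        cand = np.argmin(np.abs(s), axis=1)
        cand_s = s[np.arange(n_lines), cand]
        better = np.abs(cand_s) < best_abs
        best[better] = cand_s[better]
        best_abs[better] = np.abs(cand_s[better])
    return best


def _ssvv_tangent_frame(n_v: np.ndarray) -> np.ndarray:
    """Eight deterministic tangent directions (pi/4 apart) around ``n_v``.

    The first is the normalized tangent-plane projection of the global
    x-axis (y-axis fallback), so runs are reproducible without a seed.
    """
    for axis in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
        t0 = axis - np.dot(n_v, axis) * n_v
        norm = np.linalg.norm(t0)
        if norm >= 1e-6:
            t0 = t0 / norm
            break
    t90 = np.cross(n_v, t0)
    angles = np.arange(8) * (np.pi / 4.0)
    return np.outer(np.cos(angles), t0) + np.outer(np.sin(angles), t90)


def ssvv_votes(
    mesh: TriangleMesh,
    v: int,
    n_v: np.ndarray,
    rh: float,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """SSVV curvature tensor for triangle ``v`` (see module docstring).

    Raises when fewer than 3 of the 8 sample lines hit the surface within
    2*rh of the tangent tip (rank-deficient tensor; the regime where SSVV
    collapses once rh reaches the feature radius).
    """
    if _precomputed is not None:
        tangents, s = _precomputed
    else:
        tangents = _ssvv_tangent_frame(np.asarray(n_v, dtype=float))
        origins = mesh.centroids[v] + rh * tangents
        s = _line_mesh_intersections(
            origins,
            np.broadcast_to(n_v, (8, 3)).astype(float),
            mesh.triangle_points,
            np.full(8, v),
            max_offset=2.0 * rh,
        )
    hit = np.isfinite(s)
    if hit.sum() < 3:
        raise ValueError("SSVV: fewer than 3 surface intersections")
    h = s[hit]
    kappa = 2.0 * h / (rh**2 + h**2)
    t = tangents[hit]
    return (t * kappa[:, None]).T @ t / 8.0


# ----------------------------------------------------------------------
# tensor decomposition and combined measures
# ----------------------------------------------------------------------
def principal_from_tensor(
    B: np.ndarray, n_v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float, float, float]:
    """Principal directions/curvatures from a curvature tensor.

    The eigenvector most parallel to ``n_v`` is the diagnostic near-zero
    direction b_3; the remaining eigenvalues, sorted descending, give
    b_1 >= b_2.  Returns ``(t_1, t_2, kappa_1, kappa_2, |b_3|,
    angle(b_3, n_v))``.
    """
    eigvals, eigvecs = np.linalg.eigh(np.asarray(B, dtype=float))
    i3 = int(np.argmax(np.abs(eigvecs.T @ np.asarray(n_v, dtype=float))))
    rest = [i for i in range(3) if i != i3]
    rest.sort(key=lambda i: eigvals[i], reverse=True)
    i1, i2 = rest
    b1, b2 = eigvals[i1], eigvals[i2]
    kappa_1 = 3.0 * b1 - b2
    kappa_2 = 3.0 * b2 - b1
    cos_a = np.clip(np.abs(np.dot(eigvecs[:, i3], n_v)), -1.0, 1.0)
    return (
        eigvecs[:, i1],
        eigvecs[:, i2],
        float(kappa_1),
        float(kappa_2),
        float(abs(eigvals[i3])),
        float(np.arccos(cos_a)),
    )


def combined_measures(kappa_1, kappa_2):
    """Mean curvature H, Gaussian curvature K, curvedness C, shape index SI.

    SI follows Koenderink's convention with the umbilic limit
    ``kappa_1 = kappa_2`` mapped to ``sign(kappa_1)`` (0 on a plane).
    """
    k1 = np.asarray(kappa_1, dtype=float)
    k2 = np.asarray(kappa_2, dtype=float)
    H = (k1 + k2) / 2.0
    K = k1 * k2
    C = np.sqrt((k1**2 + k2**2) / 2.0)
    diff = k1 - k2
    with np.errstate(divide="ignore", invalid="ignore"):
        si = (2.0 / np.pi) * np.arctan(np.where(diff != 0, (k1 + k2) / np.where(diff != 0, diff, 1.0), 0.0))
    si = np.where(diff == 0, np.sign(k1), si)
    if np.isscalar(kappa_1) or np.ndim(kappa_1) == 0:
        return float(H), float(K), float(C), float(si)
    return H, K, C, si


# ----------------------------------------------------------------------
# whole-mesh driver
# ----------------------------------------------------------------------
@dataclass
class CurvatureResult:
    """Per-triangle estimation results; flagged triangles carry NaN."""

    n_v: np.ndarray
    t_1: np.ndarray
    t_2: np.ndarray
    kappa_1: np.ndarray
    kappa_2: np.ndarray
    mean_curvature: np.ndarray
    gauss_curvature: np.ndarray
    curvedness: np.ndarray
    shape_index: np.ndarray
    b3_abs: np.ndarray
    b3_angle: np.ndarray
    flagged: np.ndarray

    def as_attributes(self) -> dict[str, np.ndarray]:
        """Arrays keyed by the .vtp CellData names."""
        return {
            "n_v": self.n_v,
            "t_1": self.t_1,
            "t_2": self.t_2,
            "kappa_1": self.kappa_1,
            "kappa_2": self.kappa_2,
            "mean_curvature": self.mean_curvature,
            "gauss_curvature": self.gauss_curvature,
            "curvedness": self.curvedness,
            "shape_index": self.shape_index,
        }

    def scaled(self, factor: float) -> "CurvatureResult":
        """Curvatures converted by 1/length scale ``factor`` (units change)."""
        return CurvatureResult(
            n_v=self.n_v,
            t_1=self.t_1,
            t_2=self.t_2,
            kappa_1=self.kappa_1 * factor,
            kappa_2=self.kappa_2 * factor,
            mean_curvature=self.mean_curvature * factor,
            gauss_curvature=self.gauss_curvature * factor**2,
            curvedness=self.curvedness * factor,
            shape_index=self.shape_index,
            b3_abs=self.b3_abs * factor,
            b3_angle=self.b3_angle,
            flagged=self.flagged,
        )


def estimate_curvatures(
    mesh: TriangleMesh,
    graph: SurfaceGraph,
    radius_hit: float,
    algorithm: str = "AVV",
    normals: np.ndarray | None = None,
    neighborhoods: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CurvatureResult:
    """Full per-triangle curvature estimation.

    When ``normals`` is None the VV normals are estimated first with the
    same ``radius_hit``.  ``neighborhoods`` may pass precomputed geodesic
    neighborhoods at ``g_max = pi*radius_hit/2`` (they are computed once and
    shared between the normal and curvature steps otherwise).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    params = NeighborhoodParams(radius_hit)
    m = mesh.n_triangles
    needs_nbhd = normals is None or algorithm != "SSVV"
    if neighborhoods is None and needs_nbhd:
        neighborhoods = graph.geodesic_neighborhoods(params.g_max)
    if normals is None:
        normals, _ = estimate_normals(mesh, graph, params, neighborhoods)

    centroids = mesh.centroids
    areas = mesh.areas
    a_max = areas.max()
    degenerate = mesh.degenerate

    t_1 = np.full((m, 3), np.nan)
    t_2 = np.full((m, 3), np.nan)
    kappa_1 = np.full(m, np.nan)
    kappa_2 = np.full(m, np.nan)
    b3_abs = np.full(m, np.nan)
    b3_angle = np.full(m, np.nan)
    flagged = np.zeros(m, dtype=bool)

    if algorithm == "SSVV":
        # batch all 8*m sample lines through one intersection pass
        tangents = np.stack([_ssvv_tangent_frame(normals[v]) for v in range(m)])
        origins = (centroids[:, None, :] + radius_hit * tangents).reshape(-1, 3)
        dirs = np.repeat(normals, 8, axis=0)
        s = _line_mesh_intersections(
            origins,
            dirs,
            mesh.triangle_points,
            np.repeat(np.arange(m), 8),
            max_offset=2.0 * radius_hit,
        ).reshape(m, 8)
        for v in range(m):
            try:
                B = ssvv_votes(
                    mesh, v, normals[v], radius_hit,
                    _precomputed=(tangents[v], s[v]),
                )
            except ValueError:
                flagged[v] = True
                continue
            t_1[v], t_2[v], kappa_1[v], kappa_2[v], b3_abs[v], b3_angle[v] = (
                principal_from_tensor(B, normals[v])
            )
    else:
        use_ta = algorithm == "NVV"
        for v in range(m):
            idx, g = neighborhoods[v]
            voting = ~degenerate[idx]
            idx, g = idx[voting], g[voting]
            if len(idx) == 0:
                flagged[v] = True
                continue
            t, kappa, valid = _curvature_votes_batch(
                centroids[v], normals[v], centroids[idx], normals[idx], g, use_ta
            )
            w = np.exp(-g / params.sigma)
            if algorithm == "AVV":
                w = w * (areas[idx] / a_max)
            w = np.where(valid, w, 0.0)
            total = w.sum()
            if total <= 0:
                flagged[v] = True
                continue
            w = w * (2.0 * np.pi / total)
            B = (t * (w * kappa)[:, None]).T @ t / (2.0 * np.pi)
            t_1[v], t_2[v], kappa_1[v], kappa_2[v], b3_abs[v], b3_angle[v] = (
                principal_from_tensor(B, normals[v])
            )

    H, K, C, SI = combined_measures(kappa_1, kappa_2)
    return CurvatureResult(
        n_v=normals,
        t_1=t_1,
        t_2=t_2,
        kappa_1=kappa_1,
        kappa_2=kappa_2,
        mean_curvature=H,
        gauss_curvature=K,
        curvedness=C,
        shape_index=SI,
        b3_abs=b3_abs,
        b3_angle=b3_angle,
        flagged=flagged,
    )
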
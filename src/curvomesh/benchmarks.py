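"""Synthetic benchmark surfaces with analytic ground truth.

Two families, mirroring the two noise regimes of segmentation-derived data:

* voxel benchmarks (``make_voxel_sphere``, ``make_smooth_sphere``) are
  isosurfaces of binary/smoothed ball masks and carry quantization noise
  (or the irregular tessellation left after smoothing);
* parametric benchmarks (``make_noisy_plane``, ``make_torus``,
  ``make_cylinder``) are regular parameter-grid triangulations with exact
  analytic curvature at every triangle.

All lengths are in voxels; truth normals follow the inward convention, so
convex regions have positive principal curvatures.  Where a truth field is
undefined (principal directions on a plane or sphere) it is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .mesh import TriangleMesh
from .surface import _oriented_isosurface, binary_voxel_surface


@dataclass
class BenchmarkSurface:
    """A mesh plus analytic per-triangle ground truth."""

    mesh: TriangleMesh
    true_normals: np.ndarray
    true_kappa_1: np.ndarray
    true_kappa_2: np.ndarray
    true_t_1: np.ndarray
    true_t_2: np.ndarray
    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.true_kappa_1 < self.true_kappa_2):
            raise ValueError("ground truth must satisfy kappa_1 >= kappa_2")


def _grid_triangulation(n_rows: int, n_cols: int, wrap_rows: bool, wrap_cols: bool):
    """Faces of a regular (n_rows x n_cols) vertex grid, optionally periodic."""
    r = n_rows if wrap_rows else n_rows - 1
    c = n_cols if wrap_cols else n_cols - 1
    faces = []
    for i in range(r):
        i1 = (i + 1) % n_rows
        for j in range(c):
            j1 = (j + 1) % n_cols
            a = i * n_cols + j
            b = i * n_cols + j1
            cc = i1 * n_cols + j
            d = i1 * n_cols + j1
            faces.append((a, b, d))
            faces.append((a, d, cc))
    return np.array(faces, dtype=np.int64)


def _orient_to(mesh: TriangleMesh, target_normals: np.ndarray) -> TriangleMesh:
    """Globally flip winding so face normals agree with ``target_normals``."""
    if (mesh.normals * target_normals).sum() < 0:
        return mesh.flip_orientation()
    return mesh


# ----------------------------------------------------------------------
def make_noisy_plane(
    half_size: int = 36, noise_fraction: float = 0.1, seed: int = 0
) -> BenchmarkSurface:
    """Regularly triangulated plane with vertices displaced along their
    normals by Gaussian noise of standard deviation
    ``noise_fraction * average_edge_length`` (quantization-noise proxy).

    The default extent gives > 10^4 triangles at unit vertex spacing.
    Truth: normal = +z, kappa_1 = kappa_2 = 0.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    n = 2 * half_size + 1
    u = np.arange(n, dtype=float) - half_size
    xx, yy = np.meshgrid(u, u, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = _grid_triangulation(n, n, wrap_rows=False, wrap_cols=False)

    flat = TriangleMesh(vertices, faces)
    edges = flat.triangle_points - np.roll(flat.triangle_points, 1, axis=1)
    avg_edge = np.linalg.norm(edges, axis=2).mean()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_fraction * avg_edge, size=len(vertices))
    vertices = vertices + noise[:, None] * np.array([0.0, 0.0, 1.0])

    mesh = TriangleMesh(vertices, faces)
    z = np.array([0.0, 0.0, 1.0])
    mesh = _orient_to(mesh, np.broadcast_to(z, (mesh.n_triangles, 3)))
    m = mesh.n_triangles
    nan3 = np.full((m, 3), np.nan)
    return BenchmarkSurface(
        mesh=mesh,
        true_normals=np.broadcast_to(z, (m, 3)).copy(),
        true_kappa_1=np.zeros(m),
        true_kappa_2=np.zeros(m),
        true_t_1=nan3.copy(),
        true_t_2=nan3.copy(),
        name="noisy_plane",
        params={
            "half_size": half_size,
            "noise_fraction": noise_fraction,
            "avg_edge": float(avg_edge),
        },
        seed=seed,
    )


def _sphere_truth(mesh: TriangleMesh, center: np.ndarray, r: float):
    inward = center - mesh.centroids
    inward /= np.linalg.norm(inward, axis=1, keepdims=True)
    m = mesh.n_triangles
    nan3 = np.full((m, 3), np.nan)
    return inward, np.full(m, 1.0 / r), np.full(m, 1.0 / r), nan3, nan3.copy()


def make_voxel_sphere(r: float = 10.0, box: int = 25) -> BenchmarkSurface:
    """Sphere surface with full quantization noise from a binary ball mask.

    The ball of radius ``r`` is voxelized in a ``box**3`` volume and the
    exact voxel-boundary surface is extracted (no smoothing, no label
    interpolation): the triangles follow the voxel faces in steps, which is
    the noise regime binary segmentations actually produce.  Truth:
    kappa = 1/r, inward radial normals.
    """
    center = np.full(3, (box - 1) / 2.0)
    if r + 1 > (box - 1) / 2.0:
        raise ValueError(f"radius {r} does not fit in a {box}^3 volume")
    zz, yy, xx = np.mgrid[:box, :box, :box].astype(float)
    dist2 = (xx - center[2]) ** 2 + (yy - center[1]) ** 2 + (zz - center[0]) ** 2
    mask = dist2 <= r**2
    mesh = binary_voxel_surface(mask)
    normals, k1, k2, t1, t2 = _sphere_truth(mesh, center, r)
    return BenchmarkSurface(
        mesh, normals, k1, k2, t1, t2,
        name="voxel_sphere", params={"r": r, "box": box},
    )


def make_smooth_sphere(
    r: float = 10.0, gauss_sigma: float = 3.3, box: int | None = None
) -> BenchmarkSurface:
    """Smooth, non-uniformly tessellated sphere from a Gaussian-smoothed
    ball mask.

    Smoothing a binary ball shifts the half-maximum level surface inward by
    about ``sigma**2 / r`` (interface diffusion under curvature), so the
    isosurface level is chosen as the spherically averaged field value at
    distance ``r`` from the center — the extracted surface then has radius
    ``r`` by construction and truth kappa = 1/r holds.
    """
    if box is None:
        box = 2 * int(np.ceil(r + 3.0 * gauss_sigma)) + 3
    center = np.full(3, (box - 1) / 2.0)
    zz, yy, xx = np.mgrid[:box, :box, :box].astype(float)
    dist2 = (xx - center[2]) ** 2 + (yy - center[1]) ** 2 + (zz - center[0]) ** 2
    mask = (dist2 <= r**2).astype(np.float64)
    field_ = ndimage.gaussian_filter(mask, sigma=gauss_sigma)

    # spherical average of the smoothed field at radius r (golden-spiral
    # directions; the field is isotropic up to grid effects)
    k = np.arange(500)
    phi = np.arccos(1 - 2 * (k + 0.5) / 500)
    theta = np.pi * (1 + 5**0.5) * k
    dirs = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    pts = center + r * dirs
    level = float(ndimage.map_coordinates(field_, pts.T, order=1).mean())
    mesh = _oriented_isosurface(field_, level=level)
    normals, k1, k2, t1, t2 = _sphere_truth(mesh, center, r)
    return BenchmarkSurface(
        mesh, normals, k1, k2, t1, t2,
        name="smooth_sphere",
        params={"r": r, "gauss_sigma": gauss_sigma, "box": box, "level": level},
    )


def make_torus(
    rr: float = 25.0, csr: float = 10.0, edge_length: float = 1.0
) -> BenchmarkSurface:
    """Parametric torus (ring radius ``rr``, cross-section radius ``csr``).

    Truth with inward normals: kappa_1 = 1/csr along the tube cross-section
    (t_1), kappa_2 = cos(psi) / (rr + csr*cos(psi)) along the ring (t_2),
    psi = 0 at the outer equator.  The inner half (psi > pi/2) has negative
    Gaussian curvature.
    """
    if not 0 < csr < rr:
        raise ValueError("torus requires 0 < csr < rr")
    n_major = max(16, int(round(2 * np.pi * rr / edge_length)))
    n_minor = max(8, int(round(2 * np.pi * csr / edge_length)))
    theta = 2 * np.pi * np.arange(n_major) / n_major
    psi = 2 * np.pi * np.arange(n_minor) / n_minor
    tt, pp = np.meshgrid(theta, psi, indexing="ij")
    x = (rr + csr * np.cos(pp)) * np.cos(tt)
    y = (rr + csr * np.cos(pp)) * np.sin(tt)
    z = csr * np.sin(pp)
    vertices = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    faces = _grid_triangulation(n_major, n_minor, wrap_rows=True, wrap_cols=True)
    mesh = TriangleMesh(vertices, faces)

    c = mesh.centroids
    th = np.arctan2(c[:, 1], c[:, 0])
    ring = np.column_stack([rr * np.cos(th), rr * np.sin(th), np.zeros(len(c))])
    w = c - ring
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    cos_psi = w[:, 0] * np.cos(th) + w[:, 1] * np.sin(th)
    sin_psi = w[:, 2]
    inward = -w
    mesh = _orient_to(mesh, inward)

    t1 = np.column_stack(
        [-sin_psi * np.cos(th), -sin_psi * np.sin(th), cos_psi]
    )
    t2 = np.column_stack([-np.sin(th), np.cos(th), np.zeros(len(c))])
    k1 = np.full(len(c), 1.0 / csr)
    k2 = cos_psi / (rr + csr * cos_psi)
    return BenchmarkSurface(
        mesh, inward, k1, k2, t1, t2,
        name="torus", params={"rr": rr, "csr": csr, "edge_length": edge_length},
    )


def make_cylinder(
    r: float = 10.0, h: float = 25.0, edge_length: float = 1.0
) -> BenchmarkSurface:
    """Open parametric cylinder (no caps), axis along z.

    Truth with inward normals: kappa_1 = 1/r circumferential (t_1),
    kappa_2 = 0 along the axis (t_2).  The two end rings are open borders.
    """
    n_circ = max(8, int(round(2 * np.pi * r / edge_length)))
    n_z = max(2, int(round(h / edge_length)) + 1)
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    z = np.linspace(0.0, h, n_z)
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    vertices = np.column_stack(
        [r * np.cos(tt).ravel(), r * np.sin(tt).ravel(), zz.ravel()]
    )
    faces = _grid_triangulation(n_z, n_circ, wrap_rows=False, wrap_cols=True)
    mesh = TriangleMesh(vertices, faces)

    c = mesh.centroids
    th = np.arctan2(c[:, 1], c[:, 0])
    inward = np.column_stack([-np.cos(th), -np.sin(th), np.zeros(len(c))])
    mesh = _orient_to(mesh, inward)
    t1 = np.column_stack([-np.sin(th), np.cos(th), np.zeros(len(c))])
    t2 = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (len(c), 3)).copy()
    return BenchmarkSurface(
        mesh, inward,
        np.full(len(c), 1.0 / r), np.zeros(len(c)), t1, t2,
        name="cylinder", params={"r": r, "h": h, "edge_length": edge_length},
    )


GENERATORS = {
    "plane": make_noisy_plane,
    "voxel-sphere": make_voxel_sphere,
    "smooth-sphere": make_smooth_sphere,
    "torus": make_torus,
    "cylinder": make_cylinder,
}
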
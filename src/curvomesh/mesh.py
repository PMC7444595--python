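"""Triangle-mesh data model.

Surfaces are represented as oriented triangle meshes; all estimation happens
at triangle centers (centroids), not mesh vertices, so the per-triangle
quantities (centroid, area, normal) are the primary geometry here.

Orientation convention: normals point *inward* on a convex closed surface
(toward the enclosed volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: triangles with area below this (input units squared) are treated as
#: degenerate: they keep their graph vertex but cast no votes.
DEGENERATE_AREA = 1e-12


@dataclass
class TriangleMesh:
    """An oriented triangle mesh with per-triangle attribute arrays.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Vertex positions, in voxel or physical (e.g. nm) units.
    faces : (n_triangles, 3) int array
        Vertex indices of each triangle. The winding defines the normal via
        the right-hand rule.
    attributes : dict of str -> (n_triangles, ...) array
        Named per-triangle result arrays (e.g. ``"kappa_1"``). Flagged
        triangles carry NaN sentinels.
    """

    vertices: np.ndarray
    faces: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            if np.any(
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ):
                raise ValueError("faces must reference three distinct vertices")
        self._cache: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------
    # derived per-triangle geometry (cached)
    # ------------------------------------------------------------------
    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    @property
    def triangle_points(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        if "tp" not in self._cache:
            self._cache["tp"] = self.vertices[self.faces]
        return self._cache["tp"]

    @property
    def centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.triangle_points.mean(axis=1)
        return self._cache["centroids"]

    @property
    def areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            tp = self.triangle_points
            cross = np.cross(tp[:, 1] - tp[:, 0], tp[:, 2] - tp[:, 0])
            self._cache["areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["areas"]

    @property
    def normals(self) -> np.ndarray:
        """Unit normals from the face winding; zero rows for degenerate faces."""
        if "normals" not in self._cache:
            tp = self.triangle_points
            cross = np.cross(tp[:, 1] - tp[:, 0], tp[:, 2] - tp[:, 0])
            norm = np.linalg.norm(cross, axis=1)
            out = np.zeros_like(cross)
            ok = norm > 0
            out[ok] = cross[ok] / norm[ok, None]
            self._cache["normals"] = out
        return self._cache["normals"]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of triangles excluded from voting."""
        return self.areas < DEGENERATE_AREA

    # ------------------------------------------------------------------
    def flip_orientation(self) -> "TriangleMesh":
        """Return a copy with reversed winding (all normals negated)."""
        return TriangleMesh(
            self.vertices.copy(),
            self.faces[:, ::-1].copy(),
            {k: v.copy() for k, v in self.attributes.items()},
        )

    def submesh(self, keep: np.ndarray) -> "TriangleMesh":
        """Mesh restricted to triangles selected by boolean mask or index array.

        Unreferenced vertices are dropped; attribute arrays are sliced along
        the triangle axis.
        """
        keep = np.asarray(keep)
        faces = self.faces[keep]
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = TriangleMesh(self.vertices[used], remap[faces])
        for name, arr in self.attributes.items():
            sub.attributes[name] = np.asarray(arr)[keep]
        return sub

    def scaled(self, factor: float) -> "TriangleMesh":
        """Mesh with coordinates multiplied by ``factor`` (unit conversion)."""
        return TriangleMesh(
            self.vertices * float(factor),
            self.faces.copy(),
            {k: v.copy() for k, v in self.attributes.items()},
        )
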
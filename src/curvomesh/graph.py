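"""Surface graph: triangle adjacency, geodesic neighborhoods, borders.

The triangle mesh is mapped to a spatially embedded graph with one vertex per
triangle, positioned at the triangle centroid.  Triangle pairs sharing a mesh
edge (two vertices) are linked by *strong* edges, pairs sharing a single mesh
vertex by *weak* edges.  Shortest paths over both edge classes (Dijkstra)
approximate geodesic distances along the surface; traversing weak edges as
well enlarges the path set and can only shorten paths.

Border triangles are those with fewer than three strong edges (an open mesh
edge has no partner triangle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .mesh import TriangleMesh


@dataclass(frozen=True)
class NeighborhoodParams:
    """Geodesic-neighborhood scale derived from the ``radius_hit`` parameter.

    ``radius_hit`` (rh) approximates the radius of the smallest feature whose
    curvature (rh**-1) can still be estimated reliably.  The maximum geodesic
    reach is a quarter circle of radius rh, ``g_max = pi * rh / 2``, and the
    exponential decay length of the vote weights is ``sigma = g_max / 3`` so
    that votes beyond the neighborhood would be negligible anyway.
    """

    radius_hit: float

    def __post_init__(self) -> None:
        if self.radius_hit <= 0:
            raise ValueError("radius_hit must be positive")

    @property
    def g_max(self) -> float:
        return np.pi * self.radius_hit / 2.0

    @property
    def sigma(self) -> float:
        return self.g_max / 3.0


class SurfaceGraph:
    """Graph on triangle centroids with strong/weak edges.

    Edge lengths are Euclidean distances between the two triangle centroids.

    Attributes
    ----------
    positions : (n, 3) array
        Centroid of each triangle (= graph vertex position).
    strong, weak : scipy.sparse.csr_matrix
        Symmetric weighted adjacency matrices of each edge class.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_triangles == 0:
            raise ValueError("empty mesh")
        self.mesh = mesh
        self.positions = mesh.centroids
        n = mesh.n_triangles

        # incidence triangle x mesh-vertex; S[i, j] = #shared mesh vertices
        rows = np.repeat(np.arange(n), 3)
        cols = mesh.faces.ravel()
        inc = sparse.csr_matrix(
            (np.ones(3 * n, dtype=np.int8), (rows, cols)),
            shape=(n, int(mesh.faces.max()) + 1 if n else 0),
        )
        shared = (inc @ inc.T).tocoo()
        i, j, c = shared.row, shared.col, shared.data
        off = i < j  # upper triangle, drop self-pairs
        i, j, c = i[off], j[off], c[off]

        lengths = np.linalg.norm(self.positions[i] - self.positions[j], axis=1)
        # coincident centroids would create zero-length edges; keep them at a
        # tiny positive length so Dijkstra stays well-defined
        lengths = np.maximum(lengths, 1e-12)

        def _sym(mask: np.ndarray) -> sparse.csr_matrix:
            m = sparse.csr_matrix(
                (lengths[mask], (i[mask], j[mask])), shape=(n, n)
            )
            return (m + m.T).tocsr()

        self.strong = _sym(c == 2)
        self.weak = _sym(c == 1)
        self._adjacency = (self.strong + self.weak).tocsr()
        self._strong_degree = np.diff(self.strong.indptr)

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def strong_degree(self) -> np.ndarray:
        return self._strong_degree

    def border_vertices(self) -> np.ndarray:
        """Indices of border triangles (< 3 strong edges)."""
        return np.flatnonzero(self._strong_degree < 3)

    # ------------------------------------------------------------------
    def geodesic_neighborhood(
        self, v: int, g_max: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vertices within geodesic distance ``g_max`` of ``v`` (v excluded).

        Returns ``(indices, distances)``.
        """
        if g_max < 0:
            raise ValueError("g_max must be >= 0")
        dist = dijkstra(
            self._adjacency, directed=False, indices=int(v), limit=g_max
        )
        idx = np.flatnonzero(np.isfinite(dist))
        idx = idx[idx != v]
        return idx, dist[idx]

    def geodesic_neighborhoods(
        self,
        g_max: float,
        sources: np.ndarray | None = None,
        chunk: int = 512,
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Neighborhoods of many sources, computed in chunks.

        Returns a list of ``(indices, distances)`` pairs, one per source,
        each excluding the source itself.
        """
        if sources is None:
            sources = np.arange(self.n_vertices)
        sources = np.asarray(sources, dtype=np.int64)
        out: list[tuple[np.ndarray, np.ndarray]] = []
        for start in range(0, len(sources), chunk):
            batch = sources[start : start + chunk]
            dist = dijkstra(
                self._adjacency, directed=False, indices=batch, limit=g_max
            )
            for row, src in zip(dist, batch):
                idx = np.flatnonzero(np.isfinite(row))
                idx = idx[idx != src]
                out.append((idx, row[idx]))
        return out

    def geodesic_distances_from(self, sources: np.ndarray, limit: float) -> np.ndarray:
        """Distance matrix (len(sources), n) with inf beyond ``limit``."""
        return dijkstra(
            self._adjacency, directed=False, indices=np.asarray(sources), limit=limit
        )

    # ------------------------------------------------------------------
    def export_edge_list(self, path) -> None:
        """Plain-text edge list ``source target type length`` for debugging."""
        with open(path, "w") as fh:
            fh.write("# source target type length\n")
            for name, mat in (("strong", self.strong), ("weak", self.weak)):
                coo = sparse.triu(mat).tocoo()
                for a, b, w in zip(coo.row, coo.col, coo.data):
                    fh.write(f"{a} {b} {name} {w:.17g}\n")


def build_surface_graph(mesh: TriangleMesh) -> SurfaceGraph:
    """Build the strong/weak surface graph of a triangle mesh."""
    return SurfaceGraph(mesh)


def detect_borders(graph: SurfaceGraph) -> np.ndarray:
    """Border triangles of an (open) surface: < 3 strong edges."""
    return graph.border_vertices()


def filter_borders(
    mesh: TriangleMesh, graph: SurfaceGraph, exclusion: float
) -> TriangleMesh:
    """Remove triangles within geodesic distance ``exclusion`` of any border.

    Border triangles themselves are always removed when ``exclusion > 0``.
    A closed surface (no borders) or ``exclusion = 0`` returns the mesh
    unchanged.
    """
    if exclusion < 0:
        raise ValueError("exclusion must be >= 0")
    borders = graph.border_vertices()
    if exclusion == 0 or len(borders) == 0:
        return mesh
    dist = graph.geodesic_distances_from(borders, limit=exclusion)
    near = np.isfinite(dist).any(axis=0)
    near[borders] = True
    keep = ~near
    if not keep.any():
        raise ValueError("surface fully removed")
    return mesh.submesh(keep)
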
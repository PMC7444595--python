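"""Accuracy evaluation: error metrics, cumulative-histogram AUC, tables.

Two error types compare estimates with benchmark ground truth:

* vector error ``1 - |v_t . v_e|`` for normals and principal directions
  (orientation-sign invariant, 0 = parallel, 1 = perpendicular);
* scalar relative error ``|k_t - k_e| / |k_t|`` for principal curvatures
  (undefined for zero truth, where the absolute error ``|k_e|`` is used
  instead — e.g. the plane, or kappa_2 on the cylinder).

Accuracy over a surface is summarized as the normalized area under the
cumulative relative-frequency histogram of the errors (20 equal-width bins
over [0, 1] by default, errors clipped): 1 means all errors are zero, and
values near 0 mean all errors reach the clip limit.  Triangles flagged by
the estimator (no votes, failed sampling) are charged the maximum error so
that algorithm failures lower the score instead of silently vanishing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkSurface
from .curvature import CurvatureResult, estimate_curvatures
from .graph import SurfaceGraph
from .normals import estimate_normals


def vector_error(v_t: np.ndarray, v_e: np.ndarray) -> np.ndarray | float:
    """Orientation-invariant error between unit vectors, in [0, 1]."""
    v_t = np.asarray(v_t, dtype=float)
    v_e = np.asarray(v_e, dtype=float)
    dot = np.abs((v_t * v_e).sum(axis=-1))
    err = 1.0 - np.clip(dot, 0.0, 1.0)
    return float(err) if err.ndim == 0 else err


def scalar_relative_error(kappa_t, kappa_e) -> np.ndarray | float:
    """Relative curvature error ``|k_t - k_e| / |k_t|`` (k_t must be nonzero)."""
    kt = np.asarray(kappa_t, dtype=float)
    ke = np.asarray(kappa_e, dtype=float)
    if np.any(kt == 0):
        raise ValueError(
            "relative error undefined for zero true curvature; "
            "use the absolute error instead"
        )
    err = np.abs(kt - ke) / np.abs(kt)
    return float(err) if err.ndim == 0 else err


def curvature_errors(kappa_t: np.ndarray, kappa_e: np.ndarray) -> np.ndarray:
    """Per-triangle curvature errors: relative where the truth is nonzero,
    absolute where it is exactly zero; flagged (NaN) estimates become inf."""
    kt = np.asarray(kappa_t, dtype=float)
    ke = np.asarray(kappa_e, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.where(kt != 0, np.abs(kt - ke) / np.abs(kt), np.abs(ke))
    return np.where(np.isnan(ke), np.inf, err)


def cumulative_auc(
    errors: np.ndarray, max_error: float = 1.0, n_bins: int = 20
) -> float:
    """Normalized area under the cumulative error histogram, in [0, 1]."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot summarize an empty error list")
    if max_error <= 0 or n_bins < 1:
        raise ValueError("max_error and n_bins must be positive")
    clipped = np.clip(errors, 0.0, max_error)
    counts, _ = np.histogram(clipped, bins=n_bins, range=(0.0, max_error))
    cum = np.cumsum(counts) / errors.size
    return float(cum.mean())


def _border_near_mask(graph: SurfaceGraph, exclusion: float) -> np.ndarray:
    """Triangles within geodesic distance ``exclusion`` of a border."""
    near = np.zeros(graph.n_vertices, dtype=bool)
    borders = graph.border_vertices()
    if exclusion > 0 and len(borders):
        dist = graph.geodesic_distances_from(borders, limit=exclusion)
        near = np.isfinite(dist).any(axis=0)
        near[borders] = True
    return near


def benchmark_errors(
    bench: BenchmarkSurface,
    result: CurvatureResult,
    exclude: np.ndarray | None = None,
    max_error: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-triangle errors of a curvature result against the ground truth.

    ``exclude`` is a boolean mask of triangles left out (e.g. near borders).
    Flagged triangles are charged ``max_error``.
    """
    keep = np.ones(bench.mesh.n_triangles, dtype=bool)
    if exclude is not None:
        keep &= ~exclude
    ek1 = np.minimum(
        curvature_errors(bench.true_kappa_1[keep], result.kappa_1[keep]), max_error
    )
    ek2 = np.minimum(
        curvature_errors(bench.true_kappa_2[keep], result.kappa_2[keep]), max_error
    )
    out = {
        "kappa_1": ek1,
        "kappa_2": ek2,
        "pooled": np.concatenate([ek1, ek2]),
        "normals": vector_error(bench.true_normals[keep], result.n_v[keep]),
    }
    for name, t_true, t_est in (
        ("t_1", bench.true_t_1, result.t_1),
        ("t_2", bench.true_t_2, result.t_2),
    ):
        if not np.isnan(t_true[keep]).all():
            err = vector_error(t_true[keep], t_est[keep])
            out[name] = np.where(np.isnan(err), max_error, err)
    return out


def run_benchmark_table(
    bench: BenchmarkSurface,
    algorithms: list[str],
    rh_values: list[float],
    exclusion: float = 0.0,
    max_error: float = 1.0,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Accuracy table: per (algorithm, rh) the AUC of kappa_1, kappa_2 and
    pooled errors.

    Estimation runs on the full surface; triangles within ``exclusion`` of a
    border are excluded from the error statistics only.  A run where every
    retained triangle is flagged is a *failed* run: its AUCs are reported as
    0 with ``failed = True`` (total sampling collapse, e.g. SSVV with rh
    beyond the feature radius).
    """
    graph = SurfaceGraph(bench.mesh)
    near_border = _border_near_mask(graph, exclusion)
    max_rh = max(rh_values)
    from .graph import NeighborhoodParams

    nbhd_max = graph.geodesic_neighborhoods(NeighborhoodParams(max_rh).g_max)
    rows = []
    for rh in rh_values:
        g_max = NeighborhoodParams(rh).g_max
        if rh == max_rh:
            nbhds = nbhd_max
        else:
            nbhds = [
                (idx[d <= g_max], d[d <= g_max]) for idx, d in nbhd_max
            ]
        normals, _ = estimate_normals(
            bench.mesh, graph, NeighborhoodParams(rh), neighborhoods=nbhds
        )
        for alg in algorithms:
            result = estimate_curvatures(
                bench.mesh, graph, rh, algorithm=alg,
                normals=normals, neighborhoods=nbhds,
            )
            keep = ~near_border
            failed = bool(result.flagged[keep].all())
            if failed:
                aucs = {"auc_k1": 0.0, "auc_k2": 0.0, "auc_both": 0.0}
            else:
                errs = benchmark_errors(
                    bench, result, exclude=near_border, max_error=max_error
                )
                aucs = {
                    "auc_k1": cumulative_auc(errs["kappa_1"], max_error, n_bins),
                    "auc_k2": cumulative_auc(errs["kappa_2"], max_error, n_bins),
                    "auc_both": cumulative_auc(errs["pooled"], max_error, n_bins),
                }
            rows.append(
                {
                    "algorithm": alg,
                    "rh": rh,
                    **aucs,
                    "n_triangles": int(keep.sum()),
                    "n_failed": int(result.flagged[keep].sum()),
                    "failed": failed,
                }
            )
    return pd.DataFrame(rows)
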
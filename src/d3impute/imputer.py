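"""Density-guided imputation of flagged dropout positions.

For each cell a refined neighborhood ``E`` is built in two steps:
Euclidean k-nearest neighbors on the transformed matrix, then
re-ranking of those neighbors by shared-nearest-neighbor (SNN) overlap
|N_k(i) ∩ N_k(j)|.  The cell is projected along the line toward the
centroid ``F`` of ``E``,

    c_t = c_i + t·(F − c_i),    t ∈ t_grid,

choosing the grid point with the highest local density

    ρ(c_t) = 1 / (Σ_{c_j ∈ E} ‖c_t − c_j‖² + ε),

i.e. the smallest summed squared distance to the refined neighborhood.
Only positions flagged in the imputation index ``I1`` take values from
the projected matrix ``Y1``:

    Y_imputed = Y1 ⊙ I1 + X.

Observed entries and biological zeros pass through untouched.  All
projections are computed against the frozen input matrix so the result
does not depend on cell order; ``passes > 1`` repeats whole cycles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodPlan",
    "ProjectionResult",
    "ImputedMatrix",
    "build_neighborhoods",
    "project_cell",
    "impute_all",
    "default_t_grid",
]

_RHO_EPS = 1e-12


def default_t_grid() -> np.ndarray:
    """Eleven equispaced weights spanning "no move" (0) to "move to centroid" (1)."""
    return np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass
class NeighborhoodPlan:
    """kNN sets, SNN overlap counts and SNN-refined neighborhoods."""

    knn_sets: np.ndarray       # (n, k) Euclidean neighbors, nearest first
    snn_counts: np.ndarray     # (n, k) |N_k(i) ∩ N_k(j)| for j in N_k(i)
    refined_sets: np.ndarray   # (n, k) E(c_i): N_k(i) re-ranked by SNN overlap
    k: int


@dataclass
class ProjectionResult:
    centroid: np.ndarray
    t_grid: np.ndarray
    densities: np.ndarray
    chosen_t: float
    c_t_star: np.ndarray


@dataclass
class ImputedMatrix:
    Y1: np.ndarray
    Y_imputed: np.ndarray
    provenance: np.ndarray  # 0 observed, 1 imputed, 2 biological zero


def build_neighborhoods(X, k: int) -> NeighborhoodPlan:
    """Euclidean kNN per cell, SNN counts, and SNN-refined sets E.

    Distance ties break toward the lower cell index; SNN ties keep the
    original kNN rank.  ``E(c_i)`` is the top-k of ``N_k(c_i)`` by
    descending shared-neighbor count.
    """
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    n = values.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    D = cdist(values, values)
    np.fill_diagonal(D, np.inf)
    # stable sort on distance: ties by lower index
    knn = np.argsort(D, axis=1, kind="stable")[:, :k]
    member = np.zeros((n, n), dtype=bool)
    np.put_along_axis(member, knn, True, axis=1)
    overlap = (member.astype(np.int32) @ member.T.astype(np.int32))
    snn_counts = np.take_along_axis(overlap, knn, axis=1)
    # re-rank each cell's neighbors by descending SNN count, stable in kNN rank
    order = np.argsort(-snn_counts, axis=1, kind="stable")
    refined = np.take_along_axis(knn, order, axis=1)
    snn_sorted = np.take_along_axis(snn_counts, order, axis=1)
    return NeighborhoodPlan(knn_sets=knn, snn_counts=snn_sorted,
                            refined_sets=refined, k=k)


def project_cell(ci: np.ndarray, E: np.ndarray, t_grid=None) -> ProjectionResult:
    """Project one cell toward its refined-neighborhood centroid.

    Evaluates the density ρ(c_t) on every grid point and returns the
    densest candidate; ties go to the smaller t (the move closest to the
    original position).
    """
    ci = np.asarray(ci, dtype=float)
    E = np.atleast_2d(np.asarray(E, dtype=float))
    if E.size == 0:
        raise ValueError("refined neighborhood E must be non-empty")
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    F = E.mean(axis=0)
    candidates = ci[None, :] + t_grid[:, None] * (F - ci)[None, :]
    d2 = ((candidates[:, None, :] - E[None, :, :]) ** 2).sum(axis=(1, 2))
    densities = 1.0 / (d2 + _RHO_EPS)
    best = int(np.argmax(densities))  # first max: smallest t on ties
    # density maximization must coincide with distance-sum minimization
    assert d2[best] == d2.min()
    return ProjectionResult(
        centroid=F,
        t_grid=t_grid,
        densities=densities,
        chosen_t=float(t_grid[best]),
        c_t_star=candidates[best],
    )


def _project_all(values: np.ndarray, plan: NeighborhoodPlan,
                 t_grid: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Batch projection of the selected rows against the frozen matrix."""
    Y1 = values.copy()
    for i in rows:
        E = values[plan.refined_sets[i]]
        Y1[i] = project_cell(values[i], E, t_grid).c_t_star
    return Y1


def impute_all(X, I1: np.ndarray, k: int = 10, t_grid=None,
               passes: int = 1) -> ImputedMatrix:
    """Fill every flagged position from the density-guided projection.

    Only rows containing at least one flag are projected (the others
    never contribute values).  The final matrix is
    ``Y_imputed = Y1 ⊙ I1 + X``: observed entries keep their exact
    values, unflagged zeros stay exactly 0.
    """
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    I1 = np.asarray(I1, dtype=float)
    if I1.shape != values.shape:
        raise ValueError("I1 must match the expression matrix shape")
    if np.any((I1 != 0) & (values != 0)):
        raise ValueError("I1 flags an observed (non-zero) position")
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)

    flagged_rows = np.flatnonzero(I1.any(axis=1))
    Y1 = values.copy()
    current = values
    for _ in range(max(1, int(passes))):
        plan = build_neighborhoods(current, k)
        Y1 = _project_all(current, plan, t_grid, flagged_rows)
        current = Y1 * I1 + values
    Y_imputed = Y1 * I1 + values

    provenance = np.full(values.shape, 2, dtype=np.int8)  # biological zero
    provenance[values != 0] = 0                           # observed
    provenance[I1 == 1] = 1                               # imputed
    n_filled = int(I1.sum())
    logger.info("imputed %d positions across %d cells", n_filled, flagged_rows.size)
    return ImputedMatrix(Y1=Y1, Y_imputed=Y_imputed, provenance=provenance)
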
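"""Dual-network zero discriminator.

Zeros in a single-cell expression matrix mix genuine transcriptional
silence (biological zeros) with technical capture failures (dropouts).
This module classifies them by reconstructing the binary observation
indicator ``I0`` (1 where the transformed matrix is non-zero) with a
graph-regularized non-negative factorization ``I0 ≈ UᵀV``:

    min_{U,V ≥ 0}  ‖I0 − UᵀV‖²_F
                 + β(‖U‖²_F + ‖V‖²_F)
                 + λc·Tr(U L_c Uᵀ) + λg·Tr(V L_g Vᵀ)

where ``L_c`` / ``L_g`` are Laplacians of kNN-sparsified Pearson
similarity graphs over cells (from the single-cell matrix) and genes
(from a bulk or pseudo-bulk reference).  The multiplicative updates

    U ← U ⊙ (V·I0ᵀ + λc·U·Rc*) / (V·Vᵀ·U + β·U + λc·U·Dc)
    V ← V ⊙ (U·I0  + λg·V·Rg*) / (U·Uᵀ·V + β·V + λg·V·Dg)

keep both factors non-negative and decrease the objective monotonically.
Positions with ``I0 = 0`` whose reconstruction ``I* = UᵀV`` exceeds a
threshold τ are flagged in the imputation index ``I1``; everything else
is preserved as a biological zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraphs",
    "FactorPair",
    "build_indicator",
    "pearson_similarity",
    "knn_sparsify",
    "factorize",
    "reconstruct",
    "call_dropouts",
    "adaptive_tau",
]

_EPS = 1e-10


@dataclass
class NeighborGraphs:
    """A kNN-sparsified similarity graph with its Laplacian.

    ``S`` holds edge weights 1 (mutual neighbors), 0.5 (one-sided) or 0;
    ``R_sparse = S ⊙ max(R, 0)`` (negative correlations are clamped so
    the Laplacian stays positive semi-definite); ``degrees`` are the row
    sums of ``R_sparse`` and ``L = diag(degrees) − R_sparse``.
    """

    R: np.ndarray
    S: np.ndarray
    R_sparse: np.ndarray
    degrees: np.ndarray
    L: np.ndarray
    k: int


@dataclass
class FactorPair:
    """Non-negative factors U (p×n, cells) and V (p×m, genes)."""

    U: np.ndarray
    V: np.ndarray
    p: int
    beta: float
    lambda_c: float
    lambda_g: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    trace_terms: np.ndarray | None = None  # columns: recon, tikhonov, graph


def build_indicator(X) -> np.ndarray:
    """Binary indicator of observed entries: 1 where the matrix is non-zero."""
    values = X.values if hasattr(X, "values") else np.asarray(X)
    return (values != 0).astype(float)


def pearson_similarity(M: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Pairwise Pearson correlations of the rows or columns of ``M``.

    Constant vectors have undefined correlations; their off-diagonal
    similarities are set to 0 with a warning.  The diagonal is 1.
    """
    M = np.asarray(M, dtype=float)
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    V = M if axis == "rows" else M.T
    if V.shape[0] < 2:
        raise ValueError("need at least 2 vectors to correlate")
    sd = V.std(axis=1)
    const = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.corrcoef(V)
    R = np.nan_to_num(R, nan=0.0)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant vectors: correlations set to 0"
        )
        R[const, :] = 0.0
        R[:, const] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


def knn_sparsify(R: np.ndarray, k: int) -> NeighborGraphs:
    """Sparsify a symmetric similarity matrix by mutual-kNN weighting.

    Each node's k nearest neighbors are the k largest off-diagonal
    similarities (ties broken toward the lower index).  An edge gets
    weight 1 when both endpoints list each other, 0.5 when only one
    does, 0 otherwise; the sparsified similarity is this weight times
    the non-negative part of R.
    """
    R = np.asarray(R, dtype=float)
    d = R.shape[0]
    if R.shape != (d, d):
        raise ValueError("similarity matrix must be square")
    if not (1 <= k < d):
        raise ValueError(f"k must satisfy 1 <= k < {d}, got {k}")
    work = R.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort of -similarity breaks ties toward the lower index
    order = np.argsort(-work, axis=1, kind="stable")[:, :k]
    is_nbr = np.zeros((d, d), dtype=bool)
    np.put_along_axis(is_nbr, order, True, axis=1)
    S = np.where(is_nbr & is_nbr.T, 1.0, np.where(is_nbr | is_nbr.T, 0.5, 0.0))
    np.fill_diagonal(S, 0.0)
    R_sparse = S * np.maximum(R, 0.0)
    degrees = R_sparse.sum(axis=1)
    L = np.diag(degrees) - R_sparse
    return NeighborGraphs(R=R, S=S, R_sparse=R_sparse, degrees=degrees, L=L, k=k)


def _objective(I0, U, V, beta, lc, lg, graphs_c, graphs_g):
    recon = float(np.linalg.norm(I0 - U.T @ V) ** 2)
    tikh = float(beta * (np.sum(U**2) + np.sum(V**2)))
    graph = 0.0
    if lc > 0:
        graph += lc * float(np.sum((U @ graphs_c.L) * U))
    if lg > 0:
        graph += lg * float(np.sum((V @ graphs_g.L) * V))
    return recon, tikh, graph


def factorize(
    I0: np.ndarray,
    graphs_c: NeighborGraphs | None,
    graphs_g: NeighborGraphs | None,
    p: int = 10,
    beta: float = 0.01,
    lambda_c: float = 0.01,
    lambda_g: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> FactorPair:
    """Fit the graph-regularized NMF of the indicator matrix.

    Multiplicative updates run until the relative objective change drops
    below ``tol`` or ``max_iter`` is reached.  Initialization draws U, V
    uniformly on (0,1) scaled by sqrt(mean(I0)/p), so the initial UᵀV is
    on the scale of I0; the run is reproducible given ``seed``.
    """
    I0 = np.asarray(I0, dtype=float)
    n, m = I0.shape
    if min(beta, lambda_c, lambda_g) < 0:
        raise ValueError("hyperparameters must be non-negative")
    if p < 1:
        raise ValueError("latent dimension p must be >= 1")
    if lambda_c > 0 and graphs_c is None:
        raise ValueError("lambda_c > 0 requires a cell graph")
    if lambda_g > 0 and graphs_g is None:
        raise ValueError("lambda_g > 0 requires a gene graph")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(I0.mean(), _EPS) / p)
    U = rng.uniform(size=(p, n)) * scale
    V = rng.uniform(size=(p, m)) * scale

    use_c = lambda_c > 0 and graphs_c is not None
    use_g = lambda_g > 0 and graphs_g is not None
    dc = graphs_c.degrees if use_c else None
    dg = graphs_g.degrees if use_g else None

    trace = []
    terms = []
    recon, tikh, graph = _objective(I0, U, V, beta, lambda_c, lambda_g, graphs_c, graphs_g)
    prev = recon + tikh + graph
    trace.append(prev)
    terms.append((recon, tikh, graph))

    for it in range(1, max_iter + 1):
        num_u = V @ I0.T
        den_u = (V @ V.T) @ U + beta * U
        if use_c:
            num_u = num_u + lambda_c * (U @ graphs_c.R_sparse)
            den_u = den_u + lambda_c * (U * dc[None, :])
        U = U * (num_u / (den_u + _EPS))

        num_v = U @ I0
        den_v = (U @ U.T) @ V + beta * V
        if use_g:
            num_v = num_v + lambda_g * (V @ graphs_g.R_sparse)
            den_v = den_v + lambda_g * (V * dg[None, :])
        V = V * (num_v / (den_v + _EPS))

        recon, tikh, graph = _objective(
            I0, U, V, beta, lambda_c, lambda_g, graphs_c, graphs_g
        )
        obj = recon + tikh + graph
        if not np.isfinite(obj):
            raise RuntimeError(f"non-finite objective at iteration {it}")
        trace.append(obj)
        terms.append((recon, tikh, graph))
        if prev > 0 and abs(prev - obj) / prev < tol:
            break
        prev = obj

    logger.info("factorization stopped after %d iterations (objective %.6g)",
                len(trace) - 1, trace[-1])
    return FactorPair(
        U=U, V=V, p=p, beta=beta, lambda_c=lambda_c, lambda_g=lambda_g,
        objective_trace=np.asarray(trace), trace_terms=np.asarray(terms),
    )


def reconstruct(fp: FactorPair) -> np.ndarray:
    """The reconstructed indicator ``I* = UᵀV`` (entrywise non-negative)."""
    return fp.U.T @ fp.V


def adaptive_tau(I0: np.ndarray, I_star: np.ndarray, factor: float = 0.5) -> float:
    """Data-driven dropout threshold.

    Half the mean reconstruction value at observed (I0 = 1) positions.
    With heavy dropout the reconstruction of an expressed block sits at
    the block's observed density rather than at 1, so a threshold scaled
    to the observed positions stays calibrated where a fixed 0.5 does not.
    """
    observed = I_star[np.asarray(I0) == 1]
    if observed.size == 0:
        return 0.0
    return float(factor * observed.mean())


def call_dropouts(I0: np.ndarray, I_star: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Imputation index: 1 where I0 = 0 and the reconstruction exceeds τ.

    Observed entries are never flagged, so ``I1 ⊙ I0 = 0`` by
    construction.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    I0 = np.asarray(I0)
    I_star = np.asarray(I_star)
    if I0.shape != I_star.shape:
        raise ValueError("I0 and I_star must be conformable")
    return ((I0 == 0) & (I_star > tau)).astype(float)
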
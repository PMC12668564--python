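"""Three-stage grid search over the discriminator hyperparameters.

Stage I searches (β, λ) jointly with λc = λg = λ; Stage II, with the
winning (β, λ) fixed, searches the neighborhood size k; Stage III fixes
the latent dimension p.  Each grid point runs the discriminator and
imputer and scores the imputed matrix by the mean k-means ARI over
seeded restarts, with the silhouette coefficient breaking ties.  Later
stages never revisit earlier selections, and the full score table is
returned for inspection.

The printed search ranges (β, λ from 1e-4 to 0.1 in steps of 5e-4;
k from ⌈log2 n⌉ to n in steps of 2; p from 10 to 100 in steps of 5)
are available via ``full_grids``; the default coarse grids subsample
them logarithmically so a desk-scale search stays tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .discriminator import (
    adaptive_tau,
    build_indicator,
    call_dropouts,
    factorize,
    knn_sparsify,
    pearson_similarity,
    reconstruct,
)
from .imputer import impute_all
from .pipeline import evaluate_clustering

logger = logging.getLogger(__name__)

__all__ = ["SearchSpec", "coarse_grids", "full_grids", "grid_search"]


def full_grids(n_cells: int) -> dict:
    """The complete printed search ranges."""
    return {
        "beta_grid": list(np.arange(0.0001, 0.1 + 1e-12, 0.0005)),
        "lambda_grid": list(np.arange(0.0001, 0.1 + 1e-12, 0.0005)),
        "k_grid": list(range(int(np.ceil(np.log2(n_cells))), n_cells, 2)),
        "p_grid": list(range(10, 101, 5)),
    }


def coarse_grids(n_cells: int) -> dict:
    """Logarithmic subsample of the full ranges (default)."""
    lo = int(np.ceil(np.log2(max(n_cells, 2))))
    hi = max(lo + 1, n_cells - 1)
    ks = sorted({lo, min(2 * lo, hi), min(4 * lo, hi)})
    return {
        "beta_grid": [0.0001, 0.001, 0.01, 0.1],
        "lambda_grid": [0.0001, 0.001, 0.01, 0.1],
        "k_grid": ks,
        "p_grid": [10, 20, 50, 100],
    }


@dataclass
class SearchSpec:
    """Grids and evaluation protocol for the staged search."""

    beta_grid: list = field(default_factory=list)
    lambda_grid: list = field(default_factory=list)
    k_grid: list = field(default_factory=list)
    p_grid: list = field(default_factory=list)
    n_restarts: int = 3
    seed: int = 0

    @classmethod
    def coarse(cls, n_cells: int, **kw) -> "SearchSpec":
        return cls(**coarse_grids(n_cells), **kw)

    @classmethod
    def full(cls, n_cells: int, **kw) -> "SearchSpec":
        return cls(**full_grids(n_cells), **kw)

    def __post_init__(self) -> None:
        for name in ("beta_grid", "lambda_grid", "k_grid", "p_grid"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


def _evaluate_point(sc_t, bulk_t, labels, beta, lam, k, p, spec) -> tuple[float, float, float]:
    """Mean ARI ± SD and mean SC of the discriminate→impute→cluster pipeline."""
    I0 = build_indicator(sc_t)
    k_c = min(k, sc_t.n_cells - 1)
    k_g = min(k, sc_t.n_genes - 1)
    graphs_c = knn_sparsify(pearson_similarity(sc_t.values, "rows"), k_c)
    graphs_g = knn_sparsify(pearson_similarity(bulk_t.values, "columns"), k_g)
    aris, scs = [], []
    for r in range(spec.n_restarts):
        fp = factorize(I0, graphs_c, graphs_g, p=p, beta=beta,
                       lambda_c=lam, lambda_g=lam, seed=spec.seed + r)
        I_star = reconstruct(fp)
        I1 = call_dropouts(I0, I_star, adaptive_tau(I0, I_star))
        imp = impute_all(sc_t, I1, k=k_c)
        ev = evaluate_clustering(imp.Y_imputed, labels, seed=spec.seed + r, n_runs=1)
        aris.append(ev["ari_mean"])
        scs.append(ev["silhouette"])
    return float(np.mean(aris)), float(np.std(aris)), float(np.mean(scs))


def grid_search(
    sc_t: ExpressionMatrix,
    bulk_t: ExpressionMatrix,
    labels,
    spec: SearchSpec,
) -> tuple[dict, pd.DataFrame]:
    """Staged search; returns the best parameters and the full score table.

    ``sc_t`` / ``bulk_t`` are the already-transformed matrices.  A grid
    point whose evaluation fails is logged and scored −∞.
    """
    labels = np.asarray(labels)
    rows = []
    # defaults while a stage's own parameter is still being searched
    k0 = spec.k_grid[len(spec.k_grid) // 2]
    p0 = spec.p_grid[0]

    def score(beta, lam, k, p, stage):
        try:
            ari_m, ari_s, sc_m = _evaluate_point(
                sc_t, bulk_t, labels, beta, lam, k, p, spec
            )
        except Exception as err:  # point-level failure must not kill the search
            logger.warning("grid point (β=%g, λ=%g, k=%d, p=%d) failed: %s",
                           beta, lam, k, p, err)
            ari_m, ari_s, sc_m = -np.inf, np.nan, -np.inf
        rows.append({"stage": stage, "beta": beta, "lambda": lam, "k": k, "p": p,
                     "ari_mean": ari_m, "ari_sd": ari_s, "sc_mean": sc_m})
        return ari_m, sc_m

    # Stage I: (β, λ) jointly, ARI primary, SC tiebreak, earlier point wins ties
    best_bl, best_key = None, (-np.inf, -np.inf)
    for beta in spec.beta_grid:
        for lam in spec.lambda_grid:
            key = score(beta, lam, k0, p0, "I")
            if key > best_key:
                best_key, best_bl = key, (beta, lam)
    beta, lam = best_bl

    # Stage II: k
    best_k, best_key = None, (-np.inf, -np.inf)
    for k in spec.k_grid:
        key = score(beta, lam, k, p0, "II")
        if key > best_key:
            best_key, best_k = key, k

    # Stage III: p
    best_p, best_key = None, (-np.inf, -np.inf)
    for p in spec.p_grid:
        key = score(beta, lam, best_k, p, "III")
        if key > best_key:
            best_key, best_p = key, p

    best = {"beta": beta, "lambda": lam, "k": best_k, "p": best_p}
    logger.info("grid search selected %s", best)
    return best, pd.DataFrame(rows)
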
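"""Quality control, candidate transformations and transformation selection.

The preprocessing stage (i) filters low-quality cells and rarely
detected genes, (ii) keeps the top highly-variable genes, (iii) aligns
the single-cell gene space with a bulk reference (or a pseudo-bulk
built from the single-cell data itself), and (iv) picks, from a
seven-member candidate library, the transformation whose output
maximizes the silhouette coefficient of the labeled cells:

    To* = argmax_{To ∈ Γ} SC(To(X_QC))

The same winning transformation is then applied to the bulk matrix,
re-estimating any per-gene parameters (rank pools, Box-Cox λ) on the
bulk data itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .metrics import silhouette

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "TransformSpec",
    "TRANSFORM_METHODS",
    "filter_cells",
    "filter_genes",
    "select_hvgs",
    "intersect_with_bulk",
    "make_pseudobulk",
    "apply_transform",
    "select_transformation",
    "default_candidates",
    "cluster_labels",
]

#: the candidate transformation library Γ
TRANSFORM_METHODS = (
    "value-to-rank",
    "unit-vector",
    "log-normalization",
    "log2",
    "log10",
    "loge",
    "box-cox",
)


@dataclass
class QCParams:
    """Cell- and gene-level quality-control thresholds.

    Defaults follow common practice for droplet scRNA-seq: at least 200
    detected genes per cell, a dataset-specific upper feature bound, a
    mitochondrial-fraction cap, genes detected in at least 3 cells, and
    the top 2000 highly variable genes.
    """

    min_genes_per_cell: int = 200
    max_features_per_cell: int = 10000
    max_mito_pct: float | None = 5.0
    min_cells_per_gene: int = 3
    n_hvgs: int = 2000

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.max_features_per_cell <= 0:
            raise ValueError("cell QC thresholds must be strictly positive")
        if self.min_genes_per_cell > self.max_features_per_cell:
            raise ValueError("min_genes_per_cell must not exceed max_features_per_cell")
        if self.min_cells_per_gene <= 0 or self.n_hvgs <= 0:
            raise ValueError("gene QC thresholds must be strictly positive")
        if self.max_mito_pct is not None and self.max_mito_pct <= 0:
            raise ValueError("max_mito_pct must be strictly positive or None")


@dataclass
class TransformSpec:
    """One candidate transformation: a method name plus fitted scalars."""

    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in TRANSFORM_METHODS:
            raise ValueError(
                f"unknown transformation {self.method!r}; "
                f"choose one of {TRANSFORM_METHODS}"
            )


def default_candidates() -> list[TransformSpec]:
    """The full seven-member candidate library, in canonical order."""
    return [TransformSpec(m) for m in TRANSFORM_METHODS]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_cells(X: ExpressionMatrix, qc: QCParams) -> ExpressionMatrix:
    """Retain cells passing detected-gene and mitochondrial thresholds.

    A cell is kept when its detected-gene count lies in
    ``[min_genes_per_cell, max_features_per_cell]`` and (when a
    mitochondrial cap is set) its ``mito_pct`` does not exceed
    ``max_mito_pct``.  Cell order is preserved.
    """
    detected = (X.values > 0).sum(axis=1)
    keep = (detected >= qc.min_genes_per_cell) & (detected <= qc.max_features_per_cell)
    n_gene_fail = int((~keep).sum())
    n_mito_fail = 0
    if qc.max_mito_pct is not None:
        if X.mito_pct is None:
            raise ValueError(
                "max_mito_pct is set but the matrix carries no mito_pct annotation"
            )
        mito_ok = X.mito_pct <= qc.max_mito_pct
        n_mito_fail = int((keep & ~mito_ok).sum())
        keep &= mito_ok
    if not keep.any():
        raise ValueError("no cells survive QC")
    logger.info(
        "cell QC: kept %d/%d cells (%d failed gene-count bounds, %d failed mito cap)",
        int(keep.sum()), X.n_cells, n_gene_fail, n_mito_fail,
    )
    return X.subset_cells(np.flatnonzero(keep))


def filter_genes(X: ExpressionMatrix, qc: QCParams) -> ExpressionMatrix:
    """Drop genes detected (value > 0) in fewer than ``min_cells_per_gene`` cells."""
    detected_in = (X.values > 0).sum(axis=0)
    keep = detected_in >= qc.min_cells_per_gene
    if not keep.any():
        raise ValueError("no genes survive QC")
    logger.info("gene QC: kept %d/%d genes", int(keep.sum()), X.n_genes)
    return X.subset_genes(np.flatnonzero(keep))


def _hvg_scores(counts: np.ndarray) -> np.ndarray:
    """Standardized variance under a mean–variance trend (vst-style).

    Fits log10(variance) against log10(mean) with lowess, standardizes
    each gene by the trend-predicted standard deviation, clips the
    standardized values at sqrt(n_cells), and scores each gene by the
    variance of the clipped values.  Non-finite scores rank last.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    scores = np.full(counts.shape[1], -np.inf)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() < 2:
        warnings.warn("too few variable genes for a trend fit; ranking by raw variance")
        return np.where(np.isfinite(var), var, -np.inf)
    lx = np.log10(mean[fit_mask])
    ly = np.log10(var[fit_mask])
    fitted = lowess(ly, lx, frac=0.3, return_sorted=False)
    expected_sd = np.sqrt(10.0**fitted)
    clip = np.sqrt(n)
    sub = counts[:, fit_mask]
    z = (sub - mean[fit_mask]) / expected_sd
    z = np.clip(z, -clip, clip)
    scores[fit_mask] = z.var(axis=0, ddof=1)
    if not np.all(np.isfinite(scores[fit_mask])):
        warnings.warn("non-finite HVG scores; affected genes ranked last")
        scores[~np.isfinite(scores)] = -np.inf
    return scores


def select_hvgs(X: ExpressionMatrix, n_hvgs: int) -> ExpressionMatrix:
    """Keep the ``n_hvgs`` genes with highest standardized variance.

    Ties (and the output ordering) follow the input gene order, which
    makes selection deterministic.
    """
    if X.n_genes <= n_hvgs:
        logger.info(
            "requested %d HVGs but only %d genes present; keeping all",
            n_hvgs, X.n_genes,
        )
        return X
    scores = _hvg_scores(X.values)
    # stable sort on negated score: ties broken by input gene order
    top = np.sort(np.argsort(-scores, kind="stable")[:n_hvgs])
    return X.subset_genes(top)


def intersect_with_bulk(
    sc: ExpressionMatrix, bulk: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in single-cell order."""
    bulk_index = {g: i for i, g in enumerate(bulk.gene_ids)}
    sc_keep = [i for i, g in enumerate(sc.gene_ids) if g in bulk_index]
    if not sc_keep:
        raise ValueError(
            f"no shared genes between single-cell ({len(sc.gene_ids)} genes) "
            f"and bulk ({len(bulk.gene_ids)} genes) namespaces"
        )
    bulk_keep = [bulk_index[sc.gene_ids[i]] for i in sc_keep]
    logger.info("gene intersection: %d shared genes", len(sc_keep))
    return sc.subset_genes(np.asarray(sc_keep)), bulk.subset_genes(np.asarray(bulk_keep))


def make_pseudobulk(sc: ExpressionMatrix, mode: str = "mean") -> ExpressionMatrix:
    """Aggregate cells into a pseudo-bulk reference.

    With per-cell labels present, one pseudo-sample per label is built;
    otherwise a single row.  ``mode`` is ``"mean"`` (bulk-mean) or
    ``"sum"`` (bulk-sum).
    """
    if mode not in ("mean", "sum"):
        raise ValueError("pseudobulk mode must be 'mean' or 'sum'")
    if sc.n_cells == 0:
        raise ValueError("cannot build a pseudo-bulk from an empty matrix")
    agg = np.mean if mode == "mean" else np.sum
    if sc.labels is not None:
        groups = list(dict.fromkeys(sc.labels.tolist()))  # first-appearance order
        rows = [agg(sc.values[sc.labels == g], axis=0) for g in groups]
        ids = [f"pseudobulk_{mode}_{g}" for g in groups]
    else:
        rows = [agg(sc.values, axis=0)]
        ids = [f"pseudobulk_{mode}"]
    return ExpressionMatrix(np.vstack(rows), ids, list(sc.gene_ids))


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def _transform_values(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    method = spec.method
    X = values
    if method == "value-to-rank":
        # per-gene average ranks across cells; zeros stay zero so the
        # sparsity pattern (and hence the indicator matrix) is preserved
        out = stats.rankdata(X, method="average", axis=0).astype(float)
        out[X == 0] = 0.0
        return out
    if method == "unit-vector":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return X / norms
    if method == "log-normalization":
        target = float(spec.params.get("target_sum", 1e4))
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return np.log1p(X / totals * target)
    if method in ("log2", "log10", "loge"):
        base = {"log2": np.log(2.0), "log10": np.log(10.0), "loge": 1.0}[method]
        return np.log1p(X) / base
    if method == "box-cox":
        out = np.empty_like(X, dtype=float)
        lambdas = np.full(X.shape[1], np.nan)
        n_const = 0
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0:
                out[:, j] = col  # constant gene: identity
                n_const += 1
                continue
            transformed, lam = stats.boxcox(col + 1.0)
            out[:, j] = transformed
            lambdas[j] = lam
        if n_const:
            warnings.warn(f"box-cox: {n_const} constant genes passed through unchanged")
        spec.params["lambdas"] = lambdas
        return out
    raise AssertionError(f"unhandled method {method}")


def apply_transform(X: ExpressionMatrix, spec: TransformSpec) -> ExpressionMatrix:
    """Apply one candidate transformation; output is always finite.

    Per-gene parameters (rank pools, Box-Cox λ) are estimated on the
    matrix being transformed, so bulk matrices re-fit their own
    parameters when given the single-cell winner.
    """
    out = _transform_values(X.values, spec)
    if not np.all(np.isfinite(out)):
        raise RuntimeError(f"transformation {spec.method!r} produced non-finite values")
    return X.with_values(out)


def cluster_labels(
    values: np.ndarray, n_clusters: int, seed: int = 0, n_pcs: int = 50
) -> np.ndarray:
    """Deterministic fallback labels: k-means on the top principal components."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, min(values.shape) - 1)
    if n_pcs >= 1:
        coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(values)
    else:
        coords = values
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(coords)


def select_transformation(
    X: ExpressionMatrix,
    candidates: list[TransformSpec] | None = None,
    labels=None,
) -> tuple[TransformSpec, pd.DataFrame]:
    """Choose the transformation maximizing the silhouette coefficient.

    Each candidate is applied to ``X`` and scored by the silhouette of
    the supplied per-cell labels on the transformed matrix; the argmax
    candidate wins, with ties broken by candidate order.  A candidate on
    which the silhouette is undefined (a single label) scores −1.
    Returns the winner and the full score table.
    """
    if candidates is None:
        candidates = default_candidates()
    if not candidates:
        raise ValueError("at least one candidate transformation is required")
    if labels is None:
        labels = X.labels
    if labels is None:
        raise ValueError(
            "transformation selection needs per-cell labels "
            "(annotations or a clustering; see cluster_labels)"
        )
    labels = np.asarray(labels)
    rows = []
    best_idx, best_sc = 0, -np.inf
    for i, spec in enumerate(candidates):
        transformed = apply_transform(X, spec)
        try:
            sc = silhouette(transformed.values, labels)
        except ValueError:
            warnings.warn(
                f"silhouette undefined for candidate {spec.method!r}; scored as -1"
            )
            sc = -1.0
        rows.append({"method": spec.method, "silhouette": sc})
        if sc > best_sc:
            best_idx, best_sc = i, sc
    table = pd.DataFrame(rows)
    logger.info("selected transformation %r (SC=%.4f)", candidates[best_idx].method, best_sc)
    return candidates[best_idx], table
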
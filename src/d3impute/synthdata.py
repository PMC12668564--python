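"""Splat-style synthetic counts and seeded dropout masking.

The generator emulates the structure of the masking benchmark: a
cell×gene count matrix with a small number of cell types, generated as

* gene base means drawn from a heavy-tailed Gamma distribution,
* per-group multiplicative differential-expression factors (lognormal
  log-fold-changes with random direction) on a ``de_prob`` fraction of
  genes,
* a lognormal per-cell library-size factor,
* negative-binomial sampling with a common dispersion.

Defaults are fixed to the benchmark scenario: 500 cells × 2000 genes in
three groups with a baseline zero rate of roughly 25–27%.  Masking then
zeroes a stated fraction of the non-zero entries uniformly at random
(seeded), recording the masked positions so imputation accuracy can be
scored against withheld ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix
from . import metrics

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "MaskedSimulation",
    "simulate_counts",
    "apply_dropout_mask",
    "subset_simulation",
    "score_masking_run",
]


@dataclass
class SimParams:
    """Parameters of the group-structured count simulator.

    ``base_mean`` and ``mean_shape`` set the Gamma distribution of gene
    base means (mean ``base_mean``, shape ``mean_shape``); ``dispersion``
    is the NB overdispersion φ (variance μ + φμ²); ``de_prob`` is the
    per-group fraction of differential genes and ``de_facLoc`` /
    ``de_facScale`` the location/scale of their lognormal fold changes;
    ``lib_sigma`` is the sdlog of the per-cell library factor.
    """

    n_cells: int = 500
    n_genes: int = 2000
    n_groups: int = 3
    de_prob: float = 0.1
    de_facLoc: float = 1.0
    de_facScale: float = 0.4
    base_mean: float = 7.0
    mean_shape: float = 0.6
    dispersion: float = 0.3
    lib_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0 <= self.de_prob <= 1:
            raise ValueError("de_prob must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if min(self.n_cells, self.n_genes) < 1:
            raise ValueError("matrix dimensions must be positive")


@dataclass
class MaskedSimulation:
    """Ground truth, its masked copy, and the masked positions."""

    truth: ExpressionMatrix
    masked: ExpressionMatrix
    mask_positions: np.ndarray  # (n_masked, 2) 0-based (cell, gene) indices
    group_labels: np.ndarray
    requested_rate: float
    realized_zero_rate: float


def simulate_counts(sp: SimParams) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw a group-structured NB count matrix; reproducible given the seed."""
    rng = np.random.default_rng(sp.seed)
    mu = rng.gamma(sp.mean_shape, sp.base_mean / sp.mean_shape, size=sp.n_genes)
    # balanced group assignment, then shuffled, so every group is populated
    groups = np.repeat(np.arange(sp.n_groups), int(np.ceil(sp.n_cells / sp.n_groups)))
    groups = groups[: sp.n_cells]
    rng.shuffle(groups)

    factors = np.ones((sp.n_groups, sp.n_genes))
    if sp.de_prob > 0 and sp.n_groups > 1:
        for g in range(sp.n_groups):
            de = rng.random(sp.n_genes) < sp.de_prob
            lfc = rng.normal(sp.de_facLoc, sp.de_facScale, size=int(de.sum()))
            down = rng.random(int(de.sum())) < 0.5
            factors[g, de] = np.exp(np.where(down, -lfc, lfc))

    lib = np.exp(rng.normal(0.0, sp.lib_sigma, size=sp.n_cells))
    mean = lib[:, None] * factors[groups] * mu[None, :]
    r = 1.0 / sp.dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
    if not counts.any():
        raise ValueError("simulation produced an all-zero matrix; raise base_mean")
    zero_rate = float((counts == 0).mean())
    logger.info("simulated %dx%d counts, baseline zero rate %.2f%%",
                sp.n_cells, sp.n_genes, 100 * zero_rate)
    cells = [f"cell{i}" for i in range(sp.n_cells)]
    genes = [f"gene{j}" for j in range(sp.n_genes)]
    X = ExpressionMatrix(counts, cells, genes, labels=groups.astype(str))
    return X, groups


def apply_dropout_mask(X: ExpressionMatrix, rate: float, seed: int = 0,
                       mean_dependent: bool = False) -> MaskedSimulation:
    """Zero out ``floor(rate·nnz)`` non-zero entries, sampled without replacement.

    By default positions are sampled uniformly over the non-zero entries.
    With ``mean_dependent=True`` sampling weights follow a logistic decay
    in the gene's log mean expression (low-expression genes drop more),
    mimicking expression-dependent capture failure.
    """
    if not 0 < rate < 1:
        raise ValueError("masking rate must lie strictly between 0 and 1")
    values = X.values
    nz_cells, nz_genes = np.nonzero(values)
    nnz = nz_cells.size
    if nnz == 0:
        raise ValueError("matrix has no non-zero entries to mask")
    n_mask = int(np.floor(rate * nnz))
    rng = np.random.default_rng(seed)
    if n_mask == 0:
        chosen = np.empty(0, dtype=int)
    elif mean_dependent:
        gene_mean = values.mean(axis=0)
        logmu = np.log1p(gene_mean[nz_genes])
        w = 1.0 / (1.0 + np.exp(logmu - np.median(logmu)))
        w = w / w.sum()
        chosen = rng.choice(nnz, size=n_mask, replace=False, p=w)
    else:
        chosen = rng.choice(nnz, size=n_mask, replace=False)
    masked_values = values.copy()
    masked_values[nz_cells[chosen], nz_genes[chosen]] = 0.0
    positions = np.column_stack([nz_cells[chosen], nz_genes[chosen]])
    realized = float((masked_values == 0).mean())
    logger.info("masked %d/%d non-zeros (rate %.2f); overall zero rate now %.2f%%",
                n_mask, nnz, rate, 100 * realized)
    labels = X.labels if X.labels is not None else np.zeros(X.n_cells, dtype=int)
    return MaskedSimulation(
        truth=X,
        masked=X.with_values(masked_values),
        mask_positions=positions,
        group_labels=np.asarray(labels),
        requested_rate=rate,
        realized_zero_rate=realized,
    )


def subset_simulation(sim: MaskedSimulation, cell_ids, gene_ids) -> MaskedSimulation:
    """Restrict a simulation to the cells/genes a pipeline run retained.

    QC may drop cells or genes of the masked matrix; this remaps the
    simulation (truth, masked copy, mask positions, labels) onto the
    retained grid so imputation output can be scored against it.
    Masked positions on dropped rows/columns are removed.
    """
    cell_pos = {c: i for i, c in enumerate(sim.truth.cell_ids)}
    gene_pos = {g: j for j, g in enumerate(sim.truth.gene_ids)}
    ci = np.asarray([cell_pos[c] for c in cell_ids])
    gi = np.asarray([gene_pos[g] for g in gene_ids])
    cell_new = -np.ones(sim.truth.n_cells, dtype=int)
    cell_new[ci] = np.arange(ci.size)
    gene_new = -np.ones(sim.truth.n_genes, dtype=int)
    gene_new[gi] = np.arange(gi.size)
    pos = sim.mask_positions
    if pos.size:
        rows, cols = cell_new[pos[:, 0]], gene_new[pos[:, 1]]
        keep = (rows >= 0) & (cols >= 0)
        pos = np.column_stack([rows[keep], cols[keep]])
    truth = sim.truth.subset_cells(ci).subset_genes(gi)
    masked = sim.masked.subset_cells(ci).subset_genes(gi)
    return MaskedSimulation(
        truth=truth,
        masked=masked,
        mask_positions=pos,
        group_labels=sim.group_labels[ci],
        requested_rate=sim.requested_rate,
        realized_zero_rate=float((masked.values == 0).mean()),
    )


def score_masking_run(
    sim: MaskedSimulation,
    imputed: np.ndarray,
    I1: np.ndarray,
    truth_values: np.ndarray | None = None,
    I_star: np.ndarray | None = None,
    tau: float = 0.5,
) -> dict:
    """Score an imputation run against the withheld masked entries.

    ``imputed`` and ``I1`` must be on the same grid as the simulation
    (same cell/gene order); ``truth_values`` defaults to the raw truth
    counts but can be the transformed truth when the pipeline imputes on
    a transformed scale.

    Returns masked-position PCC and RMSE, the zero-baseline PCC (defined
    as 0: an all-zero prediction carries no linear association), the
    recall of masked positions within I1, the false-flag rate on true
    zeros, and the four-way zero-type counts (I00/I01/I10/I11) comparing
    the observation indicator with the dropout calls.
    """
    imputed = np.asarray(imputed, dtype=float)
    I1 = np.asarray(I1)
    truth = np.asarray(
        sim.truth.values if truth_values is None else truth_values, dtype=float
    )
    if imputed.shape != truth.shape or I1.shape != truth.shape:
        raise ValueError("imputed, I1 and truth must share one shape")
    rows, cols = sim.mask_positions.T if sim.mask_positions.size else (
        np.empty(0, int), np.empty(0, int))
    t = truth[rows, cols]
    y = imputed[rows, cols]
    out: dict = {}
    out["n_masked"] = int(rows.size)
    out["pcc_masked"] = metrics.pcc(y, t) if rows.size >= 2 and np.ptp(y) > 0 else 0.0
    out["rmse_masked"] = metrics.rmse(y, t) if rows.size else 0.0
    out["pcc_zero_baseline"] = 0.0  # all-zero prediction: no association
    out["rmse_zero_baseline"] = metrics.rmse(np.zeros_like(t), t) if rows.size else 0.0

    flagged = I1 != 0
    mask_ind = np.zeros(truth.shape, dtype=bool)
    mask_ind[rows, cols] = True
    true_zero = (truth == 0) & (sim.masked.values == 0) & ~mask_ind
    out["dropout_recall"] = (
        float(flagged[mask_ind].mean()) if mask_ind.any() else 0.0
    )
    out["false_flag_rate"] = (
        float(flagged[true_zero].mean()) if true_zero.any() else 0.0
    )

    # four-way zero-type counts: observed indicator vs predicted presence.
    # With a reconstruction I* available, observed entries split into
    # correctly retained (I* > tau) and false negatives; without one,
    # every observed entry counts as retained (the imputer never
    # re-zeroes an observed value).
    I0 = sim.masked.values != 0
    if I_star is not None:
        present = np.asarray(I_star) > tau
        out["I11"] = int((I0 & present).sum())
        out["I10"] = int((I0 & ~present).sum())
    else:
        out["I11"] = int(I0.sum())
        out["I10"] = 0
    out["I01"] = int((~I0 & flagged).sum())
    out["I00"] = int((~I0 & ~flagged).sum())
    assert out["I00"] + out["I01"] + out["I10"] + out["I11"] == truth.size
    return out
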
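"""Evaluation measures for imputation and downstream-analysis benchmarking.

All metrics are implemented directly from their defining formulas:

* ``skewness`` — adjusted Fisher–Pearson sample skewness, used to choose
  data transformations.
* ``silhouette`` — mean per-sample silhouette with Euclidean distance.
* ``nmi`` / ``ari`` — clustering agreement against annotated labels; the
  ARI uses the pair-confusion form ``2(ad−bc)/((a+b)(b+d)+(a+c)(c+d))``.
* ``pos`` / ``kendall`` — concordance of a pseudotemporal ordering with
  ordinal stage labels.
* ``roc_auc`` — ranked-threshold ROC sweep with trapezoidal AUC.
* ``pcc`` / ``rmse`` — accuracy of imputed values at masked positions.

Library equivalents (sklearn, scipy) exist for several of these; this
module keeps its own arithmetic so every number the package reports is
traceable to the definitions above, and the library versions serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "skewness",
    "silhouette",
    "nmi",
    "ari",
    "pos",
    "kendall",
    "roc_auc",
    "pcc",
    "rmse",
]


def skewness(values) -> float:
    """Adjusted sample skewness ``n/((n-1)(n-2)) · Σ((x-x̄)/s)³``.

    ``s`` is the n−1 sample standard deviation.  Positive values indicate
    a right-skewed distribution.  Raises for ``n < 3`` or a constant
    sample (undefined).
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("skewness requires at least 3 observations")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("skewness undefined for a constant sample")
    z = (x - x.mean()) / s
    return float(n / ((n - 1) * (n - 2)) * np.sum(z**3))


def silhouette(X_data: np.ndarray, labels) -> float:
    """Mean silhouette coefficient with Euclidean distance.

    Per sample, ``s = (B − A) / max(A, B)`` where ``A`` is the mean
    distance to other members of its own cluster and ``B`` the smallest
    mean distance to another cluster.  Samples in singleton clusters
    score 0, as do samples with ``A = B = 0``.
    """
    X_data = np.asarray(X_data, dtype=float)
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X_data, X_data)
    n = X_data.shape[0]
    K = uniq.size
    # mean distance from each sample to each cluster
    sums = np.zeros((n, K))
    counts = np.bincount(inv, minlength=K)
    for k in range(K):
        sums[:, k] = D[:, inv == k].sum(axis=1)
    s_vals = np.zeros(n)
    for i in range(n):
        k = inv[i]
        if counts[k] == 1:
            s_vals[i] = 0.0
            continue
        a = sums[i, k] / (counts[k] - 1)
        other = [sums[i, j] / counts[j] for j in range(K) if j != k]
        b = min(other)
        denom = max(a, b)
        s_vals[i] = 0.0 if denom == 0 else (b - a) / denom
    sc = float(s_vals.mean())
    assert -1.0 <= sc <= 1.0
    return sc


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def nmi(truth, pred) -> float:
    """Normalized mutual information ``2·I(X,Y)/(H(X)+H(Y))`` in nats.

    Returns 1 when both labelings are constant (all information — none —
    is shared degenerately).
    """
    x = np.asarray(truth)
    y = np.asarray(pred)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    n = x.size
    table = _contingency(x, y)
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx + hy == 0:
        return 1.0
    nz = pxy > 0
    mi = np.sum(pxy[nz] * (np.log(pxy[nz]) - np.log(np.outer(px, py)[nz])))
    val = float(2.0 * mi / (hx + hy))
    # clip tiny negative rounding noise
    val = min(max(val, 0.0), 1.0)
    return val


def ari(truth, pred) -> float:
    """Adjusted Rand index via pair-confusion counts.

    Over all n(n−1)/2 item pairs let ``a`` be same-class/same-cluster
    pairs, ``b`` different-class/same-cluster, ``c`` same-class/
    different-cluster and ``d`` different/different; the index is
    ``2(ad − bc) / ((a+b)(b+d) + (a+c)(c+d))``.  When every pair agrees
    (b = c = 0) the degenerate ratio is defined as 1.
    """
    x = np.asarray(truth)
    y = np.asarray(pred)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    if x.size < 2:
        raise ValueError("ARI requires at least 2 items")
    table = _contingency(x, y)

    def comb2(v):
        return v * (v - 1) // 2

    total = comb2(x.size)
    a = int(comb2(table).sum())
    same_x = int(comb2(table.sum(axis=1)).sum())  # a + c
    same_y = int(comb2(table.sum(axis=0)).sum())  # a + b
    b = same_y - a
    c = same_x - a
    d = total - a - b - c
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0
    val = float(2.0 * (a * d - b * c) / denom)
    assert -1.0 <= val <= 1.0 + 1e-12
    return val


def pos(pseudo_order, stage_labels) -> float:
    """Pseudotemporal ordering score in ``[-1, 1]``.

    ``pseudo_order`` gives each cell's position along the inferred path;
    ``stage_labels`` are ordinal external labels.  Every stage-comparable
    pair scores +1 when the path order agrees with the stage order and
    −1 when it opposes it; the sum is normalized by the number of
    comparable pairs so the score spans the stated range.
    """
    order = np.asarray(pseudo_order, dtype=float)
    stage = np.asarray(stage_labels, dtype=float)
    if order.shape != stage.shape:
        raise ValueError("ordering and stage labels must have equal length")
    ds = np.sign(stage[:, None] - stage[None, :])
    if not np.any(ds):
        raise ValueError("POS undefined when all stages are identical")
    do = np.sign(order[:, None] - order[None, :])
    iu = np.triu_indices(order.size, k=1)
    g = (ds * do)[iu]
    comparable = ds[iu] != 0
    val = float(g[comparable].sum() / comparable.sum())
    assert -1.0 <= val <= 1.0
    return val


def kendall(pseudo_order, stage_labels) -> float:
    """Kendall tau-a: ``2(J − W)/(n(n−1))`` over concordant/discordant pairs.

    Pairs tied in either variable count in neither J nor W.
    """
    order = np.asarray(pseudo_order, dtype=float)
    stage = np.asarray(stage_labels, dtype=float)
    n = order.size
    if n < 2:
        raise ValueError("Kendall requires at least 2 items")
    if order.shape != stage.shape:
        raise ValueError("ordering and stage labels must have equal length")
    do = np.sign(order[:, None] - order[None, :])
    ds = np.sign(stage[:, None] - stage[None, :])
    iu = np.triu_indices(n, k=1)
    prod = (do * ds)[iu]
    j = int((prod > 0).sum())
    w = int((prod < 0).sum())
    val = float(2.0 * (j - w) / (n * (n - 1)))
    assert -1.0 <= val <= 1.0
    return val


def roc_auc(scores, reference_set) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC from per-gene scores.

    ``reference_set`` is a boolean membership vector (the positive
    class).  Thresholds sweep the distinct score values from high to
    low; tied scores enter simultaneously.  Returns ``(curve, auc)``
    where ``curve`` is an array of ``(fpr, tpr)`` rows including the
    (0,0) and (1,1) endpoints.
    """
    s = np.asarray(scores, dtype=float)
    member = np.asarray(reference_set, dtype=bool)
    if s.shape != member.shape:
        raise ValueError("scores and reference membership must align")
    n_pos = int(member.sum())
    n_neg = member.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("reference set must be non-empty and proper")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    m_sorted = member[order]
    tps = np.cumsum(m_sorted)
    fps = np.cumsum(~m_sorted)
    # keep only the last index of each tied block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    assert 0.0 <= auc <= 1.0
    return np.column_stack([fpr, tpr]), auc


def pcc(a, b) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("pcc requires two equal-length vectors of size >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("pcc undefined for a zero-variance vector")
    val = float(np.sum(xc * yc) / denom)
    val = min(max(val, -1.0), 1.0)
    return val


def rmse(a, b) -> float:
    """Root mean squared difference of two equal-length vectors."""
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("rmse requires two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))
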
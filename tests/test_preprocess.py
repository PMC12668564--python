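"""QC filters, candidate transformations and silhouette-driven selection."""

import numpy as np
import pytest

from d3impute import metrics
from d3impute.containers import ExpressionMatrix
from d3impute.preprocess import (
    QCParams,
    TransformSpec,
    apply_transform,
    default_candidates,
    filter_cells,
    filter_genes,
    intersect_with_bulk,
    make_pseudobulk,
    select_hvgs,
    select_transformation,
)


def _em(values, labels=None, mito=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        labels=labels,
        mito_pct=mito,
    )


class TestCellFilter:
    def test_detected_gene_bounds(self, rng):
        # three cells detecting 150 / 500 / 9000 genes, bounds [200, 8000]
        values = np.zeros((3, 10000))
        values[0, :150] = 1
        values[1, :500] = 1
        values[2, :9000] = 1
        qc = QCParams(min_genes_per_cell=200, max_features_per_cell=8000,
                      max_mito_pct=None)
        out = filter_cells(_em(values), qc)
        assert out.cell_ids == ["c1"]

    def test_wide_bounds_are_identity(self, small_matrix):
        qc = QCParams(min_genes_per_cell=1, max_features_per_cell=10**6,
                      max_mito_pct=None)
        keep = (small_matrix.values > 0).sum(1) >= 1
        out = filter_cells(small_matrix, qc)
        assert out.n_cells == keep.sum()

    def test_matches_per_cell_predicate_oracle(self, rng):
        values = rng.poisson(0.8, size=(100, 300)).astype(float)
        mito = rng.uniform(0, 10, size=100)
        # detected genes/cell concentrate near 300*(1-exp(-0.8)) ~ 165,
        # so these bounds split the population rather than excluding it
        qc = QCParams(min_genes_per_cell=160, max_features_per_cell=172,
                      max_mito_pct=6.0)
        X = _em(values, mito=mito)
        out = filter_cells(X, qc)
        expected = [
            f"c{i}" for i in range(100)
            if 160 <= (values[i] > 0).sum() <= 172 and mito[i] <= 6.0
        ]
        assert out.cell_ids == expected

    def test_order_stability_under_permutation(self, rng):
        values = rng.poisson(0.8, size=(40, 200)).astype(float)
        X = _em(values)
        qc = QCParams(min_genes_per_cell=30, max_features_per_cell=150,
                      max_mito_pct=None)
        perm = rng.permutation(40)
        out_perm = filter_cells(X.subset_cells(perm), qc)
        out = filter_cells(X, qc)
        kept = set(out.cell_ids)
        assert out_perm.cell_ids == [X.cell_ids[i] for i in perm if X.cell_ids[i] in kept]

    def test_missing_mito_with_active_threshold(self, small_matrix):
        qc = QCParams(min_genes_per_cell=1, max_features_per_cell=100,
                      max_mito_pct=5.0)
        with pytest.raises(ValueError, match="mito"):
            filter_cells(small_matrix, qc)

    def test_all_cells_removed(self):
        values = np.ones((3, 300))
        qc = QCParams(min_genes_per_cell=301, max_features_per_cell=400,
                      max_mito_pct=None)
        with pytest.raises(ValueError, match="no cells survive"):
            filter_cells(_em(values), qc)


class TestGeneFilter:
    def test_strict_threshold(self):
        values = np.zeros((5, 3))
        values[:2, 0] = 1  # detected in 2 cells -> removed
        values[:3, 1] = 1  # exactly 3 -> retained
        values[:, 2] = 1
        out = filter_genes(_em(values), QCParams(max_mito_pct=None))
        assert out.gene_ids == ["g1", "g2"]

    def test_matches_column_sum_oracle(self, rng):
        values = (rng.random((50, 200)) < 0.04).astype(float)
        values[:, 0] = 1  # guarantee a survivor
        out = filter_genes(_em(values), QCParams(max_mito_pct=None))
        expected = [f"g{j}" for j in range(200) if (values[:, j] > 0).sum() >= 3]
        assert out.gene_ids == expected


class TestHVGs:
    def test_all_genes_returned_when_fewer_than_requested(self, small_matrix):
        out = select_hvgs(small_matrix, 100)
        assert out.gene_ids == small_matrix.gene_ids

    def test_inflated_dispersion_genes_recovered(self, rng):
        n, m = 300, 500
        mu = rng.gamma(2.0, 2.0, size=m)
        counts = rng.poisson(mu, size=(n, m)).astype(float)
        hot = rng.choice(m, size=20, replace=False)
        # 10x inflated dispersion via NB with small size parameter
        r = 0.1
        counts[:, hot] = rng.negative_binomial(
            r, r / (r + mu[hot]), size=(n, 20)
        ).astype(float)
        out = select_hvgs(_em(counts), 20)
        found = sum(1 for j in hot if f"g{j}" in out.gene_ids)
        assert found >= 18

    def test_constant_gene_never_outranks_variable_gene(self, rng):
        values = rng.poisson(3.0, size=(50, 5)).astype(float)
        values[:, 2] = 4.0  # constant gene
        out = select_hvgs(_em(values), 4)
        assert "g2" not in out.gene_ids


class TestBulkAlignment:
    def test_ordered_intersection(self):
        sc = ExpressionMatrix(np.ones((2, 3)), ["a", "b"], ["A", "B", "C"])
        bulk = ExpressionMatrix(np.ones((1, 3)), ["s"], ["B", "C", "D"])
        sc2, bulk2 = intersect_with_bulk(sc, bulk)
        assert sc2.gene_ids == ["B", "C"] == bulk2.gene_ids

    def test_bulk_superset_leaves_sc_unchanged(self):
        sc = ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["A", "B"])
        bulk = ExpressionMatrix(np.arange(8).reshape(2, 4).astype(float),
                                ["s", "t"], ["B", "A", "C", "D"])
        sc2, bulk2 = intersect_with_bulk(sc, bulk)
        assert sc2.gene_ids == sc.gene_ids
        assert bulk2.gene_ids == ["A", "B"]
        assert np.array_equal(bulk2.values, bulk.values[:, [1, 0]])

    def test_empty_intersection_fails(self):
        sc = ExpressionMatrix(np.ones((2, 1)), ["a", "b"], ["A"])
        bulk = ExpressionMatrix(np.ones((1, 1)), ["s"], ["Z"])
        with pytest.raises(ValueError, match="no shared genes"):
            intersect_with_bulk(sc, bulk)

    def test_random_namespaces_match_set_oracle(self, rng):
        sc_genes = [f"g{i}" for i in rng.choice(100, 40, replace=False)]
        bulk_genes = [f"g{i}" for i in rng.choice(100, 60, replace=False)]
        sc = ExpressionMatrix(np.ones((3, 40)), ["a", "b", "c"], sc_genes)
        bulk = ExpressionMatrix(np.ones((2, 60)), ["s", "t"], bulk_genes)
        sc2, _ = intersect_with_bulk(sc, bulk)
        assert sc2.gene_ids == [g for g in sc_genes if g in set(bulk_genes)]


class TestPseudobulk:
    def test_mean_and_sum(self):
        X = _em([[2.0, 0.0], [4.0, 2.0]])
        assert make_pseudobulk(X, "mean").values[0, 0] == 3.0
        assert make_pseudobulk(X, "sum").values[0, 0] == 6.0

    def test_per_label_groupby_oracle(self, rng):
        values = rng.poisson(2.0, size=(12, 5)).astype(float)
        labels = np.array(["x", "y"] * 6)
        X = _em(values, labels=labels)
        pb = make_pseudobulk(X, "mean")
        assert pb.n_cells == 2
        np.testing.assert_allclose(pb.values[0], values[labels == "x"].mean(0))
        np.testing.assert_allclose(pb.values[1], values[labels == "y"].mean(0))


class TestTransforms:
    def test_log10_values(self):
        X = _em([[0.0, 9.0], [99.0, 0.0]])
        out = apply_transform(X, TransformSpec("log10"))
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(1.0)
        assert out.values[1, 0] == pytest.approx(2.0)

    def test_unit_vector(self):
        X = _em([[3.0, 4.0]])
        out = apply_transform(X, TransformSpec("unit-vector"))
        np.testing.assert_allclose(out.values, [[0.6, 0.8]])

    def test_boxcox_reduces_skewness(self, rng):
        col = rng.lognormal(1.0, 1.0, size=300)
        X = _em(col[:, None])
        out = apply_transform(X, TransformSpec("box-cox"))
        assert abs(metrics.skewness(out.values[:, 0])) < abs(metrics.skewness(col))

    def test_boxcox_constant_gene_passthrough(self):
        X = _em(np.column_stack([np.full(5, 2.0), np.arange(5, dtype=float)]))
        with pytest.warns(UserWarning, match="constant genes"):
            out = apply_transform(X, TransformSpec("box-cox"))
        np.testing.assert_array_equal(out.values[:, 0], X.values[:, 0])

    @pytest.mark.parametrize("method", ["value-to-rank", "log2", "log10", "loge",
                                        "log-normalization", "box-cox"])
    def test_zero_maps_to_zero(self, rng, method):
        values = rng.poisson(1.0, size=(30, 8)).astype(float)
        values[3] = 0.0
        out = apply_transform(_em(values), TransformSpec(method))
        assert np.all(out.values[values == 0] == 0)
        assert np.all(np.isfinite(out.values))

    @pytest.mark.parametrize("method", ["log2", "log10", "loge"])
    def test_monotone_transforms_preserve_within_gene_order(self, rng, method):
        values = rng.gamma(2.0, 3.0, size=(25, 4))
        out = apply_transform(_em(values), TransformSpec(method))
        for j in range(4):
            assert np.array_equal(np.argsort(values[:, j], kind="stable"),
                                  np.argsort(out.values[:, j], kind="stable"))

    def test_determinism(self, small_matrix):
        a = apply_transform(small_matrix, TransformSpec("log-normalization"))
        b = apply_transform(small_matrix, TransformSpec("log-normalization"))
        assert np.array_equal(a.values, b.values)


class TestSelectTransformation:
    def test_single_candidate_returned(self, rng):
        values = rng.poisson(2.0, size=(20, 6)).astype(float)
        labels = np.r_[np.zeros(10), np.ones(10)]
        spec, table = select_transformation(_em(values), [TransformSpec("log2")], labels)
        assert spec.method == "log2"
        assert len(table) == 1

    def test_separated_clusters_win(self, rng):
        # two clusters whose separation survives a per-cell L2 normalization
        # (direction-coded) but is destroyed by per-gene ranking of the
        # heavily overlapping magnitudes
        a = np.abs(rng.normal(0, 0.05, size=(15, 2))) + [[10.0, 0.1]]
        b = np.abs(rng.normal(0, 0.05, size=(15, 2))) + [[0.1, 10.0]]
        scale = rng.lognormal(2.0, 1.0, size=30)[:, None]
        X = _em(np.vstack([a, b]) * scale)
        labels = np.r_[np.zeros(15), np.ones(15)]
        spec, table = select_transformation(
            X, [TransformSpec("unit-vector"), TransformSpec("value-to-rank")], labels
        )
        assert spec.method == "unit-vector"

    def test_reported_sc_matches_independent_recomputation(self, rng):
        values = rng.negative_binomial(2, 0.2, size=(30, 10)).astype(float)
        labels = rng.integers(0, 3, size=30)
        X = _em(values)
        spec, table = select_transformation(X, default_candidates(), labels)
        for _, row in table.iterrows():
            transformed = apply_transform(X, TransformSpec(row["method"]))
            expected = metrics.silhouette(transformed.values, labels)
            assert row["silhouette"] == pytest.approx(expected, abs=1e-12)
        best = table.loc[table["silhouette"].idxmax(), "method"]
        assert spec.method == best
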
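"""QC metrics, filters, normalization, variable genes, PCA and clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from modpres.preprocess import (
    QCThresholds,
    assign_cell_types,
    cluster_cells,
    compute_cell_qc,
    filter_cells,
    filter_genes,
    log_normalize,
    run_pca,
    scale_genes,
    select_optimal_dims,
    select_variable_genes,
)


def _qc_row(n_umi, n_genes, pct_mito, complexity):
    return pd.DataFrame(
        {"n_umi": [n_umi], "n_genes": [n_genes], "pct_mito": [pct_mito],
         "complexity": [complexity]}
    )


class TestCellQC:
    def test_metric_arithmetic(self):
        # 3 genes; one mitochondrial
        counts = pd.DataFrame(
            [[900, 100, 0], [1, 1, 0]], columns=["G1", "MT-1", "G3"]
        )
        qc = compute_cell_qc(counts)
        assert qc.loc[0, "n_umi"] == 1000
        assert qc.loc[0, "pct_mito"] == pytest.approx(0.10)
        assert qc.loc[0, "n_genes"] == 2
        # complexity = log10(n_genes)/log10(n_umi)
        assert qc.loc[0, "complexity"] == pytest.approx(np.log10(2) / np.log10(1000))

    def test_complexity_closed_form(self):
        # a cell with 500 detected genes and 1000 UMIs
        cols = [f"G{i}" for i in range(500)]
        row = np.ones(500)
        row[0] = 501  # total 1000
        qc = compute_cell_qc(pd.DataFrame([row], columns=cols))
        assert qc.loc[0, "complexity"] == pytest.approx(np.log10(500) / np.log10(1000), abs=1e-10)
        assert qc.loc[0, "complexity"] == pytest.approx(0.8995, abs=5e-4)

    def test_zero_umi_cell_fails_filter(self):
        counts = pd.DataFrame([[0, 0], [5, 5]], columns=["G1", "G2"])
        qc = compute_cell_qc(counts)
        assert np.isnan(qc.loc[0, "complexity"])
        keep = filter_cells(qc, QCThresholds(min_umi=1, min_genes=1, min_complexity=0.0))
        assert not keep[0]


class TestFilters:
    @pytest.mark.parametrize(
        "umi,genes,mito,cx,expected",
        [
            (1000, 600, 0.16, 0.9, False),   # more than 15% mito -> out
            (1000, 499, 0.05, 0.9, False),   # fewer than 500 genes -> out
            (299, 600, 0.05, 0.9, False),    # fewer than 300 transcripts -> out
            (1000, 600, 0.05, 0.69, False),  # complexity below 0.70 -> out
            (300, 500, 0.15, 0.70, True),    # exactly on every threshold -> kept
        ],
    )
    def test_boundary_semantics(self, umi, genes, mito, cx, expected):
        keep = filter_cells(_qc_row(umi, genes, mito, cx))
        assert bool(keep[0]) is expected

    def test_gene_filter_boundaries(self):
        # genes nonzero in 10, 9 and 0 cells
        X = np.zeros((12, 3))
        X[:10, 0] = 1
        X[:9, 1] = 1
        keep = filter_genes(pd.DataFrame(X, columns=["A", "B", "C"]))
        assert list(keep) == [True, False, False]

    def test_filters_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(50, 30))
        counts = pd.DataFrame(X, columns=[f"G{i}" for i in range(30)])
        keep1 = filter_genes(counts, min_cells=5)
        filtered = counts.loc[:, keep1]
        keep2 = filter_genes(filtered, min_cells=5)
        assert keep2.all()


class TestLogNormalize:
    def test_closed_form(self):
        counts = pd.DataFrame([[1, 9999], [0, 10000]], columns=["A", "B"])
        norm = log_normalize(counts)
        assert norm.iloc[0, 0] == pytest.approx(np.log(2), abs=1e-12)
        assert norm.iloc[1, 0] == 0.0

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(5, 20)) + 1
        doubled = counts.copy()
        doubled[2] *= 3
        a = log_normalize(counts.astype(float))
        b = log_normalize(doubled.astype(float))
        np.testing.assert_allclose(a[2], b[2], atol=1e-12)

    def test_zero_total_cell_is_an_error(self):
        with pytest.raises(ValueError, match="zero total"):
            log_normalize(np.array([[0, 0], [1, 1]]))


class TestVariableGenes:
    def test_cardinality_contract(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(2.0, (100, 57)),
                              columns=[f"G{i}" for i in range(57)])
        got = select_variable_genes(counts, fraction=0.2)
        assert len(got) == int(np.ceil(0.2 * 57))

    def test_constant_gene_never_beats_variable(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(3.0, (200, 20)).astype(float)
        X[:, 0] = 5.0  # constant
        counts = pd.DataFrame(X, columns=[f"G{i}" for i in range(20)])
        top = select_variable_genes(counts, fraction=0.5)
        assert "G0" not in top

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            select_variable_genes(pd.DataFrame(np.ones((5, 12))), fraction=0.0)

    def test_planted_module_genes_enriched(self, small_dataset):
        datasets, truth = small_dataset
        ref = datasets["reference"]
        top = set(select_variable_genes(ref, fraction=0.2))
        planted = set(truth.module_labels.index[truth.module_labels != "grey"])
        n_genes = ref.n_vars
        in_top_planted = len(top & planted)
        in_top_bg = len(top) - in_top_planted
        out_planted = len(planted) - in_top_planted
        out_bg = (n_genes - len(planted)) - in_top_bg
        odds = (in_top_planted * out_bg) / max(in_top_bg * out_planted, 1)
        assert odds > 1.0


class TestScaleGenes:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(3, 2, (100, 5)))
        z = scale_genes(df)
        np.testing.assert_allclose(z.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(0, ddof=1), 1.0, atol=1e-10)

    def test_clipping_at_ten(self):
        x = np.zeros(200)
        x[0] = 100.0  # an extreme outlier lands beyond 10 sd
        z = scale_genes(pd.DataFrame({"g": x}))
        assert z["g"].max() == pytest.approx(10.0)

    def test_constant_gene_becomes_zero(self):
        z = scale_genes(pd.DataFrame({"g": np.ones(10)}))
        assert (z["g"] == 0).all()


class TestPCA:
    def test_variance_conservation(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 8)))
        res = run_pca(scale_genes(df), npcs=8)
        assert res.pv.sum() == pytest.approx(100.0, abs=1e-8)

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(6)
        res = run_pca(pd.DataFrame(rng.normal(size=(50, 10))), npcs=5)
        cov = np.cov(res.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_two_block_structure_dominates(self):
        rng = np.random.default_rng(7)
        f1, f2 = rng.normal(size=(2, 300))
        X = np.column_stack(
            [3 * f1 + 0.3 * rng.normal(size=300) for _ in range(5)]
            + [3 * f2 + 0.3 * rng.normal(size=300) for _ in range(5)]
        )
        res = run_pca(scale_genes(pd.DataFrame(X)), npcs=8)
        assert res.pv[:2].sum() > 50.0


class TestOptimalDims:
    def test_hand_traced_examples(self):
        assert select_optimal_dims([40, 20, 12, 8, 6, 4.5, 3, 2.95, 2.2, 1.35]) == 6
        assert select_optimal_dims([96, 4]) == 2
        assert select_optimal_dims([5.0] * 8) == 1

    def test_neither_criterion_met_warns(self):
        with pytest.warns(UserWarning):
            assert select_optimal_dims([60, 40]) == 2

    def _oracle(self, pv):
        """Exhaustive restatement of the 3-step rule."""
        cp = np.cumsum(pv)
        s2 = next((i + 1 for i in range(len(pv)) if cp[i] > 90 and pv[i] < 5), None)
        s3 = next((i + 1 for i in range(len(pv) - 1) if pv[i] - pv[i + 1] < 0.1), None)
        cands = [s for s in (s2, s3) if s is not None]
        return min(cands) if cands else len(pv)

    def test_agrees_with_oracle_on_random_profiles(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.integers(2, 40)
            raw = rng.dirichlet(np.ones(n)) * 100
            pv = np.sort(raw)[::-1]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert select_optimal_dims(pv) == self._oracle(pv)


class TestClustering:
    def test_two_blobs_perfectly_separated(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.3, (100, 5))
        b = rng.normal(6, 0.3, (100, 5))
        coords = np.vstack([a, b])
        truth = np.array([0] * 100 + [1] * 100)
        labels = cluster_cells(coords, resolution=0.5, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_tiny_resolution_single_cluster(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(80, 4))
        labels = cluster_cells(coords, resolution=0.01, seed=0)
        assert len(np.unique(labels)) == 1

    def test_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.3, (60, 4))
        b = rng.normal(5, 0.3, (60, 4))
        coords = np.vstack([a, b])
        perm = rng.permutation(120)
        l1 = cluster_cells(coords, resolution=0.5, seed=3)
        l2 = cluster_cells(coords[perm], resolution=0.5, seed=3)
        assert adjusted_rand_score(l1[perm], l2) == 1.0


class TestAssignCellTypes:
    def test_full_clustering_path_recovers_types(self):
        # on module-free data the QC -> HVG -> PCA -> Louvain -> marker-argmax
        # chain assigns nearly every cell its planted type
        from modpres.preprocess import log_normalize as ln
        from modpres.syndata import default_config, generate_dataset
        from modpres.preprocess import run_pca, select_optimal_dims, \
            select_variable_genes, scale_genes, cluster_cells, filter_genes
        cfg = default_config(seed=0)
        cfg.modules = []
        datasets, truth = generate_dataset(cfg)
        adata = datasets["reference"]
        adata = adata[filter_cells(compute_cell_qc(adata))].copy()
        adata = adata[:, filter_genes(adata)].copy()
        adata = ln(adata)
        hvg = select_variable_genes(adata, fraction=0.2)
        pca = run_pca(scale_genes(adata, genes=hvg), npcs=40, seed=0)
        dims = select_optimal_dims(pca.pv)
        labels = cluster_cells(pca.scores, dims=dims, resolution=2.0, seed=0)
        assigned = assign_cell_types(labels, adata, truth.markers)
        accuracy = (assigned.to_numpy() == adata.obs["cell_type"].to_numpy()).mean()
        assert accuracy > 0.9

    def test_recovers_planted_types(self, small_dataset):
        datasets, truth = small_dataset
        ref = datasets["reference"].copy()
        from modpres.preprocess import log_normalize as ln
        ref = ln(ref)
        # use the planted type labels as "clusters": per-cluster argmax must echo them
        codes, cats = pd.factorize(ref.obs["cell_type"])
        assigned = assign_cell_types(codes, ref, truth.markers)
        accuracy = (assigned.to_numpy() == ref.obs["cell_type"].to_numpy()).mean()
        assert accuracy > 0.9

    def test_single_marker_forces_type(self):
        df = pd.DataFrame({"m1": [5.0, 4.0, 6.0], "x": [1.0, 2.0, 1.5]})
        got = assign_cell_types(np.zeros(3, dtype=int), df,
                                {"mast": ["m1"], "B": ["zz_absent"]})
        assert (got == "mast").all()

    def test_missing_marker_type_warns(self):
        df = pd.DataFrame({"m1": [5.0, 4.0], "x": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="no markers"):
            assign_cell_types(np.zeros(2, dtype=int), df, {"mast": ["m1"], "B": ["nope"]})

    def test_all_markers_absent_is_error(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            assign_cell_types(np.zeros(2, dtype=int), df, {"B": ["nope"]})
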
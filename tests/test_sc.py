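"""Single-nucleus core: QC thresholds, normalization closed forms, HVG
selection, PCA projection identities, clustering, multinomial downsampling,
differential expression, composition tables."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from corticolumn.sc import (
    qc_filter,
    normalize_log,
    select_hvgs,
    pca_embed,
    cluster_graph,
    downsample_umis,
    differential_expression,
    subclass_proportions,
)


def _adata(X, obs=None):
    X = np.asarray(X)
    return ad.AnnData(
        X=sp.csr_matrix(X.astype(np.int64)),
        obs=obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])]),
    )


class TestQCFilter:
    def _cell(self, n_genes_detected, total, width):
        """Row with the requested detection count and UMI total."""
        row = np.zeros(width, dtype=np.int64)
        row[:n_genes_detected] = 1
        row[0] += total - n_genes_detected
        return row

    def test_hand_checked_thresholds(self):
        w = 7000
        rows = [
            self._cell(800, 1000, w),     # keep
            self._cell(700, 1000, w),     # boundary genes: removed (strict)
            self._cell(900, 40000, w),    # boundary UMIs: removed (strict)
            self._cell(6500, 6600, w),    # boundary genes: removed
            self._cell(1000, 39999, w),   # keep
        ]
        out = qc_filter(_adata(np.array(rows)), min_cells_per_gene=1)
        assert list(out.obs_names) == ["c0", "c4"]

    def test_gene_detected_in_eight_cells_removed(self):
        X = np.ones((20, 1200), dtype=np.int64)
        X[:, 0] = 0
        X[:8, 0] = 1  # gene g0 detected in exactly 8 surviving cells
        out = qc_filter(_adata(X), min_genes=1000, max_genes=1300, max_umis=10**6)
        assert "g0" not in out.var_names
        assert out.n_vars == 1199

    def test_empty_result_warns_not_raises(self):
        with pytest.warns(UserWarning, match="every cell"):
            out = qc_filter(_adata(np.ones((3, 5))))
        assert out.n_obs == 0

    def test_order_stability_under_permutation(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2, size=(30, 1500))
        # heterogeneous detection so the filter keeps a strict subset
        X[::3] = (X[::3] > 1).astype(np.int64)
        a = _adata(X)
        perm = rng.permutation(30)
        b = a[perm].copy()
        out_a = qc_filter(a, min_genes=900, max_genes=1600, max_umis=10**6)
        out_b = qc_filter(b, min_genes=900, max_genes=1600, max_umis=10**6)
        assert 0 < out_a.n_obs < 30
        expected = [n for n in a.obs_names[perm] if n in set(out_a.obs_names)]
        assert list(out_b.obs_names) == expected


class TestNormalizeLog:
    def test_closed_form(self):
        out = normalize_log(_adata([[10, 30, 60, 0]]), scale=100)
        np.testing.assert_allclose(
            np.asarray(out.X.todense()).ravel(),
            [np.log(11), np.log(31), np.log(61), 0.0],
        )

    def test_zero_total_cell_maps_to_zeros(self, toy_counts):
        out = normalize_log(toy_counts)
        assert np.asarray(out.X[1]).max() == 0.0

    def test_expm1_rescaling_recovers_proportions(self, toy_counts):
        out = normalize_log(toy_counts, scale=1e4)
        x = np.asarray(out.X)
        props = np.expm1(x[0]) / np.expm1(x[0]).sum()
        np.testing.assert_allclose(props, [0.1, 0.3, 0.6, 0.0], atol=1e-12)


class TestSelectHVGs:
    def test_planted_high_variance_genes_selected(self):
        rng = np.random.default_rng(1)
        n, flat, hot = 300, 500, 10
        # flat genes: near-constant, means spread over [4, 6]; planted
        # genes: strongly bimodal, at most one per mean bin
        X = rng.normal(0.0, 0.05, size=(n, flat + hot))
        X[:, :flat] += 4.0 + 2.0 * np.arange(flat) / flat
        for j in range(hot):
            mu = 4.1 + 0.18 * j
            X[: n // 2, flat + j] = 0.0
            X[n // 2 :, flat + j] += 2 * mu
        X = X.clip(min=0)
        adata = ad.AnnData(X=np.log1p(X), var=pd.DataFrame(index=[f"g{i:04d}" for i in range(flat + hot)]))
        sel = select_hvgs(adata, n=hot)
        assert set(sel) == {f"g{i:04d}" for i in range(flat, flat + hot)}

    def test_identity_when_n_equals_genes(self, toy_counts):
        norm = normalize_log(toy_counts)
        assert set(select_hvgs(norm, n=4)) == set(norm.var_names)

    def test_n_too_large_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            select_hvgs(normalize_log(toy_counts), n=10)


class TestPCAEmbed:
    def test_rank2_perfect_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 20))
        adata = ad.AnnData(X=X)
        emb = pca_embed(adata, D=2)
        Z = (X - emb.gene_center) / emb.gene_scale
        recon = emb.scores @ emb.loadings.T
        np.testing.assert_allclose(recon, Z, atol=1e-8)

    def test_projection_matches_fit_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2)) @ rng.normal(size=(2, 15))
        adata = ad.AnnData(X=X)
        emb = pca_embed(adata, D=2)
        np.testing.assert_allclose(emb.project(X), emb.scores, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        emb = pca_embed(ad.AnnData(X=rng.normal(size=(40, 30))), D=5)
        np.testing.assert_allclose(emb.loadings.T @ emb.loadings, np.eye(5), atol=1e-6)

    def test_balanced_with_full_equal_labels_matches_unbalanced(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 12))
        labels = np.repeat(["a", "b"], 20)
        e1 = pca_embed(ad.AnnData(X=X), D=3)
        e2 = pca_embed(ad.AnnData(X=X), D=3, balance_labels=labels, balance_to=20)
        np.testing.assert_allclose(np.abs(e1.scores), np.abs(e2.scores), atol=1e-8)


class TestClusterGraph:
    def test_two_blobs_two_clusters(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.2, (60, 5)), rng.normal(8, 0.2, (60, 5))])
        emb = pca_embed(ad.AnnData(X=X), D=3)
        # k comparable to blob size: each blob is near-clique, split only
        # across the gap
        labels = cluster_graph(emb, k_neighbors=40, resolution=1.0, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        emb = pca_embed(ad.AnnData(X=rng.normal(size=(80, 10))), D=5)
        l1 = cluster_graph(emb, 10, 1.0, seed=42)
        l2 = cluster_graph(emb, 10, 1.0, seed=42)
        np.testing.assert_array_equal(l1, l2)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(8)
        emb = pca_embed(ad.AnnData(X=rng.normal(size=(10, 5))), D=2)
        with pytest.raises(ValueError):
            cluster_graph(emb, k_neighbors=10)


class TestDownsampleUMIs:
    def test_forced_target_totals_exact(self):
        adata = _adata([[10, 30, 60]])
        out = downsample_umis(adata, donor_totals=np.array([10]), seed=0)
        assert out.X.sum() == 10
        out0 = downsample_umis(adata, donor_totals=np.array([0]), seed=0)
        assert out0.X.sum() == 0

    def test_target_above_total_leaves_cell_unchanged(self):
        adata = _adata([[10, 30, 60]])
        out = downsample_umis(adata, donor_totals=np.array([1000]), seed=0)
        np.testing.assert_array_equal(np.asarray(out.X.todense()), [[10, 30, 60]])

    def test_never_increases_entries(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(3, size=(20, 50))
        adata = _adata(X)
        out = downsample_umis(adata, donor_totals=rng.integers(0, 100, 30), seed=1)
        assert (np.asarray(out.X.todense()) <= X).all()

    def test_unbiased_fractions(self):
        # mean per-gene fraction over many resamples matches multinomial moments
        adata = _adata([[10, 30, 60]])
        sums = np.zeros(3)
        n_rep = 2000
        for s in range(n_rep):
            out = downsample_umis(adata, donor_totals=np.array([10]), seed=s)
            sums += np.asarray(out.X.todense()).ravel() / 10.0
        frac = sums / n_rep
        se = np.sqrt(np.array([0.1 * 0.9, 0.3 * 0.7, 0.6 * 0.4]) / 10 / n_rep)
        assert (np.abs(frac - [0.1, 0.3, 0.6]) < 3 * se).all()

    def test_negative_targets_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            downsample_umis(toy_counts, donor_totals=np.array([-1]))


class TestDifferentialExpression:
    def _planted(self):
        rng = np.random.default_rng(10)
        X = rng.poisson(5, size=(40, 6))
        X[:20, 0] += 50  # planted up in group A
        X[:20, 1] += 50
        raw = _adata(X)
        norm = normalize_log(raw)
        a = np.arange(20)
        b = np.arange(20, 40)
        return raw, norm, a, b

    def test_planted_genes_recovered_exactly(self):
        raw, norm, a, b = self._planted()
        table = differential_expression(norm, raw, a, b)
        assert set(table.gene) == {"g0", "g1"}

    def test_antisymmetry_under_group_swap(self):
        raw, norm, a, b = self._planted()
        t_ab = differential_expression(norm, raw, a, b, lfc_min=-10, pct_min=-1, alpha=1.1)
        t_ba = differential_expression(norm, raw, b, a, lfc_min=-10, pct_min=-1, alpha=1.1)
        m_ab = t_ab.set_index("gene")
        m_ba = t_ba.set_index("gene")
        np.testing.assert_allclose(m_ab["log2FC"], -m_ba.loc[m_ab.index, "log2FC"], atol=1e-12)
        np.testing.assert_allclose(m_ab["p"], m_ba.loc[m_ab.index, "p"], atol=1e-12)

    def test_overlapping_groups_rejected(self):
        raw, norm, a, b = self._planted()
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(norm, raw, a, np.arange(10, 30))

    def test_gene_zero_in_both_groups_excluded(self):
        X = np.zeros((10, 2), dtype=np.int64)
        X[:, 1] = 5
        raw = _adata(X)
        norm = normalize_log(raw)
        table = differential_expression(norm, raw, np.arange(5), np.arange(5, 10))
        assert "g0" not in set(table.gene)


class TestSubclassProportions:
    def test_simple_split(self):
        cells = pd.DataFrame(
            {"sample": "s1", "subclass": ["a", "a", "b", "b"], "cell_class": "x"}
        )
        out = subclass_proportions(cells)
        np.testing.assert_allclose(out.loc["s1"], [0.5, 0.5])

    def test_within_restricts_denominator(self):
        cells = pd.DataFrame(
            {
                "sample": "s1",
                "subclass": ["Pvalb", "Sst", "L4", "L4"],
                "cell_class": ["gabaergic", "gabaergic", "glut", "glut"],
            }
        )
        out = subclass_proportions(cells, within="gabaergic")
        assert set(out.columns) == {"Pvalb", "Sst"}
        np.testing.assert_allclose(out.loc["s1"].sum(), 1.0, atol=1e-12)

    def test_rows_sum_to_one(self, small_atlas):
        _, adata, _ = small_atlas
        out = subclass_proportions(adata.obs)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_denominator_rejected(self):
        cells = pd.DataFrame({"sample": ["s1"], "subclass": ["a"], "cell_class": ["x"]})
        with pytest.raises(ValueError):
            subclass_proportions(cells, within="missing_class")
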
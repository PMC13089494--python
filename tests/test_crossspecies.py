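"""Cross-species operations: ortholog alignment, joint embedding, overlap
statistic, balanced transfer with pool depletion, confusion matrices,
silhouettes, loading/profile correlations."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from corticolumn.sc import normalize_log, pca_embed
from corticolumn.crossspecies import (
    OrthologMap,
    ortholog_subset,
    integrate_embed,
    cluster_overlap_fraction,
    balanced_label_transfer,
    confusion_matrix,
    silhouette_pairwise,
    loading_correlations,
    profile_correlations,
)


def _ann(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return ad.AnnData(X=X, var=pd.DataFrame(index=genes))


class TestOrthologSubset:
    def test_identity_map_intersection(self):
        a = _ann(np.ones((2, 3)), ["x", "y", "z"])
        b = _ann(np.ones((2, 2)), ["y", "z"])
        omap = OrthologMap.identity(["x", "y", "z"])
        sa, sb = ortholog_subset(a, b, omap)
        assert list(sa.var_names) == ["y", "z"] == list(sb.var_names)

    def test_renaming_and_order(self):
        a = _ann(np.arange(10).reshape(2, 5), [f"a{i}" for i in range(5)])
        b = _ann(np.arange(10).reshape(2, 5), [f"b{i}" for i in range(5)])
        omap = OrthologMap(pd.DataFrame({"gene_a": ["a2", "a0", "a4"], "gene_b": ["b0", "b2", "b4"]}))
        sa, sb = ortholog_subset(a, b, omap)
        assert list(sa.var_names) == ["a0", "a2", "a4"]
        assert list(sb.var_names) == ["a0", "a2", "a4"]  # renamed to species-A ids
        # b columns follow the map: a0<-b2, a2<-b0, a4<-b4
        np.testing.assert_array_equal(sb.X[:, 0], b.X[:, 2])

    def test_duplicate_mapping_rejected(self):
        with pytest.raises(ValueError, match="one-to-one"):
            OrthologMap(pd.DataFrame({"gene_a": ["x", "x"], "gene_b": ["u", "v"]}))


class TestIntegrateEmbed:
    def test_identical_datasets_zero_shift(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 20))
        emb, tags = integrate_embed([_ann(X), _ann(X.copy())], D=5)
        np.testing.assert_allclose(emb.scores[tags == 0], emb.scores[tags == 1], atol=1e-8)

    def test_constant_offset_reduced(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 20))
        Y = X + 5.0  # constant gene offset
        emb_pre = pca_embed(_ann(np.vstack([X, Y])), D=5)
        pre = np.linalg.norm(emb_pre.scores[:80].mean(0) - emb_pre.scores[80:].mean(0))
        emb, tags = integrate_embed([_ann(X), _ann(Y)], D=5)
        post = np.linalg.norm(emb.scores[tags == 0].mean(0) - emb.scores[tags == 1].mean(0))
        assert post < pre

    def test_shared_low_rank_structure_recovered(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(3, 30))
        A = rng.normal(size=(100, 3)) @ basis + 0.01 * rng.normal(size=(100, 30))
        B = rng.normal(size=(120, 3)) @ basis + 0.01 * rng.normal(size=(120, 30))
        emb, _ = integrate_embed([_ann(A), _ann(B)], D=3)
        # principal angle between recovered loading span and the true basis
        # span, expressed in the per-gene z-scored coordinates the embedding
        # works in
        Q1, _ = np.linalg.qr(emb.loadings)
        sd = np.vstack([A, B]).std(axis=0)
        Q2, _ = np.linalg.qr((basis / sd).T)
        s = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
        angle_deg = np.degrees(np.arccos(np.clip(s.min(), -1, 1)))
        assert angle_deg < 10

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            integrate_embed([_ann(np.ones((5, 4)))])


class TestClusterOverlap:
    def test_hand_computed_value(self):
        # subclass i spread (0.6, 0.4), j spread (0.2, 0.8) over two clusters
        sub = ["i"] * 10 + ["j"] * 10
        clu = [0] * 6 + [1] * 4 + [0] * 2 + [1] * 8
        O = cluster_overlap_fraction(np.array(sub), np.array(clu))
        assert O.loc["i", "j"] == pytest.approx(0.6)

    def test_identity_and_bounds(self):
        rng = np.random.default_rng(3)
        sub = rng.choice(["a", "b", "c"], 200)
        clu = rng.integers(0, 4, 200)
        O = cluster_overlap_fraction(sub, clu)
        assert np.allclose(np.diag(O), 1.0)
        assert ((O.to_numpy() >= 0) & (O.to_numpy() <= 1)).all()
        np.testing.assert_allclose(O, O.T)

    def test_disjoint_clusters_zero(self):
        sub = np.array(["i"] * 5 + ["j"] * 5)
        clu = np.array([0] * 5 + [1] * 5)
        assert cluster_overlap_fraction(sub, clu).loc["i", "j"] == 0.0

    def test_equals_one_iff_identical_distributions(self):
        sub = np.array(["i"] * 4 + ["j"] * 8)
        clu = np.array([0, 0, 1, 1] + [0] * 4 + [1] * 4)
        O = cluster_overlap_fraction(sub, clu)
        assert O.loc["i", "j"] == pytest.approx(1.0)


class TestBalancedTransfer:
    def _separable(self, n_ref=120, n_query=40):
        rng = np.random.default_rng(4)
        centers = {"a": 0.0, "b": 8.0, "c": -8.0}
        Xr, lab = [], []
        for name, c in centers.items():
            Xr.append(rng.normal(c, 0.3, size=(n_ref // 3, 20)))
            lab += [name] * (n_ref // 3)
        Xq = rng.normal(8.0, 0.3, size=(n_query, 20))  # all from 'b'
        return _ann(np.vstack(Xr)), np.array(lab), _ann(Xq)

    def test_separable_accuracy_one(self):
        ref, lab, query = self._separable()
        res = balanced_label_transfer(ref, lab, query, n_iter=3, cap=30, D=5, k_vote=10, seed=0)
        assert (res.predicted == "b").all()
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_pool_depletion_before_reuse(self):
        ref, lab, query = self._separable()
        # cap 30 on pools of 40: after 2 iterations every cell used at least once
        res = balanced_label_transfer(ref, lab, query, n_iter=2, cap=30, D=5, k_vote=10, seed=1)
        counts = res.usage_counts.to_numpy()
        assert counts.min() >= 1
        assert counts.max() <= 2

    def test_depletion_schedule_draw_sizes(self):
        # pool of 250 with cap 100 draws 100, 100, 50, then resets
        from corticolumn.crossspecies import _DepletingPool

        rng = np.random.default_rng(5)
        pool = _DepletingPool(np.arange(250), rng)
        sizes = [pool.draw(100).size for _ in range(4)]
        assert sizes == [100, 100, 50, 100]

    def test_k_vote_exceeding_draw_rejected(self):
        ref, lab, query = self._separable()
        with pytest.raises(ValueError, match="k_vote"):
            balanced_label_transfer(ref, lab, query, n_iter=1, cap=2, D=2, k_vote=50)


class TestConfusionMatrix:
    def test_perfect_prediction_identity(self):
        labels = np.array(["a", "b", "c", "a"])
        cm = confusion_matrix(labels, labels)
        np.testing.assert_allclose(cm.to_numpy(), np.eye(3)[[0, 1, 2]][:, [0, 1, 2]])

    def test_single_predicted_label(self):
        cm = confusion_matrix(np.array(["a", "b", "b"]), np.array(["a", "a", "a"]))
        assert cm.loc["a"].sum() == pytest.approx(1.0)
        assert cm.loc["b"].sum() == 0.0

    def test_hand_counted_fractions(self):
        true = np.array(["x", "x", "x", "y", "y", "y"])
        pred = np.array(["x", "x", "y", "y", "y", "x"])
        cm = confusion_matrix(true, pred)
        assert cm.loc["x", "x"] == pytest.approx(2 / 3)
        assert cm.loc["x", "y"] == pytest.approx(1 / 3)
        rows = cm.sum(axis=1)
        np.testing.assert_allclose(rows[rows > 0], 1.0, atol=1e-12)


class TestSilhouette:
    def test_distant_tight_clusters_near_one(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.01, (30, 3)), rng.normal(100, 0.01, (30, 3))])
        lab = np.array(["a"] * 30 + ["b"] * 30)
        assert silhouette_pairwise(X, lab, ("a", "b")) > 0.99

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 3))
        lab = np.array(["a", "b"] * 100)
        assert abs(silhouette_pairwise(X, lab, ("a", "b"))) < 0.05

    def test_invariant_under_rotation(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(3, 1, (40, 3))])
        lab = np.array(["a"] * 40 + ["b"] * 40)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        s1 = silhouette_pairwise(X, lab, ("a", "b"))
        s2 = silhouette_pairwise(X @ Q, lab, ("a", "b"))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (25, 4)), rng.normal(2, 1, (25, 4))])
        lab = np.array(["a"] * 25 + ["b"] * 25)
        assert silhouette_pairwise(X, lab, ("a", "b")) == pytest.approx(
            silhouette_score(X, lab), abs=1e-9
        )


class TestLoadingCorrelations:
    def _emb(self, loadings):
        from corticolumn.sc import Embedding

        g, d = loadings.shape
        return Embedding(
            scores=np.zeros((1, d)),
            loadings=loadings,
            gene_center=np.zeros(g),
            gene_scale=np.ones(g),
        )

    def test_self_correlation_diagonal_one(self):
        rng = np.random.default_rng(10)
        L = rng.normal(size=(50, 4))
        genes = pd.Index([f"g{i}" for i in range(50)])
        omap = OrthologMap.identity(genes)
        out = loading_correlations(self._emb(L), self._emb(L), genes, genes, omap)
        np.testing.assert_allclose(np.abs(np.diag(out)), 1.0, atol=1e-12)

    def test_sign_flip_negates_row(self):
        rng = np.random.default_rng(11)
        L = rng.normal(size=(50, 4))
        L2 = L.copy()
        L2[:, 1] *= -1
        genes = pd.Index([f"g{i}" for i in range(50)])
        omap = OrthologMap.identity(genes)
        a = loading_correlations(self._emb(L), self._emb(L), genes, genes, omap)
        b = loading_correlations(self._emb(L2), self._emb(L), genes, genes, omap)
        np.testing.assert_allclose(b.iloc[1], -a.iloc[1], atol=1e-12)


class TestProfileCorrelations:
    def test_identical_and_reversed_profiles(self):
        # two labels with identical mean profiles -> rho 1; reversed -> -1
        base = np.tile(np.arange(5, dtype=float), (4, 1))
        X = np.vstack([base, base[:, ::-1]])
        adata = _ann(X)
        lab = np.array(["u"] * 4 + ["v"] * 4)
        out = profile_correlations(adata, lab, n_hvg=5)
        assert out.loc["u", "v"] == pytest.approx(-1.0)
        lab2 = np.array(["u"] * 2 + ["w"] * 2 + ["v"] * 4)
        out2 = profile_correlations(adata, lab2, n_hvg=5)
        assert out2.loc["u", "w"] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        from scipy.stats import spearmanr

        X = np.array([[1.0, 2, 3, 4, 5], [1.0, 3, 2, 5, 4]])
        adata = _ann(X)
        out = profile_correlations(adata, np.array(["a", "b"]), n_hvg=5)
        assert out.loc["a", "b"] == pytest.approx(spearmanr(X[0], X[1]).statistic)
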
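"""Cross-species integration and label transfer.

Genes are restricted to one-to-one orthologs, datasets are embedded jointly
(per-dataset z-scoring, joint PCA, a single global mutual-nearest-neighbor
shift per dataset), and labels move from reference to query by balanced
iterative k-nearest-neighbor voting: each iteration draws at most ``cap``
cells per subclass from a depleting pool (reset when exhausted), fits a
fresh embedding, projects the query, and votes among the ``k_vote`` nearest
reference cells with inverse-distance weights; probabilities are averaged
over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .sc import Embedding, pca_embed, select_hvgs, _densify

__all__ = [
    "OrthologMap",
    "LabelTransferResult",
    "ortholog_subset",
    "integrate_embed",
    "cluster_overlap_fraction",
    "balanced_label_transfer",
    "confusion_matrix",
    "silhouette_pairwise",
    "loading_correlations",
    "profile_correlations",
]


@dataclass
class OrthologMap:
    """Strictly one-to-one gene pairs between species A and B."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        p = self.pairs
        if p.empty:
            raise ValueError("ortholog map is empty")
        if p["gene_a"].duplicated().any() or p["gene_b"].duplicated().any():
            raise ValueError("ortholog map is not one-to-one")

    @classmethod
    def identity(cls, genes) -> "OrthologMap":
        g = pd.Index(genes)
        return cls(pd.DataFrame({"gene_a": g, "gene_b": g}))


@dataclass
class LabelTransferResult:
    probabilities: pd.DataFrame  # query cells x reference labels, rows sum to 1
    predicted: pd.Series  # argmax label, lexicographic tie-break
    n_iterations: int
    usage_counts: pd.Series | None = None  # reference-cell draw counts (audit)


def ortholog_subset(
    a: ad.AnnData, b: ad.AnnData, omap: OrthologMap
) -> tuple[ad.AnnData, ad.AnnData]:
    """Restrict both matrices to mapped genes present in both, columns
    aligned in identical order under species-A naming (sorted by gene_a)."""
    pairs = omap.pairs
    keep = pairs["gene_a"].isin(a.var_names) & pairs["gene_b"].isin(b.var_names)
    pairs = pairs[keep].sort_values("gene_a")
    if pairs.empty:
        raise ValueError("no mapped genes present in both matrices")
    a_sub = a[:, pairs["gene_a"].to_numpy()].copy()
    b_sub = b[:, pairs["gene_b"].to_numpy()].copy()
    b_sub.var_names = pairs["gene_a"].to_numpy()
    return a_sub, b_sub


def integrate_embed(
    parts: list[ad.AnnData],
    D: int = 30,
    mnn_k: int = 20,
    seed: int = 0,
) -> tuple[Embedding, np.ndarray]:
    """Joint embedding of >=2 normalized datasets sharing a gene space.

    Each dataset is z-scored per gene, the concatenation is reduced by PCA to
    ``D`` components, and every dataset except the largest receives one
    global shift: the mean displacement across its mutual nearest neighbor
    pairs (k = ``mnn_k``) with the largest dataset.  Returns the embedding
    (scores hold all cells, in input order) and an integer dataset tag per
    cell.  Deterministic for fixed inputs and seed.
    """
    if len(parts) < 2:
        raise ValueError("need at least 2 datasets")
    mats, tags = [], []
    for t, p in enumerate(parts):
        X = _densify(p.X)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mats.append((X - mu) / sd)
        tags.append(np.full(X.shape[0], t))
    Z = np.vstack(mats)
    tags = np.concatenate(tags)
    joint = ad.AnnData(X=Z)
    emb = pca_embed(joint, D=min(D, min(Z.shape) - 1), seed=seed)
    scores = emb.scores
    largest = int(np.argmax([m.shape[0] for m in mats]))
    ref_idx = np.flatnonzero(tags == largest)
    ref = scores[ref_idx]
    for t in range(len(parts)):
        if t == largest:
            continue
        qi = np.flatnonzero(tags == t)
        q = scores[qi]
        k_rq = min(mnn_k, len(ref))
        k_qr = min(mnn_k, len(q))
        nn_r = NearestNeighbors(n_neighbors=k_rq).fit(ref)
        nn_q = NearestNeighbors(n_neighbors=k_qr).fit(q)
        _, q2r = nn_r.kneighbors(q)  # per query cell: ref neighbors
        _, r2q = nn_q.kneighbors(ref)  # per ref cell: query neighbors
        back = [set(row) for row in r2q]
        pairs = [
            (i, j)
            for i, row in enumerate(q2r)
            for j in row
            if i in back[j]
        ]
        if pairs:
            disp = np.mean([ref[j] - q[i] for i, j in pairs], axis=0)
            scores[qi] += disp
    emb.scores = scores
    return emb, tags


def cluster_overlap_fraction(
    subclass_labels: np.ndarray, cluster_labels: np.ndarray
) -> pd.DataFrame:
    """Symmetric subclass-pair overlap across integrated clusters.

    ``O(i, j) = sum_c min(n_ic / n_i, n_jc / n_j)`` — the shared mass of the
    two subclasses' cluster distributions; 1 iff identical, 0 iff disjoint.
    """
    subclass_labels = np.asarray(subclass_labels)
    cluster_labels = np.asarray(cluster_labels)
    if subclass_labels.shape[0] != cluster_labels.shape[0]:
        raise ValueError("label vectors differ in length")
    tab = pd.crosstab(pd.Series(subclass_labels), pd.Series(cluster_labels))
    if (tab.sum(axis=1) == 0).any():
        raise ValueError("empty subclass")
    frac = tab.div(tab.sum(axis=1), axis=0).to_numpy()
    n = frac.shape[0]
    O = np.empty((n, n))
    for i in range(n):
        O[i] = np.minimum(frac[i], frac).sum(axis=1)
    return pd.DataFrame(O, index=tab.index, columns=tab.index)


class _DepletingPool:
    """Per-subclass sampling without replacement across iterations; the pool
    refills (and reshuffles) once exhausted, so every cell is used at least
    once before any is reused."""

    def __init__(self, indices: np.ndarray, rng: np.random.Generator):
        self.all = np.asarray(indices)
        self.rng = rng
        self.remaining = self.rng.permutation(self.all)

    def draw(self, cap: int) -> np.ndarray:
        if self.remaining.size == 0:
            self.remaining = self.rng.permutation(self.all)
        take = min(cap, self.remaining.size)
        out = self.remaining[:take]
        self.remaining = self.remaining[take:]
        return out


def balanced_label_transfer(
    reference: ad.AnnData,
    ref_labels: np.ndarray | pd.Series,
    query: ad.AnnData,
    n_iter: int = 100,
    cap: int = 100,
    D: int = 30,
    k_vote: int = 30,
    seed: int = 0,
) -> LabelTransferResult:
    """Balanced iterative kNN label transfer from a normalized reference to a
    normalized query (shared gene space).

    Per iteration: draw <=``cap`` cells per subclass from a depleting pool,
    fit a PCA embedding on the draw, project the query, and convert the
    ``k_vote`` nearest reference neighbors of each query cell into a label
    probability vector with inverse-distance weights.  Final probabilities
    are the mean over iterations; the predicted label is the argmax with
    lexicographic tie-break.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    labels = np.asarray(ref_labels).astype(str)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("reference must carry at least 2 subclasses")
    rng = np.random.default_rng(seed)
    pools = {u: _DepletingPool(np.flatnonzero(labels == u), rng) for u in uniq}
    Xref = _densify(reference.X)
    Xq = _densify(query.X)
    probs = np.zeros((query.n_obs, uniq.size))
    usage = np.zeros(reference.n_obs, dtype=int)
    for it in range(n_iter):
        draw = np.concatenate([pools[u].draw(cap) for u in uniq])
        draw.sort()
        usage[draw] += 1
        if k_vote > draw.size:
            raise ValueError(f"k_vote={k_vote} exceeds draw size {draw.size}")
        sub = ad.AnnData(X=Xref[draw])
        emb = pca_embed(sub, D=min(D, min(sub.shape) - 1), seed=int(rng.integers(2**31)))
        qs = emb.project(Xq)
        nn = NearestNeighbors(n_neighbors=k_vote).fit(emb.scores)
        dist, idx = nn.kneighbors(qs)
        w = 1.0 / (dist + 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        lab_idx = np.searchsorted(uniq, labels[draw])
        for col in range(k_vote):
            np.add.at(probs, (np.arange(query.n_obs), lab_idx[idx[:, col]]), w[:, col])
    probs /= n_iter
    prob_df = pd.DataFrame(probs, index=query.obs_names, columns=uniq)
    # argmax with lexicographic tie-break: uniq is sorted, argmax takes first
    predicted = pd.Series(
        uniq[np.argmax(probs, axis=1)], index=query.obs_names, name="predicted"
    )
    return LabelTransferResult(
        probabilities=prob_df,
        predicted=predicted,
        n_iterations=n_iter,
        usage_counts=pd.Series(usage, index=reference.obs_names),
    )


def confusion_matrix(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    row_normalize: bool = True,
) -> pd.DataFrame:
    """Predicted (rows) x true (columns) label matrix; rows sum to 1 when
    normalized, with all-zero rows kept as zeros."""
    true_labels = pd.Series(np.asarray(true_labels).astype(str), name="true")
    predicted_labels = pd.Series(np.asarray(predicted_labels).astype(str), name="predicted")
    labels = sorted(set(true_labels) | set(predicted_labels))
    tab = pd.crosstab(predicted_labels, true_labels).reindex(
        index=labels, columns=labels, fill_value=0
    )
    if row_normalize:
        sums = tab.sum(axis=1)
        tab = tab.div(sums.where(sums > 0, 1.0), axis=0)
    return tab


def silhouette_pairwise(
    scores: np.ndarray, labels: np.ndarray, pair: tuple[str, str]
) -> float:
    """Mean silhouette over the cells of two label groups, Euclidean distance
    in embedding space; singleton cells score 0."""
    labels = np.asarray(labels).astype(str)
    a, b = pair
    ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be nonempty")
    from scipy.spatial.distance import cdist

    Xa, Xb = scores[ia], scores[ib]
    Daa = cdist(Xa, Xa)
    Dbb = cdist(Xb, Xb)
    Dab = cdist(Xa, Xb)
    vals = []
    for i in range(ia.size):
        if ia.size == 1:
            vals.append(0.0)
            continue
        a_i = Daa[i].sum() / (ia.size - 1)
        b_i = Dab[i].mean()
        vals.append((b_i - a_i) / max(a_i, b_i) if max(a_i, b_i) > 0 else 0.0)
    for j in range(ib.size):
        if ib.size == 1:
            vals.append(0.0)
            continue
        a_j = Dbb[j].sum() / (ib.size - 1)
        b_j = Dab[:, j].mean()
        vals.append((b_j - a_j) / max(a_j, b_j) if max(a_j, b_j) > 0 else 0.0)
    return float(np.mean(vals))


def loading_correlations(
    emb_a: Embedding,
    emb_b: Embedding,
    genes_a: pd.Index,
    genes_b: pd.Index,
    omap: OrthologMap,
    top: int = 4,
) -> pd.DataFrame:
    """Pearson correlations between the gene-loading vectors of the first
    ``top`` components of two species' embeddings, restricted to one-to-one
    orthologs present in both."""
    pairs = omap.pairs
    pairs = pairs[pairs["gene_a"].isin(genes_a) & pairs["gene_b"].isin(genes_b)]
    if len(pairs) < 2:
        raise ValueError("fewer than 2 shared genes")
    ia = pd.Index(genes_a).get_indexer(pairs["gene_a"])
    ib = pd.Index(genes_b).get_indexer(pairs["gene_b"])
    La = emb_a.loadings[ia, :top]
    Lb = emb_b.loadings[ib, :top]
    out = np.empty((top, top))
    for i in range(top):
        for j in range(top):
            out[i, j] = np.corrcoef(La[:, i], Lb[:, j])[0, 1]
    return pd.DataFrame(
        out,
        index=[f"A_PC{i + 1}" for i in range(top)],
        columns=[f"B_PC{j + 1}" for j in range(top)],
    )


def profile_correlations(
    norm: ad.AnnData,
    labels: np.ndarray | pd.Series,
    n_hvg: int = 3000,
    zscore_within: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between subclass-average expression
    profiles over the top ``n_hvg`` highly variable genes.

    With ``zscore_within`` (a per-cell group vector, e.g. IT vs. CGE), the
    log-normalized values are z-scored per gene within each group before
    averaging.
    """
    labels = np.asarray(labels).astype(str)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 labels")
    hvgs = select_hvgs(norm, n=min(n_hvg, norm.n_vars))
    X = _densify(norm[:, hvgs].X)
    if zscore_within is not None:
        groups = np.asarray(zscore_within).astype(str)
        for g in np.unique(groups):
            m = groups == g
            mu = X[m].mean(axis=0)
            sd = X[m].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X[m] = (X[m] - mu) / sd
    profiles = np.stack([X[labels == u].mean(axis=0) for u in uniq])
    out = np.empty((uniq.size, uniq.size))
    for i in range(uniq.size):
        for j in range(uniq.size):
            out[i, j] = 1.0 if i == j else spearmanr(profiles[i], profiles[j]).statistic
    return pd.DataFrame(out, index=uniq, columns=uniq)
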
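"""Single-nucleus preprocessing core.

Operates on :class:`anndata.AnnData` objects holding sparse UMI counts
(cells x genes).  Normalization is log-CP10K with stored per-gene centering
and scaling so embeddings support out-of-sample projection; highly variable
genes use a binned standardized-dispersion statistic; graph clustering is
Leiden on a kNN graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Embedding",
    "qc_filter",
    "normalize_log",
    "select_hvgs",
    "pca_embed",
    "cluster_graph",
    "downsample_umis",
    "differential_expression",
    "subclass_proportions",
]


@dataclass
class Embedding:
    """A fitted linear embedding with out-of-sample projection support.

    ``loadings`` columns are orthonormal; ``gene_center``/``gene_scale``
    reproduce the standardization applied before the SVD.
    """

    scores: np.ndarray  # cells x D
    loadings: np.ndarray  # genes x D
    gene_center: np.ndarray
    gene_scale: np.ndarray
    explained_variance_ratio: np.ndarray | None = None

    @property
    def D(self) -> int:
        return self.loadings.shape[1]

    def project(self, X: np.ndarray | sp.spmatrix) -> np.ndarray:
        """Project new cells (same gene space) onto the fitted components."""
        X = _densify(X)
        return ((X - self.gene_center) / self.gene_scale) @ self.loadings


def _densify(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def _per_cell_stats(X) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(X):
        Xc = X.tocsr()
        genes = np.diff(Xc.indptr)
        umis = np.asarray(Xc.sum(axis=1)).ravel()
    else:
        genes = (X > 0).sum(axis=1)
        umis = X.sum(axis=1)
    return np.asarray(genes).ravel(), np.asarray(umis).ravel()


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 700,
    max_genes: int = 6500,
    max_umis: int = 40000,
    min_cells_per_gene: int = 9,
) -> ad.AnnData:
    """Cell then gene quality filtering of a raw count matrix.

    Keeps cells whose detected-gene count lies strictly between ``min_genes``
    and ``max_genes`` and whose UMI total is strictly below ``max_umis``;
    then keeps genes detected in at least ``min_cells_per_gene`` of the
    surviving cells (so genes seen in eight or fewer cells are dropped at the
    default).  An empty result is returned with a warning, not an error.
    """
    genes, umis = _per_cell_stats(adata.X)
    keep_cells = (genes > min_genes) & (genes < max_genes) & (umis < max_umis)
    out = adata[keep_cells].copy()
    if out.n_obs == 0:
        warnings.warn("qc_filter removed every cell")
        return out
    detected = np.asarray((out.X > 0).sum(axis=0)).ravel()
    out = out[:, detected >= min_cells_per_gene].copy()
    if out.n_vars == 0:
        warnings.warn("qc_filter removed every gene")
    return out


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log-CP10K: per cell ln(1 + count/total * scale); zero-total cells map
    to all-zero rows.  Returns a new AnnData with float X."""
    X = adata.X
    if sp.issparse(X):
        X = X.tocsr().astype(np.float64)
        totals = np.asarray(X.sum(axis=1)).ravel()
        inv = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
        X = sp.diags(inv) @ X
        X.data = np.log1p(X.data)
    else:
        X = np.asarray(X, dtype=np.float64)
        totals = X.sum(axis=1, keepdims=True)
        X = np.log1p(np.divide(X * scale, totals, out=np.zeros_like(X), where=totals > 0))
    out = ad.AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns = dict(adata.uns)
    return out


def select_hvgs(adata: ad.AnnData, n: int = 3000, n_bins: int = 20) -> pd.Index:
    """Top-``n`` highly variable genes by standardized dispersion.

    Dispersion = variance/mean of the (expm1 of) normalized expression;
    z-scored within ``n_bins`` equal-count bins of gene mean to remove the
    mean-variance trend.  Ties break deterministically by gene id.
    """
    if n > adata.n_vars:
        raise ValueError(f"n={n} exceeds gene count {adata.n_vars}")
    X = _densify(adata.X)
    expr = np.expm1(X)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros_like(mean)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    # equal-width bins over the gene-mean range
    lo, hi = mean.min(), mean.max()
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, lo + 1])
    which = np.clip(np.digitize(mean, edges[1:-1]), 0, len(edges) - 2)
    z = np.zeros_like(disp)
    for b in np.unique(which):
        idx = np.flatnonzero(which == b)
        mu, sd = disp[idx].mean(), disp[idx].std(ddof=0)
        z[idx] = (disp[idx] - mu) / sd if sd > 0 else 0.0
    ranking = pd.DataFrame({"z": z}, index=adata.var_names)
    ranking = ranking.sort_values(["z"], ascending=False, kind="stable")
    # deterministic tie-break by gene id within equal scores
    ranking = ranking.iloc[
        np.lexsort((ranking.index.to_numpy(), -ranking["z"].to_numpy()))
    ]
    return pd.Index(ranking.index[:n])


def pca_embed(
    adata: ad.AnnData,
    D: int = 30,
    balance_labels: pd.Series | np.ndarray | None = None,
    balance_to: int | None = None,
    scale_max: float = 10.0,
    seed: int = 0,
) -> Embedding:
    """PCA on standardized normalized expression, with optional
    label-balanced fitting.

    When ``balance_labels`` is given, the loadings (and the per-gene
    centering/scaling) are computed on a per-label random downsample of
    ``balance_to`` cells (default: size of the smallest label) and *all*
    cells are projected onto them.  Component signs are fixed so the largest
    absolute loading of each component is positive.
    """
    X = _densify(adata.X)
    if D > min(X.shape):
        raise ValueError(f"D={D} exceeds min(cells, genes)={min(X.shape)}")
    if balance_labels is not None:
        labels = np.asarray(balance_labels)
        if labels.shape[0] != X.shape[0]:
            raise ValueError("balance_labels length mismatch")
        rng = np.random.default_rng(seed)
        uniq, counts = np.unique(labels, return_counts=True)
        if (counts == 0).any():
            raise ValueError("label with zero cells")
        target = balance_to if balance_to is not None else int(counts.min())
        fit_idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(labels == u), size=min(target, c), replace=False)
                for u, c in zip(uniq, counts)
            ]
        )
        fit_idx.sort()
    else:
        fit_idx = np.arange(X.shape[0])

    Xfit = X[fit_idx]
    center = Xfit.mean(axis=0)
    scale = Xfit.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = np.clip((Xfit - center) / scale, -scale_max, scale_max)
    if min(Z.shape) <= 500:
        # exact SVD for small problems
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        Vt = Vt[:D]
        s = s[:D]
    else:
        from sklearn.utils.extmath import randomized_svd

        _, s, Vt = randomized_svd(
            Z, n_components=D, n_iter=7, random_state=int(seed) % (2**31)
        )
    # sign convention: largest-|loading| entry positive
    flip = np.sign(Vt[np.arange(D), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    loadings = (Vt * flip[:, None]).T
    ev = (s[:D] ** 2) / (Z.shape[0] * Z.var(axis=0).sum() + 1e-300)
    emb = Embedding(
        scores=np.empty((0, D)),
        loadings=loadings,
        gene_center=center,
        gene_scale=scale,
        explained_variance_ratio=ev,
    )
    emb.scores = np.clip((X - center) / scale, -scale_max, scale_max) @ loadings
    return emb


def cluster_graph(
    emb: Embedding, k_neighbors: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community labels on the kNN graph of embedding scores."""
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    X = emb.scores
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def downsample_umis(
    adata: ad.AnnData, donor_totals: np.ndarray, seed: int = 0
) -> ad.AnnData:
    """Multinomial depth matching against an empirical UMI-total distribution.

    For each cell a target total ``t`` is drawn from ``donor_totals``; cells
    at or below their target are unchanged, otherwise ``t`` molecules are
    drawn without replacement from the cell's pool (multivariate
    hypergeometric), so the resulting total is exactly ``min(t, original)``,
    no entry ever increases, and the expected counts are the original
    fractions times ``t``.
    """
    donor_totals = np.asarray(donor_totals)
    if donor_totals.size == 0:
        raise ValueError("donor_totals is empty")
    if (donor_totals < 0).any():
        raise ValueError("negative donor totals")
    rng = np.random.default_rng(seed)
    X = adata.X.tocsr().copy() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    X = X.astype(np.int64)
    targets = rng.choice(donor_totals, size=adata.n_obs, replace=True)
    for i in range(adata.n_obs):
        row = X.data[X.indptr[i] : X.indptr[i + 1]]
        total = row.sum()
        t = int(targets[i])
        if t >= total or total == 0:
            continue
        new = rng.multivariate_hypergeometric(row, t)
        X.data[X.indptr[i] : X.indptr[i + 1]] = new
    X.eliminate_zeros()
    out = ad.AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns = dict(adata.uns)
    return out


def differential_expression(
    norm: ad.AnnData,
    raw: ad.AnnData,
    group_a: np.ndarray,
    group_b: np.ndarray,
    lfc_min: float = 0.75,
    pct_min: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum differential expression between two cell groups.

    ``group_a``/``group_b`` are disjoint boolean masks or index arrays over
    cells.  Per gene: two-sided Mann-Whitney P on log-normalized expression,
    log2FC = log2((mean_A + 1)/(mean_B + 1)) of the depth-normalized counts
    (``expm1`` of the log-normalized values, the usual fold-change scale),
    and pct1 = detection fraction (raw count > 0) in group A.  The returned table
    keeps genes with log2FC > ``lfc_min``, pct1 > ``pct_min`` and raw
    P < ``alpha``, sorted by descending log2FC; a Benjamini-Hochberg column is
    included but not used for filtering.
    """
    a = _as_index(group_a, norm.n_obs)
    b = _as_index(group_b, norm.n_obs)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap")
    Xn = _densify(norm.X)
    Xa, Xb = Xn[a], Xn[b]
    raw_a = raw.X[a] if not sp.issparse(raw.X) else raw.X.tocsr()[a]
    nonconst = ~np.all(np.concatenate([Xa, Xb]) == np.concatenate([Xa, Xb])[0], axis=0)
    p = np.ones(norm.n_vars)
    if nonconst.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_nc = mannwhitneyu(
                Xa[:, nonconst], Xb[:, nonconst], alternative="two-sided", axis=0
            )
        p[nonconst] = p_nc
    lfc = np.log2(
        (np.expm1(Xa).mean(axis=0) + 1) / (np.expm1(Xb).mean(axis=0) + 1)
    )
    pct1 = np.asarray((raw_a > 0).mean(axis=0)).ravel()
    raw_b = raw.X[b] if not sp.issparse(raw.X) else raw.X.tocsr()[b]
    pct2 = np.asarray((raw_b > 0).mean(axis=0)).ravel()
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"gene": norm.var_names, "log2FC": lfc, "pct1": pct1, "pct2": pct2,
         "p": p, "p_adj": p_adj}
    )
    table = table[(table.log2FC > lfc_min) & (table.pct1 > pct_min) & (table.p < alpha)]
    return table.sort_values("log2FC", ascending=False).reset_index(drop=True)


def _as_index(g, n: int) -> np.ndarray:
    g = np.asarray(g)
    if g.dtype == bool:
        if g.shape[0] != n:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(g)
    return g.astype(int)


def subclass_proportions(
    cells: pd.DataFrame,
    level: str = "subclass",
    within: str | None = None,
    sample_col: str = "sample",
    class_col: str = "cell_class",
) -> pd.DataFrame:
    """Per-replicate label fractions.

    Returns a samples x labels table of fractions of each ``level`` label
    among the denominator population — all cells, or only cells of class
    ``within``.  Rows sum to 1.
    """
    if level not in cells.columns:
        raise ValueError(f"column {level!r} missing from cell table")
    df = cells
    if within is not None:
        df = df[df[class_col].astype(str) == within]
    if len(df) == 0:
        raise ValueError("empty denominator population")
    counts = (
        df.groupby([sample_col, level], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    return counts.div(counts.sum(axis=1), axis=0)
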
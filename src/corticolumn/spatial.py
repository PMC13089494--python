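"""Spatial-column construction and laminar statistics.

A :class:`SpatialColumn` pools QC-passed cells from one or more cortical
ROIs rescaled to a common width and height; depth is micrometres from the
pial surface and ``subpial_frac = depth / height`` spans the column from the
top of layer 2/3 (0) to the bottom of layer 6 (1).  Laminar statistics
include boundary-reflected kernel density profiles, a binned Gini index of
laminar confinement, below/above-median density ratios, and depth-axis
partial Spearman correlations with permutation significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .crossspecies import integrate_embed

__all__ = [
    "SpatialColumn",
    "stereo_qc",
    "build_pseudocolumn",
    "assign_labels_multiround",
    "subpial_density_profile",
    "gini_subpial",
    "density_ratio_below_above",
    "depth_axis_partial_correlation",
]


@dataclass
class SpatialColumn:
    """Pooled cortical-column cells with subpial depth coordinates."""

    cells: pd.DataFrame  # columns x_um, depth_um, optionally labels
    width_um: float
    height_um: float
    counts: ad.AnnData | None = None  # expression of the same cells, same order

    def __post_init__(self) -> None:
        f = self.subpial_frac
        if len(f) and ((f < -1e-9).any() or (f > 1 + 1e-9).any()):
            raise ValueError("depth outside [0, height]")

    @property
    def subpial_frac(self) -> np.ndarray:
        if self.height_um <= 0:
            return np.zeros(len(self.cells))
        return self.cells["depth_um"].to_numpy() / self.height_um


def stereo_qc(
    adata: ad.AnnData,
    min_genes: int = 50,
    min_umis: int = 100,
    units_per_um: float = 2.0,
    coord_cols: tuple[str, str] = ("x_units", "y_units"),
) -> ad.AnnData:
    """Spatial cell-bin QC and unit conversion.

    Keeps cells with at least ``min_genes`` detected genes and at least
    ``min_umis`` UMIs (cells with fewer are removed), then converts platform
    coordinates to micrometres (``units_per_um`` chip units per um) into
    ``x_um``/``depth_um`` columns.
    """
    if units_per_um <= 0:
        raise ValueError("units_per_um must be positive")
    X = adata.X
    import scipy.sparse as sp

    if sp.issparse(X):
        genes = np.asarray((X > 0).sum(axis=1)).ravel()
        umis = np.asarray(X.sum(axis=1)).ravel()
    else:
        genes = (X > 0).sum(axis=1)
        umis = X.sum(axis=1)
    keep = (genes >= min_genes) & (umis >= min_umis)
    out = adata[keep].copy()
    cx, cy = coord_cols
    if cx in out.obs:
        out.obs["x_um"] = out.obs[cx].astype(float) / units_per_um
        out.obs["depth_um"] = out.obs[cy].astype(float) / units_per_um
    return out


def build_pseudocolumn(rois: list[SpatialColumn]) -> SpatialColumn:
    """Pool ROIs into one pseudocolumn scaled to the largest ROI.

    The ROI of largest area defines the target width and height; every ROI's
    x and depth coordinates are scaled by the corresponding ratios and the
    cells pooled.  Expression (``counts``) is concatenated when present on
    all ROIs.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    areas = [r.width_um * r.height_um for r in rois]
    if any(a <= 0 for a in areas):
        raise ValueError("zero-extent ROI")
    target = rois[int(np.argmax(areas))]
    Wt, Ht = target.width_um, target.height_um
    frames = []
    for r in rois:
        df = r.cells.copy()
        df["x_um"] = df["x_um"] * (Wt / r.width_um)
        df["depth_um"] = df["depth_um"] * (Ht / r.height_um)
        frames.append(df)
    cells = pd.concat(frames, axis=0)
    counts = None
    if all(r.counts is not None for r in rois):
        counts = ad.concat([r.counts for r in rois], join="inner", merge="first")
    return SpatialColumn(cells=cells, width_um=Wt, height_um=Ht, counts=counts)


def assign_labels_multiround(
    query_norm: ad.AnnData,
    reference_norm: ad.AnnData,
    ref_labels: np.ndarray | pd.Series,
    thresholds: tuple[float, ...] = (1.0, 1.0, 0.75),
    k: int = 50,
    D: int = 30,
    seed: int = 0,
    return_audit: bool = False,
):
    """Multi-round kNN label assignment of spatial cells from a dissociated
    reference.

    Each round integrates the currently unassigned query cells with the
    reference (round 1 downsamples the reference to the query count; later
    rounds use the full reference), takes each query cell's ``k`` nearest
    reference neighbors in the joint embedding, and assigns the plurality
    label when its fraction meets the round's threshold.  Ties for plurality
    leave the cell unassigned that round; assigned cells are removed before
    the next round; cells failing every round are returned as unassigned.
    With ``return_audit`` the per-round unassigned counts are appended to
    the return value.
    """
    if any(b > a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be non-increasing")
    labels = np.asarray(ref_labels).astype(str)
    rng = np.random.default_rng(seed)
    assigned = pd.Series(index=query_norm.obs_names, dtype=object)
    unassigned = np.arange(query_norm.n_obs)
    audit: list[int] = []
    for rnd, thr in enumerate(thresholds):
        if unassigned.size == 0:
            break
        if rnd == 0 and reference_norm.n_obs > unassigned.size:
            ref_idx = np.sort(
                rng.choice(reference_norm.n_obs, size=unassigned.size, replace=False)
            )
        else:
            ref_idx = np.arange(reference_norm.n_obs)
        if k > ref_idx.size:
            raise ValueError(f"k={k} exceeds reference size {ref_idx.size}")
        ref_part = reference_norm[ref_idx]
        q_part = query_norm[unassigned]
        emb, tags = integrate_embed(
            [ref_part.copy(), q_part.copy()], D=D, seed=seed + rnd
        )
        ref_scores = emb.scores[tags == 0]
        q_scores = emb.scores[tags == 1]
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k).fit(ref_scores)
        _, idx = nn.kneighbors(q_scores)
        neigh = labels[ref_idx][idx]  # q x k
        newly = []
        for i in range(neigh.shape[0]):
            vals, counts = np.unique(neigh[i], return_counts=True)
            top = counts.max()
            if (counts == top).sum() > 1:
                continue  # plurality tie
            if top / k >= thr:
                assigned.iloc[unassigned[i]] = vals[np.argmax(counts)]
                newly.append(i)
        unassigned = np.delete(unassigned, newly)
        audit.append(unassigned.size)
    if return_audit:
        return assigned, query_norm.obs_names[unassigned], audit
    return assigned, query_norm.obs_names[unassigned]


def subpial_density_profile(
    col: SpatialColumn,
    label: str | None = None,
    bandwidth_frac: float = 0.05,
    grid: int = 201,
    label_col: str = "subclass",
) -> pd.DataFrame:
    """Boundary-reflected Gaussian kernel density of subpial position.

    Evaluated on a regular grid over [0, 1]; reflection at both boundaries
    makes the profile integrate to 1 over the column.
    """
    f = col.subpial_frac
    if label is not None:
        f = f[col.cells[label_col].astype(str).to_numpy() == label]
    if f.size < 2:
        raise ValueError("need at least 2 cells for a density profile")
    xs = np.linspace(0.0, 1.0, grid)
    h = bandwidth_frac

    def _k(x):
        z = (x[:, None] - f[None, :]) / h
        return np.exp(-0.5 * z * z).sum(axis=1) / (f.size * h * np.sqrt(2 * np.pi))

    dens = _k(xs) + _k(-xs) + _k(2.0 - xs)
    return pd.DataFrame({"subpial_frac": xs, "density": dens})


def gini_subpial(
    col: SpatialColumn, label: str | None = None, n_bins: int = 20,
    label_col: str = "subclass",
) -> float:
    """Gini index of laminar confinement over equal-width subpial bins.

    ``G = sum_ij |c_i - c_j| / (2 B sum_b c_b)``; 0 for a uniform laminar
    spread, (B-1)/B when the whole population sits in a single bin.
    """
    f = col.subpial_frac
    if label is not None:
        f = f[col.cells[label_col].astype(str).to_numpy() == label]
    if f.size == 0:
        raise ValueError("no cells of requested label")
    counts, _ = np.histogram(f, bins=n_bins, range=(0.0, 1.0))
    c = counts.astype(float)
    return float(np.abs(c[:, None] - c[None, :]).sum() / (2.0 * n_bins * c.sum()))


def density_ratio_below_above(
    col: SpatialColumn, target_label: str, reference_label: str,
    label_col: str = "subclass",
) -> float:
    """Extent-normalized density ratio of a target population below vs.
    above the median subpial depth of a reference population."""
    lab = col.cells[label_col].astype(str).to_numpy()
    f = col.subpial_frac
    tgt = f[lab == target_label]
    ref = f[lab == reference_label]
    if tgt.size == 0 or ref.size == 0:
        raise ValueError("both labels must be present")
    split = float(np.median(ref))
    if split <= 0.0 or split >= 1.0:
        raise ValueError("degenerate split depth")
    below = (tgt > split).sum() / (1.0 - split)
    above = (tgt <= split).sum() / split
    return float(below / above) if above > 0 else np.inf


def depth_axis_partial_correlation(
    depth: np.ndarray,
    dist_b: np.ndarray,
    dist_c: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Partial Spearman correlations of depth with distance to each of two
    polytope vertices, each controlling for the other, with permutation
    significance.

    All three variables are rank-transformed; the partial correlation on
    ranks is ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``.  The
    null permutes depth only, keeping the (dist_b, dist_c) pairing intact;
    two-sided ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``.
    """
    depth = np.asarray(depth, dtype=float)
    db = np.asarray(dist_b, dtype=float)
    dc = np.asarray(dist_c, dtype=float)
    n = depth.size
    if n < 10 or db.size != n or dc.size != n:
        raise ValueError("need equal-length inputs with n >= 10")
    for v in (depth, db, dc):
        if np.ptp(v) == 0:
            raise ValueError("constant variable: correlation undefined")
    rd = _std_ranks(depth)
    rb = _std_ranks(db)
    rc = _std_ranks(dc)
    r_bc = float(rb @ rc / n)

    def _partials(x: np.ndarray) -> tuple[float, float]:
        r_xb = float(x @ rb / n)
        r_xc = float(x @ rc / n)
        den_b = max(np.sqrt(max((1 - r_xc**2) * (1 - r_bc**2), 0.0)), 1e-12)
        den_c = max(np.sqrt(max((1 - r_xb**2) * (1 - r_bc**2), 0.0)), 1e-12)
        pb = np.clip((r_xb - r_xc * r_bc) / den_b, -1.0, 1.0)
        pc = np.clip((r_xc - r_xb * r_bc) / den_c, -1.0, 1.0)
        return pb, pc

    rho_b, rho_c = _partials(rd)
    rng = np.random.default_rng(seed)
    hits_b = hits_c = 0
    for _ in range(n_perm):
        pb, pc = _partials(rd[rng.permutation(n)])
        hits_b += abs(pb) >= abs(rho_b)
        hits_c += abs(pc) >= abs(rho_c)
    return {
        "rho_b_given_c": float(rho_b),
        "rho_c_given_b": float(rho_c),
        "p_b": (1 + hits_b) / (1 + n_perm),
        "p_c": (1 + hits_c) / (1 + n_perm),
    }


def _std_ranks(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    r = r - r.mean()
    return r / np.sqrt((r**2).mean())
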
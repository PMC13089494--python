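"""Principal convex hull (archetypal) analysis and polytope geometry.

Fits a K-vertex polytope to an embedded cell cloud by minimizing
``||X^T - X^T C S||_F^2`` where the columns of C (cells x K) lie on the unit
simplex — optionally relaxed so each column sum may range over
``[1 - delta, 1 + delta]`` — and the columns of S (K x cells) lie on the unit
simplex.  Archetypes are the convex (or delta-relaxed) combinations
``X^T C`` of observed cells; each cell is approximated by a mixture of
archetypes given by its S column.  Optimization is alternating projected
gradient descent with per-block adaptive step sizes and furthest-sum
initialization; the sum of squared errors is guaranteed non-increasing.

Vertex-count selection uses an explained-variance elbow: the candidate whose
(K, EV) point is furthest from the chord joining the first and last
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "Polytope",
    "pcha_fit",
    "select_vertex_count",
    "vertex_geometry",
    "continuum_shuffle_test",
]


@dataclass
class Polytope:
    """Fitted principal convex hull.

    ``archetypes`` are in the original (uncentered) coordinates of the data
    the fit was run on; ``S`` columns are the per-cell mixture weights and sum
    to 1; ``ev = 1 - sse/tss`` with tss the total squared deviation from the
    data mean.
    """

    K: int
    archetypes: np.ndarray  # K x D
    S: np.ndarray  # K x cells
    C: np.ndarray  # cells x K
    delta: float
    sse: float
    ev: float
    center: np.ndarray
    sse_history: list = field(default_factory=list)


def _furthest_sum(Xt: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum seeding: greedily pick points maximizing summed distance
    to the already-picked set, replacing the random initial pick at the end."""
    N = Xt.shape[1]
    first = int(rng.integers(N))
    picked = [first]
    sumdist = np.zeros(N)
    for _ in range(K):
        d = np.linalg.norm(Xt - Xt[:, picked[-1]][:, None], axis=0)
        sumdist += d
        if len(picked) == K + 1:
            break
        sumdist_masked = sumdist.copy()
        sumdist_masked[picked] = -np.inf
        picked.append(int(np.argmax(sumdist_masked)))
    # drop the random seed point, keep K greedy picks
    return np.array(picked[1:][:K] if len(picked) > K else picked[:K])


def _sse(Xt: np.ndarray, XC: np.ndarray, S: np.ndarray) -> float:
    # direct D x N residual; cheap because the embedding dimension D is small
    R = Xt - XC @ S
    return float((R * R).sum())


def pcha_fit(
    X: np.ndarray,
    noc: int,
    delta: float = 0.0,
    max_iter: int = 250,
    tol: float = 3e-6,
    seed: int = 0,
) -> Polytope:
    """Fit a ``noc``-vertex principal convex hull to ``X`` (cells x D).

    The data are centered internally (the center is recorded and added back
    to the reported archetypes).  ``delta`` relaxes the archetype-defining
    combinations so the polytope may inflate slightly beyond the data hull.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    N, D = X.shape
    if noc < 1 or noc > N:
        raise ValueError(f"noc={noc} out of range for {N} cells")
    rng = np.random.default_rng(seed)
    center = X.mean(axis=0)
    Xt = (X - center).T  # D x N
    SST = float((Xt**2).sum())
    if SST == 0.0:
        S = np.full((noc, N), 1.0 / noc)
        C = np.zeros((N, noc))
        C[: min(N, noc), np.arange(min(N, noc))] = 1.0
        return Polytope(noc, np.tile(center, (noc, 1)), S, C, delta, 0.0, 1.0, center, [0.0])

    idx = _furthest_sum(Xt, noc, rng)
    C = np.zeros((N, noc))
    C[idx, np.arange(noc)] = 1.0
    S = -np.log(rng.random((noc, N)))
    S /= S.sum(axis=0, keepdims=True)

    XC = Xt @ C  # D x K
    sse = _sse(Xt, XC, S)
    history = [sse]
    muS, muC = 1.0, 1.0
    nrm = SST / N

    for it in range(max_iter):
        sse_prev = sse
        # ---- S update (simplex columns) ----
        for _ in range(10):
            g = (XC.T @ (XC @ S) - XC.T @ Xt) / nrm
            g -= (g * S).sum(axis=0, keepdims=True)
            improved = False
            for _ in range(12):
                S_new = np.maximum(S - muS * g, 0.0)
                tot = S_new.sum(axis=0, keepdims=True)
                tot[tot == 0] = 1.0
                S_new = S_new / tot
                sse_new = _sse(Xt, XC, S_new)
                if sse_new <= sse * (1 + 1e-12):
                    S, sse = S_new, sse_new
                    muS *= 1.2
                    improved = True
                    break
                muS /= 2.0
            if not improved:
                break
        # ---- C update (delta-relaxed simplex columns) ----
        SSt = S @ S.T
        XSt = Xt @ S.T  # D x K
        for _ in range(10):
            gC = (Xt.T @ (XC @ SSt - XSt)) / nrm  # N x K
            colsum = C.sum(axis=0, keepdims=True)
            gC -= (gC * C).sum(axis=0, keepdims=True) / np.maximum(colsum, 1e-12)
            improved = False
            for _ in range(12):
                C_new = np.maximum(C - muC * gC, 0.0)
                tot = C_new.sum(axis=0, keepdims=True)
                tot[tot == 0] = 1.0
                if delta > 0:
                    scale = np.clip(tot, 1.0 - delta, 1.0 + delta)
                else:
                    scale = 1.0
                C_new = C_new / tot * scale
                XC_new = Xt @ C_new
                sse_new = _sse(Xt, XC_new, S)
                if sse_new <= sse * (1 + 1e-12):
                    C, XC, sse = C_new, XC_new, sse_new
                    muC *= 1.2
                    improved = True
                    break
                muC /= 2.0
            if not improved:
                break
        history.append(sse)
        if sse_prev - sse < tol * sse_prev:
            break

    ev = 1.0 - sse / SST
    archetypes = XC.T + center
    return Polytope(noc, archetypes, S, C, delta, sse, ev, center, history)


def select_vertex_count(
    X: np.ndarray,
    candidates=range(2, 11),
    delta: float = 0.0,
    n_restarts: int = 5,
    seed: int = 0,
    return_profile: bool = False,
):
    """Automated elbow selection of the vertex count.

    Fits the best-of-``n_restarts`` polytope for each candidate K, then picks
    the K whose (K, EV) point lies furthest (perpendicular distance) from the
    chord joining the first and last candidate points; ties go to the
    smallest K.
    """
    candidates = list(candidates)
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate vertex counts for an elbow")
    rng = np.random.default_rng(seed)
    evs = []
    for K in candidates:
        best = -np.inf
        for _ in range(n_restarts):
            fit = pcha_fit(X, K, delta=delta, seed=int(rng.integers(2**31)))
            best = max(best, fit.ev)
        evs.append(best)
    k_star = _elbow(np.asarray(candidates, dtype=float), np.asarray(evs))
    if return_profile:
        return int(k_star), dict(zip(candidates, evs))
    return int(k_star)


def _elbow(ks: np.ndarray, evs: np.ndarray) -> int:
    p0 = np.array([ks[0], evs[0]])
    p1 = np.array([ks[-1], evs[-1]])
    chord = p1 - p0
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        return int(ks[1])
    pts = np.stack([ks, evs], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / nrm
    # endpoints (distance 0 by construction) are excluded; near-ties (e.g. a
    # linear profile, all distances ~0) resolve to the smallest K
    interior = np.arange(1, len(ks) - 1)
    d = dist[interior]
    best = d.max()
    return int(ks[interior[np.flatnonzero(d >= best - 1e-12)[0]]])


def vertex_geometry(
    X: np.ndarray, p: Polytope, plane: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-cell Euclidean distance to each archetype, plus barycentric
    weights for triangle fits.

    For ``K = 3`` and a component ``plane`` (pair of column indices),
    barycentric coordinates are computed in that plane, clamped to [0, 1] and
    renormalized for cells outside the triangle.
    """
    X = np.asarray(X, dtype=np.float64)
    dists = np.linalg.norm(X[:, None, :] - p.archetypes[None, :, :], axis=2)
    bary = None
    if plane is not None:
        if p.K != 3:
            raise ValueError("barycentric plane requires a 3-vertex polytope")
        i, j = plane
        tri = p.archetypes[:, [i, j]]  # 3 x 2
        T = np.stack([tri[0] - tri[2], tri[1] - tri[2]], axis=1)  # 2 x 2
        det = np.linalg.det(T)
        if abs(det) < 1e-12:
            raise ValueError("degenerate triangle in requested plane")
        rel = X[:, [i, j]] - tri[2]
        lam12 = rel @ np.linalg.inv(T).T
        bary = np.column_stack([lam12, 1.0 - lam12.sum(axis=1)])
        bary = np.clip(bary, 0.0, 1.0)
        bary /= bary.sum(axis=1, keepdims=True)
    return dists, bary


def continuum_shuffle_test(
    X: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Continuum-vs-gap test for two putative subclasses.

    Projects cells onto the unit axis joining the two subclass centroids and
    measures ``T`` = (kernel-density minimum between the two subclass median
    projections) / (smaller of the densities at the two medians):  T near 1
    indicates a continuum, near 0 a density gap.  The null shuffles each
    gene's values independently *within* each subclass (destroying inter-gene
    covariance while preserving per-subclass marginals) and recomputes T;
    ``p = (1 + #{T_null >= T_obs}) / (1 + n_shuffles)`` tests against the
    noisy-discrete alternative.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    a, b = pair
    ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
    if ia.size < 10 or ib.size < 10:
        raise ValueError("each subclass needs at least 10 cells")
    rng = np.random.default_rng(seed)

    def _T(M: np.ndarray) -> float:
        ca, cb = M[ia].mean(axis=0), M[ib].mean(axis=0)
        u = cb - ca
        nu = np.linalg.norm(u)
        if nu == 0:
            return 1.0
        u /= nu
        proj = M[np.concatenate([ia, ib])] @ u
        ma = np.median(M[ia] @ u)
        mb = np.median(M[ib] @ u)
        lo, hi = min(ma, mb), max(ma, mb)
        kde = gaussian_kde(proj)
        grid = np.linspace(lo, hi, 101)
        valley = kde(grid).min()
        ref = min(kde([ma])[0], kde([mb])[0])
        return float(valley / ref) if ref > 0 else 1.0

    t_obs = _T(X)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        M = X.copy()
        for idx in (ia, ib):
            for gcol in range(M.shape[1]):
                M[idx, gcol] = M[rng.permutation(idx), gcol]
        null[s] = _T(M)
    pval = (1 + int((null >= t_obs).sum())) / (1 + n_shuffles)
    return t_obs, null, pval
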
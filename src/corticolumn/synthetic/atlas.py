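"""Synthetic single-nucleus atlas generator.

Cells belong to glutamatergic / GABAergic / non-neuronal classes.  IT
(intratelencephalic) glutamatergic cells draw a latent expression vector that
is a convex mixture of ``it_archetypes`` archetype programs plus Gaussian
noise; every other subclass is a discrete cluster with its own marker-gene
block.  UMI counts are negative-binomial with a log-normal per-cell library
size, which is how the two species' sequencing-depth difference enters.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import GeneratorConfig, SyntheticTruth

__all__ = ["generate_atlas"]

_BASELINE_LATENT = 0.6  # softplus(0.6) ~ 1.03: background expression level
_SIGNATURE_LATENT = 3.0  # latent boost of a signature/marker gene


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _GenePanel:
    """Deterministic layout of archetype signatures and subclass markers."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        n = cfg.n_genes
        self.gene_ids = np.array([f"g{i:05d}" for i in range(n)])
        self.signature = np.full(n, "background", dtype=object)
        discrete = self._discrete_subclasses(cfg)
        n_blocks = cfg.it_archetypes + len(discrete)
        block = max(4, min(n // (n_blocks + 2), 40))
        pos = 0
        self.archetype_blocks: list[np.ndarray] = []
        for k in range(cfg.it_archetypes):
            idx = np.arange(pos, pos + block)
            self.archetype_blocks.append(idx)
            self.signature[idx] = f"archetype_{k}"
            pos += block
        self.marker_blocks: dict[str, np.ndarray] = {}
        for name in discrete:
            idx = np.arange(pos, pos + block)
            self.marker_blocks[name] = idx
            self.signature[idx] = name
            pos += block
        if pos > n:
            raise ValueError(
                f"n_genes={n} too small for {n_blocks} signature blocks"
            )
        # gene-level baseline variation, shared by all cells
        self.baseline = _BASELINE_LATENT + 0.5 * rng.standard_normal(n)
        # archetype programs: baseline plus signature block boost
        K = cfg.it_archetypes
        self.archetype_programs = np.tile(self.baseline, (K, 1))
        for k, idx in enumerate(self.archetype_blocks):
            self.archetype_programs[k, idx] += _SIGNATURE_LATENT

    @staticmethod
    def _discrete_subclasses(cfg: GeneratorConfig) -> list[str]:
        names: list[str] = []
        if cfg.class_proportions.get("glutamatergic", 0) > 0 and cfg.glut_it_fraction < 1:
            names += list(cfg.non_it_glut_proportions)
        if cfg.class_proportions.get("gabaergic", 0) > 0:
            names += list(cfg.gabaergic_proportions)
        if cfg.class_proportions.get("nonneuronal", 0) > 0:
            names += list(cfg.nonneuronal_proportions)
        return names


def _draw_composition(cfg: GeneratorConfig, rng: np.random.Generator):
    """Per-cell (class, subclass) labels drawn from the configured simplices.

    IT cells get a placeholder subclass; their final label is the argmax
    archetype, assigned after weights are drawn.
    """
    classes = np.array(list(cfg.class_proportions))
    p_class = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
    cell_class = rng.choice(classes, size=cfg.n_cells, p=p_class)
    subclass = np.empty(cfg.n_cells, dtype=object)
    is_it = np.zeros(cfg.n_cells, dtype=bool)
    for cls, table in [
        ("gabaergic", cfg.gabaergic_proportions),
        ("nonneuronal", cfg.nonneuronal_proportions),
    ]:
        m = cell_class == cls
        if m.any():
            names = np.array(list(table))
            p = np.array([table[n] for n in names], dtype=float)
            subclass[m] = rng.choice(names, size=int(m.sum()), p=p)
    m = cell_class == "glutamatergic"
    if m.any():
        it_draw = rng.random(int(m.sum())) < cfg.glut_it_fraction
        is_it[np.flatnonzero(m)[it_draw]] = True
        non_it = np.flatnonzero(m)[~it_draw]
        if non_it.size:
            names = np.array(list(cfg.non_it_glut_proportions))
            p = np.array([cfg.non_it_glut_proportions[n] for n in names], dtype=float)
            subclass[non_it] = rng.choice(names, size=non_it.size, p=p)
    return cell_class, subclass, is_it


def _latent_matrix(
    cfg: GeneratorConfig,
    panel: _GenePanel,
    subclass: np.ndarray,
    is_it: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    latent = np.tile(panel.baseline, (cfg.n_cells, 1))
    if is_it.any():
        latent[is_it] = weights[is_it] @ panel.archetype_programs
    for name, idx in panel.marker_blocks.items():
        m = subclass == name
        if m.any():
            latent[np.ix_(m, idx)] += _SIGNATURE_LATENT
    if noise_sd > 0:
        latent += noise_sd * rng.standard_normal(latent.shape)
    return latent


def _nb_counts(
    latent: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> sp.csr_matrix:
    """Negative-binomial sampling: rates = softplus(latent) normalized per
    cell, library sizes log-normal, gamma-Poisson mixture with shared shape."""
    rates = _softplus(latent)
    rates /= rates.sum(axis=1, keepdims=True)
    lib = rng.lognormal(cfg.mean_log_umis, cfg.sd_log_umis, size=latent.shape[0])
    mu = rates * lib[:, None]
    lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
    counts = rng.poisson(lam)
    return sp.csr_matrix(counts.astype(np.int64))


def generate_atlas(
    config: GeneratorConfig, *, sample_counts: bool = True, keep_latent: bool = False
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a synthetic snRNA-seq atlas.

    Returns an :class:`~anndata.AnnData` whose ``X`` holds sparse integer UMI
    counts, whose ``obs`` is the cell table (sample, species, class, subclass)
    and whose ``var`` records each gene's generative signature, together with
    a :class:`SyntheticTruth`.  With ``sample_counts=False`` the
    negative-binomial step is skipped and ``X`` holds the noise-free latent
    expression directly (used to check the simplex geometry of IT cells).
    Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    panel = _GenePanel(config, rng)
    cell_class, subclass, is_it = _draw_composition(config, rng)

    K = config.it_archetypes
    weights = np.zeros((config.n_cells, K))
    if is_it.any():
        alpha = np.asarray(config.archetype_concentration, dtype=float)
        weights[is_it] = rng.dirichlet(alpha, size=int(is_it.sum()))
        it_names = np.asarray(config.it_subclass_names, dtype=object)
        subclass[is_it] = it_names[np.argmax(weights[is_it], axis=1)]

    latent = _latent_matrix(
        config, panel, subclass, is_it, weights, rng, config.noise_sd
    )
    if sample_counts:
        X: sp.spmatrix | np.ndarray = _nb_counts(latent, config, rng)
    else:
        X = latent.copy()

    obs = pd.DataFrame(
        {
            "sample": [
                f"{config.species_preset}_rep{i + 1}"
                for i in rng.integers(0, config.n_samples, size=config.n_cells)
            ],
            "species": config.species_preset,
            "cell_class": pd.Categorical(cell_class),
            "subclass": pd.Categorical(subclass.astype(str)),
            "is_it": is_it,
        },
        index=pd.Index(
            [f"{config.species_preset}_c{i:06d}" for i in range(config.n_cells)],
            name="cell_id",
        ),
    )
    var = pd.DataFrame(
        {"signature": panel.signature},
        index=pd.Index(panel.gene_ids, name="gene_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["generator"] = {"seed": config.seed, "species": config.species_preset}
    if keep_latent:
        adata.layers["latent"] = latent

    proportions = _generative_proportions(config)
    truth = SyntheticTruth(
        subclass=subclass.astype(str),
        cell_class=cell_class.astype(str),
        archetype_weights=weights,
        depth_um=None,
        proportions=proportions,
        pnn_mode=config.pnn_mode,
    )
    return adata, truth


def _generative_proportions(cfg: GeneratorConfig) -> dict[str, float]:
    out: dict[str, float] = {}
    p_glut = cfg.class_proportions.get("glutamatergic", 0.0)
    for n, p in cfg.non_it_glut_proportions.items():
        out[n] = p_glut * (1 - cfg.glut_it_fraction) * p
    for n, p in cfg.gabaergic_proportions.items():
        out[n] = cfg.class_proportions.get("gabaergic", 0.0) * p
    for n, p in cfg.nonneuronal_proportions.items():
        out[n] = cfg.class_proportions.get("nonneuronal", 0.0) * p
    # IT subclasses split p_glut * it_fraction by the Dirichlet argmax measure,
    # symmetric only for symmetric concentrations; recorded as the total.
    out["IT_total"] = p_glut * cfg.glut_it_fraction
    return out
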
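"""Synthetic spatial-transcriptomics column generator.

Cells carry (x, depth) coordinates inside a cortical column spanning the top
of layer 2/3 to the bottom of layer 6.  Each subclass draws depth from its
configured truncated-normal law; IT cells' archetype mixture weights covary
with depth through a Gaussian kernel over the archetypes' home-layer depths,
so the transcriptomic continuum is spatially graded.  Counts reuse the
negative-binomial machinery of the atlas generator (spatial platforms are
shallower; see ``spatial_depth_factor``).
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from .atlas import _GenePanel, _draw_composition, _latent_matrix, _nb_counts
from .config import ARCHETYPE_DEPTHS_UM, GeneratorConfig, SyntheticTruth

__all__ = ["generate_spatial"]

# Stereo-seq cell bins capture far fewer molecules than nuclei libraries.
SPATIAL_DEPTH_FACTOR = 0.15
# Bandwidth (um) of the depth -> archetype-weight kernel.
DEPTH_KERNEL_BW_UM = 160.0
# Concentration of the Dirichlet jitter around the kernel mean.
WEIGHT_JITTER_KAPPA = 25.0


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal (laws are comfortably inside the
    column, so acceptance is high)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_spatial(
    config: GeneratorConfig, *, sample_counts: bool = True
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a synthetic spatial column.

    Returns an AnnData whose ``obs`` carries ``x_um`` and ``depth_um``
    (micrometres from the pial surface, increasing downward) alongside the
    usual cell table, and the ground truth.  Zero requested cells yield an
    empty column without error.
    """
    rng = np.random.default_rng(config.seed + 7919)
    panel = _GenePanel(config, rng)
    cell_class, subclass, is_it = _draw_composition(config, rng)
    n = config.n_cells
    H, W = config.column_height_um, config.column_width_um

    # subclass first, then depth from its law
    depth = np.empty(n)
    x = rng.uniform(0.0, W, size=n)
    K = config.it_archetypes
    weights = np.zeros((n, K))
    arch_depths = np.asarray(ARCHETYPE_DEPTHS_UM[:K])

    if is_it.any():
        # IT cells: pick subclass by archetype share, then depth, then weights
        it_idx = np.flatnonzero(is_it)
        home = rng.integers(0, K, size=it_idx.size)
        it_names = np.asarray(config.it_subclass_names, dtype=object)
        subclass[it_idx] = it_names[home]
    for name in pd.unique(pd.Series(subclass.astype(object))):
        if name is None:
            continue
        m = subclass == name
        if not m.any():
            continue
        if str(name) not in config.depth_law:
            raise KeyError(f"depth law missing for subclass {name!r}")
        mu, sd = config.depth_law[str(name)]
        depth[m] = _truncnorm(rng, mu, sd, 0.0, H, int(m.sum()))

    if is_it.any():
        it_idx = np.flatnonzero(is_it)
        kern = np.exp(
            -((depth[it_idx, None] - arch_depths[None, :]) ** 2)
            / (2.0 * DEPTH_KERNEL_BW_UM**2)
        )
        kern /= kern.sum(axis=1, keepdims=True)
        alpha = WEIGHT_JITTER_KAPPA * kern + 1e-3
        weights[it_idx] = np.vstack([rng.dirichlet(a) for a in alpha])

    shallow = config.with_(
        mean_log_umis=config.mean_log_umis + np.log(SPATIAL_DEPTH_FACTOR)
    )
    latent = _latent_matrix(config, panel, subclass, is_it, weights, rng, config.noise_sd)
    X = _nb_counts(latent, shallow, rng) if sample_counts else latent.copy()

    obs = pd.DataFrame(
        {
            "sample": f"{config.species_preset}_roi1",
            "species": config.species_preset,
            "cell_class": pd.Categorical(cell_class.astype(str)),
            "subclass": pd.Categorical(subclass.astype(str)),
            "is_it": is_it,
            "x_um": x,
            "depth_um": depth,
        },
        index=pd.Index(
            [f"{config.species_preset}_s{i:06d}" for i in range(n)], name="cell_id"
        ),
    )
    var = pd.DataFrame(
        {"signature": panel.signature}, index=pd.Index(panel.gene_ids, name="gene_id")
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["generator"] = {
        "seed": config.seed,
        "species": config.species_preset,
        "column_height_um": H,
        "column_width_um": W,
    }
    truth = SyntheticTruth(
        subclass=subclass.astype(str),
        cell_class=cell_class.astype(str),
        archetype_weights=weights,
        depth_um=depth.copy(),
        proportions={},
        pnn_mode=config.pnn_mode,
    )
    return adata, truth
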
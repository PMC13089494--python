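"""Workflow orchestration: atlas comparison, spatial column, histology.

Each workflow generates (or loads) its inputs, runs the corresponding
analysis stages, and writes a numeric report (JSON) plus TSV tables under
the output directory.  Identical configuration yields identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import species_preset, generate_atlas, it_preset
from .synthetic.spatial import generate_spatial
from .synthetic.histo import generate_histo
from .sc import (
    qc_filter, normalize_log, select_hvgs, pca_embed, cluster_graph,
    subclass_proportions,
)
from .crossspecies import (
    OrthologMap, ortholog_subset, cluster_overlap_fraction,
    balanced_label_transfer, confusion_matrix, integrate_embed,
)
from .pareto import select_vertex_count
from .spatial import (
    SpatialColumn, build_pseudocolumn, assign_labels_multiround,
    gini_subpial, density_ratio_below_above, subpial_density_profile,
)
from .histo import background_subtract_normalize, layer_densities, pv_pnn_association

log = logging.getLogger("corticolumn")

GABA_SET = ("Frem1", "Lamp5", "Pvalb", "Sst", "Vip")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "it_vertex_count",
    "atlas_pvalb_recovery",
    "histology_density_excess",
]


def it_vertex_count(
    seed: int,
    n_cells: int = 2000,
    n_genes: int = 300,
    D: int = 10,
    candidates=range(2, 11),
    n_restarts: int = 5,
) -> int:
    """Elbow-selected vertex count of one synthetic IT continuum.

    Generates an IT-only dataset with the default continuum preset,
    log-normalizes, embeds with PCA, and runs the polytope vertex-count
    scan.
    """
    cfg = it_preset(n_cells=n_cells, n_genes=n_genes, seed=seed)
    adata, _ = generate_atlas(cfg)
    emb = pca_embed(normalize_log(adata), D=D, seed=seed)
    return select_vertex_count(emb.scores, candidates, n_restarts=n_restarts, seed=seed)


def make_reference(species: str, seed: int, n_cells: int = 10000):
    """QC'd, labeled, normalized same-species reference atlas for transfer."""
    cfg = species_preset(species).with_(n_cells=n_cells, seed=seed)
    ref, _ = generate_atlas(cfg)
    refqc = qc_filter(ref)
    return refqc, normalize_log(refqc)


def atlas_pvalb_recovery(
    species: str,
    seed: int,
    n_cells: int = 10000,
    transfer_iterations: int = 20,
    reference=None,
) -> float:
    """Pvalb percentage of the GABAergic population recovered by the atlas
    workflow (QC, normalization, clustering, reference-based labeling) on a
    fresh species-preset atlas.

    ``reference`` is an optional (qc'd AnnData, normalized AnnData) pair; by
    default a labeled reference atlas is generated from an offset seed.
    """
    from .synthetic.config import subclass_to_class

    gcfg = species_preset(species).with_(n_cells=n_cells, seed=seed)
    adata, _ = generate_atlas(gcfg)
    qc = qc_filter(adata)
    norm = normalize_log(qc)
    emb = pca_embed(norm, D=30, seed=seed)
    clusters = cluster_graph(emb, k_neighbors=15, resolution=1.0, seed=seed)
    if reference is None:
        reference = make_reference(species, seed + 100003, n_cells)
    refqc, refnorm = reference
    shared = refnorm.var_names.intersection(norm.var_names)
    res = balanced_label_transfer(
        refnorm[:, shared].copy(),
        refqc.obs["subclass"].astype(str).to_numpy(),
        norm[:, shared].copy(),
        n_iter=transfer_iterations,
        seed=seed,
    )
    cells = pd.DataFrame(
        {
            "sample": qc.obs["sample"].to_numpy(),
            "subclass": res.predicted.to_numpy(),
            "cell_class": [subclass_to_class(s) for s in res.predicted],
            "cluster": clusters.astype(str),
        },
        index=qc.obs_names,
    )
    props = subclass_proportions(cells, level="subclass", within="gabaergic")
    return float(100.0 * props.get("Pvalb", pd.Series(0.0, index=props.index)).mean())


def histology_density_excess(seed: int) -> float:
    """Percent excess of whole-column PV density, opossum vs. paired mouse
    field (identical geometry, species presets)."""
    dens = {}
    for species in ("mouse", "opossum"):
        f, _ = generate_histo(species_preset(species).with_(seed=seed))
        ld = layer_densities(f)
        dens[species] = ld["n_cells"].sum() / ld["area_mm2"].sum()
    return float(100.0 * (dens["opossum"] / dens["mouse"] - 1.0))


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run; unknown keys are rejected on load."""

    workflow: str = "all"  # atlas | spatial | histology | all
    seed: int = 0
    outdir: str = "pipeline_out"
    n_cells_atlas: int = 4000
    n_cells_spatial: int = 1500
    n_genes: int = 2000
    transfer_iterations: int = 10
    pcha_candidates: tuple[int, int] = (2, 8)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.workflow not in ("atlas", "spatial", "histology", "all"):
            raise ValueError(f"unknown workflow {self.workflow!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pcha_candidates" in data:
            data["pcha_candidates"] = tuple(data["pcha_candidates"])
        return cls(**data)


def _species_atlases(cfg: PipelineConfig):
    for species, seed_off in (("mouse", 0), ("opossum", 1)):
        gcfg = species_preset(species).with_(
            n_cells=cfg.n_cells_atlas, n_genes=cfg.n_genes, seed=cfg.seed + seed_off
        )
        adata, truth = generate_atlas(gcfg)
        yield species, adata, truth


def run_atlas_workflow(cfg: PipelineConfig, outdir: Path) -> dict:
    """QC, embedding, clustering, cross-species integration and label
    transfer, composition statistics."""
    report: dict = {}
    data = {}
    for species, adata, truth in _species_atlases(cfg):
        qc = qc_filter(adata)
        norm = normalize_log(qc)
        emb = pca_embed(norm, D=30, seed=cfg.seed)
        clusters = cluster_graph(emb, k_neighbors=15, resolution=1.0, seed=cfg.seed)
        qc.obs["cluster"] = pd.Categorical(clusters.astype(str))
        data[species] = (qc, norm)
        report[f"{species}_n_cells_qc"] = int(qc.n_obs)
        report[f"{species}_n_clusters"] = int(len(set(clusters)))
        props = subclass_proportions(qc.obs, level="subclass", within="gabaergic")
        if "Pvalb" in props.columns:
            report[f"{species}_pvalb_pct_gaba"] = float(100 * props["Pvalb"].mean())
        props.to_csv(outdir / f"{species}_gaba_proportions.tsv", sep="\t")

    # cross-species: identity orthologs on the shared synthetic panel
    (m_qc, m_norm), (o_qc, o_norm) = data["mouse"], data["opossum"]
    omap = OrthologMap.identity(m_norm.var_names.intersection(o_norm.var_names))
    m_sub, o_sub = ortholog_subset(m_norm, o_norm, omap)
    emb, tags = integrate_embed([m_sub, o_sub], D=30, seed=cfg.seed)
    joint_labels = np.concatenate(
        [m_qc.obs["subclass"].astype(str), o_qc.obs["subclass"].astype(str)]
    )
    joint_clusters = cluster_graph(
        _scores_embedding(emb), k_neighbors=15, resolution=1.0, seed=cfg.seed
    )
    overlap = cluster_overlap_fraction(joint_labels, joint_clusters)
    overlap.to_csv(outdir / "subclass_cluster_overlap.tsv", sep="\t")
    report["overlap_matrix_mean"] = float(
        overlap.to_numpy()[np.triu_indices(len(overlap), 1)].mean()
    )

    res = balanced_label_transfer(
        m_sub, m_qc.obs["subclass"].astype(str).to_numpy(), o_sub,
        n_iter=cfg.transfer_iterations, seed=cfg.seed,
    )
    conf = confusion_matrix(
        o_qc.obs["subclass"].astype(str).to_numpy(), res.predicted.to_numpy()
    )
    conf.to_csv(outdir / "cross_species_confusion.tsv", sep="\t")
    shared_gaba = [g for g in GABA_SET if g in conf.index and g in conf.columns]
    report["gaba_diagonal_mean"] = float(
        np.mean([conf.loc[g, g] for g in shared_gaba])
    )

    # IT polytope per species
    for species, (qc, norm) in data.items():
        it = norm[qc.obs["is_it"].to_numpy()]
        if it.n_obs > 50:
            emb_it = pca_embed(it, D=10, seed=cfg.seed)
            lo, hi = cfg.pcha_candidates
            k_star = select_vertex_count(
                emb_it.scores, range(lo, hi + 1), n_restarts=3, seed=cfg.seed
            )
            report[f"{species}_it_vertex_count"] = int(k_star)
    return report


def _scores_embedding(emb):
    from .sc import Embedding

    return Embedding(
        scores=emb.scores,
        loadings=emb.loadings,
        gene_center=emb.gene_center,
        gene_scale=emb.gene_scale,
    )


def run_spatial_workflow(cfg: PipelineConfig, outdir: Path) -> dict:
    """Stereo-style column analysis against a same-species reference."""
    report: dict = {}
    for species, seed_off in (("mouse", 0), ("opossum", 1)):
        gcfg = species_preset(species).with_(
            n_cells=cfg.n_cells_spatial, n_genes=cfg.n_genes, seed=cfg.seed + 10 + seed_off
        )
        spat, truth = generate_spatial(gcfg)
        ref_cfg = gcfg.with_(n_cells=cfg.n_cells_atlas, seed=cfg.seed + 20 + seed_off)
        ref, _ = generate_atlas(ref_cfg)
        refqc = qc_filter(ref)
        shared = spat.var_names.intersection(refqc.var_names)
        q_norm = normalize_log(spat[:, shared].copy())
        r_norm = normalize_log(refqc[:, shared].copy())
        labels, un = assign_labels_multiround(
            q_norm, r_norm, refqc.obs["subclass"].astype(str).to_numpy(),
            thresholds=(1.0, 0.75, 0.5), k=30, seed=cfg.seed,
        )
        col = SpatialColumn(
            cells=spat.obs.assign(assigned=labels.to_numpy()),
            width_um=gcfg.column_width_um,
            height_um=gcfg.column_height_um,
            counts=spat,
        )
        report[f"{species}_assigned_frac"] = float(labels.notna().mean())
        ginis = {}
        for sub in col.cells["assigned"].dropna().unique():
            n_sub = (col.cells["assigned"] == sub).sum()
            if n_sub >= 25:
                ginis[str(sub)] = gini_subpial(col, str(sub), label_col="assigned")
        report[f"{species}_gini"] = ginis
        pd.Series(ginis).to_csv(outdir / f"{species}_gini.tsv", sep="\t", header=False)
        upper, mid = ("L2/3", "L4") if species == "mouse" else ("IT_A", "IT_B")
        try:
            report[f"{species}_density_ratio_below_above"] = density_ratio_below_above(
                col, upper, mid, label_col="assigned"
            )
        except ValueError:
            report[f"{species}_density_ratio_below_above"] = None
    return report


def run_histology_workflow(cfg: PipelineConfig, outdir: Path) -> dict:
    """Paired-species PV/WFA field quantification."""
    report: dict = {}
    dens = {}
    for species, seed_off in (("mouse", 0), ("opossum", 1)):
        gcfg = species_preset(species).with_(seed=cfg.seed + 30)
        f, truth = generate_histo(gcfg)
        corrected = background_subtract_normalize(f)
        ld = layer_densities(f)
        ld.to_csv(outdir / f"{species}_layer_densities.tsv", sep="\t", index=False)
        dens[species] = float(ld["n_cells"].sum() / ld["area_mm2"].sum())
        assoc = pv_pnn_association(f, corrected, n_null_per_cell=3, seed=cfg.seed)
        report[f"{species}_pv_density_per_mm2"] = dens[species]
        report[f"{species}_wfa_median_difference"] = assoc["median_difference"]
    report["pv_density_excess_pct"] = float(
        100 * (dens["opossum"] / dens["mouse"] - 1)
    )
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the selected workflow(s); returns and writes the report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg)}
    stages = {
        "atlas": run_atlas_workflow,
        "spatial": run_spatial_workflow,
        "histology": run_histology_workflow,
    }
    selected = stages if cfg.workflow == "all" else {cfg.workflow: stages[cfg.workflow]}
    for name, fn in selected.items():
        log.info("running %s workflow (seed=%d)", name, cfg.seed)
        try:
            report[name] = fn(cfg, outdir)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
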
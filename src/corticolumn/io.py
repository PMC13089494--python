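"""File I/O for every pipeline artifact.

Counts travel as MatrixMarket (MTX) plus gene/cell TSVs, cell tables as TSV,
histology fields as single-channel TIFF plus centroid/polyline CSVs, configs
as YAML key-value files.  Writers log the generator seed where known;
readers validate type invariants and report offending files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
import yaml

from .synthetic.config import GeneratorConfig
from .synthetic.histo import HistoField

log = logging.getLogger("corticolumn")

__all__ = [
    "write_counts",
    "read_counts",
    "write_cell_table",
    "read_cell_table",
    "write_histo_field",
    "read_histo_field",
    "write_config",
    "read_config",
    "load_dataset",
]


def write_counts(adata: ad.AnnData, prefix: Path | str) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(prefix) + ".mtx", X.tocoo())
    adata.obs.to_csv(str(prefix) + ".cells.tsv", sep="\t")
    adata.var.to_csv(str(prefix) + ".genes.tsv", sep="\t")
    seed = adata.uns.get("generator", {}).get("seed")
    log.info("wrote counts %s (seed=%s)", prefix, seed)


def read_counts(prefix: Path | str) -> ad.AnnData:
    prefix = Path(prefix)
    try:
        X = scipy.io.mmread(str(prefix) + ".mtx").tocsr()
    except Exception as e:  # corrupt MTX: name the file
        raise ValueError(f"failed to parse MTX {prefix}.mtx: {e}") from e
    if (X.data < 0).any():
        raise ValueError(f"{prefix}.mtx contains negative entries")
    obs = pd.read_csv(str(prefix) + ".cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t", index_col=0)
    if obs.index.duplicated().any() or var.index.duplicated().any():
        raise ValueError(f"{prefix}: duplicate cell or gene identifiers")
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_cell_table(cells: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, sep="\t")


def read_cell_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_histo_field(f: HistoField, prefix: Path | str) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(prefix) + ".tif", f.image.astype(np.float32))
    pd.DataFrame(f.pv_centroids, columns=["x_um", "y_um"]).to_csv(
        str(prefix) + ".centroids.csv", index=False
    )
    pd.DataFrame(f.pial_polyline, columns=["x_um", "y_um"]).to_csv(
        str(prefix) + ".pial.csv", index=False
    )
    meta = {"px_size_um": float(f.px_size_um)}
    for name, poly in f.layer_polygons.items():
        meta.setdefault("layers", {})[name] = np.asarray(poly).tolist()
    with open(str(prefix) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_histo_field(prefix: Path | str) -> HistoField:
    prefix = Path(prefix)
    img = tifffile.imread(str(prefix) + ".tif").astype(np.float64)
    cen = pd.read_csv(str(prefix) + ".centroids.csv").to_numpy()
    pial = pd.read_csv(str(prefix) + ".pial.csv").to_numpy()
    with open(str(prefix) + ".meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    polys = {k: np.asarray(v) for k, v in meta.get("layers", {}).items()}
    return HistoField(
        image=img,
        px_size_um=float(meta["px_size_um"]),
        pial_polyline=pial,
        cortical_mask=np.ones(img.shape, dtype=bool),
        layer_polygons=polys,
        pv_centroids=cen,
    )


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_config(cfg: GeneratorConfig, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg.to_dict()), fh, sort_keys=True)


def read_config(path: Path | str) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("archetype_concentration", "histo_field_mm"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "depth_law" in data:
        data["depth_law"] = {k: tuple(v) for k, v in data["depth_law"].items()}
    return GeneratorConfig(**data)


def load_dataset(path: Path | str, kind: str):
    """Load one typed artifact: counts | spatial | annotation | histo."""
    path = Path(path)
    if kind == "counts":
        return read_counts(path)
    if kind == "spatial":
        adata = read_counts(path)
        for col in ("x_um", "depth_um"):
            if col not in adata.obs.columns:
                raise ValueError(f"{path}: spatial table missing column {col!r}")
        return adata
    if kind == "annotation":
        from .annotation import read_gene_gtf

        return read_gene_gtf(path)
    if kind == "histo":
        return read_histo_field(path)
    raise ValueError(f"unknown dataset kind {kind!r}")
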
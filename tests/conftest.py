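import numpy as np
import pandas as pd
import pytest
import anndata as ad

from corticolumn.synthetic import GeneratorConfig, species_preset, generate_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """A small mouse-preset atlas shared across read-only tests."""
    cfg = species_preset("mouse").with_(n_cells=400, n_genes=400, seed=11)
    adata, truth = generate_atlas(cfg)
    return cfg, adata, truth


@pytest.fixture
def toy_counts():
    """Tiny dense count matrix with known per-cell totals."""
    X = np.array(
        [
            [10, 30, 60, 0],
            [0, 0, 0, 0],
            [5, 5, 5, 5],
        ]
    )
    return ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(3)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(4)]),
    )
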
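import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import synocircuit as syn
from synocircuit import preprocess
from synocircuit.io import COUNTS_LAYER, LOGNORM_LAYER

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


def make_expression(counts, cell_ids=None, gene_ids=None, mito_prefix="mt-"):
    """Build a validated expression AnnData from a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    counts_sp = sp.csr_matrix(counts.astype(np.int64))
    adata = ad.AnnData(
        X=counts_sp.copy(),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
        layers={COUNTS_LAYER: counts_sp},
    )
    adata.uns["mito_prefix"] = mito_prefix
    return adata


def make_lognorm(values, cell_ids=None, gene_ids=None):
    """Expression AnnData with an explicit normalized layer (counts synthetic)."""
    values = np.asarray(values, dtype=float)
    adata = make_expression(np.rint(np.expm1(values)).astype(int), cell_ids, gene_ids)
    adata.layers[LOGNORM_LAYER] = sp.csr_matrix(values)
    adata.X = adata.layers[LOGNORM_LAYER].copy()
    return adata


@pytest.fixture(scope="session")
def reference_atlas():
    """The package's reference study conditions: 3 types x 200 cells x 3 conditions."""
    cfg = syn.default_config(seed=20)
    adata, ann, truth = syn.generate_atlas(cfg)
    norm = preprocess.normalize_log(adata)
    return cfg, norm, ann, truth


@pytest.fixture(scope="session")
def small_atlas():
    """A quick atlas for unit tests that only need structure, not power."""
    cfg = syn.default_config(
        seed=7, n_cells_per_type_per_condition=60, n_genes=500
    )
    adata, ann, truth = syn.generate_atlas(cfg)
    norm = preprocess.normalize_log(adata)
    return cfg, norm, ann, truth
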
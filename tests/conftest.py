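import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse


def make_adata(counts, gene_names=None, barcodes=None, condition=None, cluster=None):
    """Build a cells-by-genes AnnData from a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_names = gene_names or [f"g{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"cell{i}" for i in range(n_cells)]
    obs = pd.DataFrame(index=barcodes)
    if condition is not None:
        obs["condition"] = list(condition)
    if cluster is not None:
        obs["cluster"] = list(cluster)
    return ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame(index=gene_names),
    )


@pytest.fixture
def adata_factory():
    return make_adata


@pytest.fixture(scope="session")
def planted_dataset():
    """A processed two-condition dataset with a strongly planted signature."""
    from dataclasses import replace

    import cellsig as cs

    config = cs.SimConfig(n_genes=1200, n_cells_per_condition=250, seed=42)
    sig = cs.pick_signature(config, n_up=40, n_down=10, name="planted", seed=43)
    config = replace(
        config,
        planted_effects=(
            cs.PlantedEffect(sig, "shSELP", up_log_fold=1.2, down_log_fold=-0.8),
        ),
    )
    adata, truth = cs.simulate_counts(config)
    adata = cs.filter_genes(cs.filter_cells(adata), cs.QCConfig())
    cs.scale_genes(cs.normalize_log(adata))
    return adata, truth, sig
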
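import anndata as ad
import numpy as np
import pandas as pd
import pytest


def make_adata(X, cell_ids=None, gene_ids=None, **obs_cols) -> ad.AnnData:
    """Small AnnData helper for hand-built matrices."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    obs = pd.DataFrame(index=cell_ids or [f"c{i}" for i in range(n)])
    for k, v in obs_cols.items():
        obs[k] = v
    var = pd.DataFrame(index=gene_ids or [f"g{j}" for j in range(m)])
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.fixture(scope="session")
def sc_dataset():
    """One default synthetic single-cell dataset shared by read-only tests."""
    from sctarget.pipeline import default_sc_config
    from sctarget.simulate import simulate_scrna

    return simulate_scrna(default_sc_config(seed=11))


@pytest.fixture(scope="session")
def lognorm_dataset(sc_dataset):
    from sctarget import qc

    adata, truth = sc_dataset
    adata, _ = qc.qc_filter(adata, qc.QCThresholds(min_genes=50))
    return qc.normalize_log(adata), truth
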
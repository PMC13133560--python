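"""Shared fixtures: a gene panel and small simulated tissue sections."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from fibrotalk import preprocess, spatial_stats, synthetic_data


@pytest.fixture(scope="session")
def panel():
    return synthetic_data.generate_panel()


@pytest.fixture(scope="session")
def ar_sample(panel):
    """One moderate AR tissue section, QC'd, normalized, with its graph."""
    cfg = synthetic_data.SimConfig(cells_per_sample=2200)
    sample = synthetic_data.generate_tissue(cfg, panel, "AR_fix", "AR", 42)
    cells, adata, _ = preprocess.filter_cells(sample.cells, sample.adata)
    preprocess.normalize_expression(adata)
    graph = spatial_stats.build_neighbor_graph(cells, 20.0)
    return sample, cells, adata, graph


@pytest.fixture(scope="session")
def control_sample(panel):
    cfg = synthetic_data.SimConfig(cells_per_sample=2200)
    sample = synthetic_data.generate_tissue(cfg, panel, "ctrl_fix", "control", 43)
    cells, adata, _ = preprocess.filter_cells(sample.cells, sample.adata)
    preprocess.normalize_expression(adata)
    graph = spatial_stats.build_neighbor_graph(cells, 20.0)
    return sample, cells, adata, graph


def make_adata(counts, gene_names=None, cell_ids=None, normalize=True):
    """Small dense-counts AnnData helper for hand-built test cases."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    genes = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(n_genes)]
    ids = list(cell_ids) if cell_ids is not None else [f"c{i}" for i in range(n_cells)]
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if normalize:
        preprocess.normalize_expression(adata)
    return adata


def make_cells(xy, types, sample_id="s1", group="AR", cell_ids=None):
    """Minimal cell table around coordinates + type labels."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    ids = list(cell_ids) if cell_ids is not None else [f"c{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "cell_id": ids,
            "sample_id": sample_id,
            "group": group,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cell_type": list(types),
            "n_genes": 120,
            "n_transcripts": 800,
            "pct_mito": 0.05,
        }
    )
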
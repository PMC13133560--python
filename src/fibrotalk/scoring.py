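"""Gene-module scores, fibroblast ligand scores and crosstalk scores.

Three related quantities:

* module score -- per-cell, control-adjusted mean expression of a gene set
  (binned-control construction), min-max normalized to [0, 1] over the
  scored pool of cells;
* fibroblast ligand score -- per CD4+ T cell, the summed normalized
  expression of five pro-Th2 ligands (TSLP, ICOSL, OX40L, CCL17, POSTN) in
  its nearest fibroblast within the neighborhood radius;
* crosstalk score -- per sample, the arithmetic mean of its ligand scores;
  a composite variant multiplies adjacency, fibroblast mediator expression
  and T-cell Th2 signature components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .preprocess import LOGNORM_LAYER
from .spatial_stats import NeighborGraph

logger = logging.getLogger(__name__)

PRO_TH2_LIGANDS = ("TSLP", "ICOSL", "OX40L", "CCL17", "POSTN")
#: fibroblast type-2 mediators used for the composite score's mediator component
TH2_MEDIATORS = ("TSLP", "IL33", "CCL17", "ICOSL", "OX40L", "POSTN")
CORE_TH2_SET = ("IL4", "IL5", "IL13", "IL9")


def _lognorm_dense(adata: AnnData, genes=None) -> np.ndarray:
    Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    if genes is not None:
        cols = [adata.var_names.get_loc(g) for g in genes]
        Y = Y[:, cols]
    return np.asarray(Y.todense())


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] over the pool; all-equal input maps to all zeros."""
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi == lo:
        return np.zeros_like(raw, dtype=float)
    return (raw - lo) / (hi - lo)


def module_score(
    adata: AnnData,
    gene_set: list[str],
    gene_set_name: str = "custom",
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned-control gene-module score per cell.

    Genes are binned by their mean normalized expression over the scored
    pool (``n_bins`` equal-frequency bins). For every set gene, ``n_ctrl``
    control genes are drawn from its bin (the whole bin, deterministically,
    when the bin has at most ``n_ctrl`` genes). The raw score is the mean
    expression of the set genes minus the mean expression of the pooled
    controls; ``norm_score`` min-max rescales the raw scores over the cell
    pool (all-equal raw scores map to 0).
    """
    present = [g for g in gene_set if g in adata.var_names]
    if not present:
        raise ValueError(f"no gene of set {gene_set_name!r} found in the panel")
    if len(present) < len(gene_set):
        logger.info(
            "module_score(%s): %d/%d set genes present in panel",
            gene_set_name, len(present), len(gene_set),
        )
    Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    gene_means = np.asarray(Y.mean(axis=0)).ravel()

    # equal-frequency bins on the expression rank of every panel gene
    order = pd.Series(gene_means, index=adata.var_names)
    ranks = order.rank(method="first")
    n_bins_eff = min(n_bins, adata.n_vars)
    bins = pd.cut(ranks, bins=n_bins_eff, labels=False)

    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    name_to_col = {g: i for i, g in enumerate(adata.var_names)}
    for g in present:
        bin_genes = order.index[bins == bins[g]]
        if len(bin_genes) <= n_ctrl:
            chosen = list(bin_genes)
        else:
            chosen = list(rng.choice(bin_genes, size=n_ctrl, replace=False))
        ctrl_idx.extend(name_to_col[c] for c in chosen)

    set_cols = [name_to_col[g] for g in present]
    set_mean = np.asarray(Y[:, set_cols].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(Y[:, ctrl_idx].mean(axis=1)).ravel()
    raw = set_mean - ctrl_mean
    return pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "gene_set_name": gene_set_name,
            "raw_score": raw,
            "norm_score": minmax_normalize(raw),
        }
    ).set_index("cell_id")


def fibroblast_ligand_score(
    cells: pd.DataFrame,
    graph: NeighborGraph,
    adata: AnnData,
    t_type: str = "CD4_T",
    fibro_type: str = "fibroblast",
    ligands: tuple[str, ...] = PRO_TH2_LIGANDS,
) -> pd.DataFrame:
    """Pro-Th2 ligand score of the nearest fibroblast of each CD4+ T cell.

    For every T cell with at least one fibroblast within the graph radius,
    the minimum-distance fibroblast is selected (distance ties broken by
    the lexicographically smaller fibroblast cell id) and the score is the
    sum of that fibroblast's normalized expression over ``ligands``. T
    cells with no fibroblast in range are excluded (their count is logged).
    """
    missing = [g for g in ligands if g not in adata.var_names]
    if missing:
        raise ValueError(f"ligand genes missing from panel: {missing}")
    labels = cells["cell_type"].to_numpy(dtype=object)
    cell_ids = cells["cell_id"].to_numpy(dtype=object)
    is_t = labels == t_type
    is_f = labels == fibro_type

    gi, gj, dist = graph.i, graph.j, graph.dist
    tf = is_t[gi] & is_f[gj]
    ft = is_f[gi] & is_t[gj]
    t_idx = np.concatenate([gi[tf], gj[ft]])
    f_idx = np.concatenate([gj[tf], gi[ft]])
    d = np.concatenate([dist[tf], dist[ft]])

    n_t_total = int(is_t.sum())
    if len(t_idx) == 0:
        logger.info("fibroblast_ligand_score: no T-fibroblast pairs within radius")
        return pd.DataFrame(
            columns=["t_cell_id", "paired_fibroblast_id", "pair_distance", "ligand_score"]
        )
    pairs = pd.DataFrame(
        {
            "t_idx": t_idx,
            "f_idx": f_idx,
            "pair_distance": d,
            "fibro_id": cell_ids[f_idx],
        }
    )
    pairs = pairs.sort_values(["t_idx", "pair_distance", "fibro_id"], kind="mergesort")
    nearest = pairs.groupby("t_idx", sort=True).first().reset_index()

    lig = _lognorm_dense(adata, list(ligands))
    scores = lig[nearest["f_idx"].to_numpy(dtype=int)].sum(axis=1)
    n_excluded = n_t_total - len(nearest)
    logger.info(
        "fibroblast_ligand_score: %d/%d T cells paired (%d without fibroblast in radius)",
        len(nearest), n_t_total, n_excluded,
    )
    return pd.DataFrame(
        {
            "t_cell_id": cell_ids[nearest["t_idx"].to_numpy(dtype=int)],
            "paired_fibroblast_id": nearest["fibro_id"].to_numpy(dtype=object),
            "pair_distance": nearest["pair_distance"].to_numpy(dtype=float),
            "ligand_score": scores,
        }
    )


@dataclass
class CrosstalkScore:
    """Sample-level crosstalk summary."""

    sample_id: str
    mean_ligand_score: float  # NaN (flagged) when n_pairs == 0
    n_pairs: int
    composite_score: float | None = None


def sample_crosstalk_score(ligand_records: pd.DataFrame, sample_id: str) -> CrosstalkScore:
    """Arithmetic mean of a sample's single-cell fibroblast ligand scores."""
    n = len(ligand_records)
    if n == 0:
        logger.warning("sample %s has no T-fibroblast pairs; crosstalk undefined", sample_id)
        return CrosstalkScore(sample_id=sample_id, mean_ligand_score=float("nan"), n_pairs=0)
    return CrosstalkScore(
        sample_id=sample_id,
        mean_ligand_score=float(ligand_records["ligand_score"].mean()),
        n_pairs=n,
    )


def composite_crosstalk_score(
    adjacency_component: float, mediator_component: float, th2_component: float
) -> float:
    """Product of the three crosstalk components.

    Components are (1) the sample's CD4-T-to-fibroblast adjacency fraction,
    (2) the sample-mean fibroblast mediator module norm-score, and (3) the
    sample-mean core-Th2 norm-score of CD4+ T cells.
    """
    comps = (adjacency_component, mediator_component, th2_component)
    for c in comps:
        if not np.isfinite(c):
            raise ValueError("composite components must be finite")
        if c < 0:
            raise ValueError("composite components must be nonnegative")
    return float(np.prod(comps))
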
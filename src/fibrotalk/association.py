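"""Adjacency-stratified contrasts and correlation analyses.

Links the spatial niche structure to expression and to clinical severity:
expression contrasts between fibroblast-adjacent (>=1 fibroblast within
the neighborhood radius) and fibroblast-poor (none) CD4+ T cells, Pearson
correlations at the single-cell level (ligand score vs. Th2 readouts) and
at the sample level (crosstalk score vs. serum IgE / SPT wheal diameter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .de_lr import wilcoxon_rank_sum
from .preprocess import LOGNORM_LAYER
from .spatial_stats import NeighborGraph

logger = logging.getLogger(__name__)


@dataclass
class StratifiedContrast:
    """Expression of one gene in adjacent vs non-adjacent cells of a type."""

    name: str
    n_adjacent: int
    n_nonadjacent: int
    mean_adjacent: float
    mean_nonadjacent: float
    fold: float  # +inf flag when the non-adjacent mean is zero
    p: float
    per_sample_means: pd.DataFrame | None = None


def adjacent_expression_contrast(
    cells: pd.DataFrame,
    graph: NeighborGraph,
    adata: AnnData,
    gene: str,
    t_type: str = "CD4_T",
    partner: str = "fibroblast",
) -> StratifiedContrast:
    """Fold-difference of a gene between fibroblast-adjacent and -poor T cells.

    Means are taken on the depth-normalized scale (``expm1`` of the log
    layer); the p-value is a two-sided Wilcoxon rank-sum across cells.
    Per-sample stratum means are attached for group-level testing.
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not in panel")
    labels = cells["cell_type"].to_numpy(dtype=object)
    is_t = labels == t_type
    partner_mask = labels == partner
    adj = graph.has_neighbor_of(partner_mask)
    a_mask = is_t & adj
    n_mask = is_t & ~adj
    if not a_mask.any() or not n_mask.any():
        logger.warning("adjacent_expression_contrast(%s): empty stratum", gene)
        return StratifiedContrast(gene, int(a_mask.sum()), int(n_mask.sum()),
                                  float("nan"), float("nan"), float("nan"), float("nan"))
    col = adata.var_names.get_loc(gene)
    expr = np.expm1(np.asarray(sp.csr_matrix(adata.layers[LOGNORM_LAYER])[:, col].todense()).ravel())
    va, vn = expr[a_mask], expr[n_mask]
    mean_a, mean_n = float(va.mean()), float(vn.mean())
    if mean_n > 0:
        fold = mean_a / mean_n
    else:
        fold = float("inf") if mean_a > 0 else float("nan")
    _, p = wilcoxon_rank_sum(va, vn)
    per_sample = (
        pd.DataFrame(
            {
                "sample_id": cells["sample_id"].to_numpy(dtype=object)[is_t],
                "adjacent": adj[is_t],
                "expr": expr[is_t],
            }
        )
        .groupby(["sample_id", "adjacent"], observed=True)["expr"]
        .mean()
        .unstack("adjacent")
    )
    return StratifiedContrast(gene, int(a_mask.sum()), int(n_mask.sum()),
                              mean_a, mean_n, fold, float(p), per_sample)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    pearson_r: float
    p: float


def pearson_correlation(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pearson_correlation: zero variance in %s or %s", x_name, y_name)
        return CorrelationResult(x_name, y_name, x.size, float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, int(x.size), float(r), float(p))


def clinical_association(
    crosstalk_scores: pd.DataFrame,
    clinical: pd.DataFrame,
    score_column: str = "mean_ligand_score",
) -> dict[str, CorrelationResult]:
    """Correlate per-sample crosstalk scores with clinical severity metrics.

    ``crosstalk_scores`` needs columns ``sample_id`` and ``score_column``;
    ``clinical`` needs ``sample_id``, ``serum_IgE`` and ``spt_wheal``.
    Samples must match one-to-one.
    """
    missing = set(crosstalk_scores["sample_id"]) ^ set(clinical["sample_id"])
    if missing:
        raise ValueError(f"unmatched sample ids between scores and clinical table: {sorted(missing)}")
    merged = crosstalk_scores.merge(clinical, on="sample_id", validate="one_to_one")
    out = {}
    for metric in ("serum_IgE", "spt_wheal"):
        out[metric] = pearson_correlation(
            merged[score_column], merged[metric], x_name=score_column, y_name=metric
        )
    return out
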
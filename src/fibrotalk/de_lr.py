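"""Differential expression, pathway enrichment and ligand-receptor tests.

DE between groups within a cell type uses the Wilcoxon rank-sum test on
log-normalized expression with the conventional detection-fraction and
fold-change filters (min.pct 0.1, log2FC threshold 0.25, BH adjustment).
Ligand-receptor co-expression between a sender and a receiver type is
tested with a label-permutation null on the mean-of-means interaction
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .preprocess import LOGNORM_LAYER
from .spatial_stats import bh_adjust

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 12
#: default fibroblast -> CD4 T ligand-receptor pairs (OX40 = TNFRSF4)
DEFAULT_LR_PAIRS = (("TSLP", "IL7R"), ("OX40L", "TNFRSF4"), ("ICOSL", "ICOS"))


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses exact enumeration for small samples without ties (combined
    n <= 12), otherwise the tie-corrected normal approximation with
    continuity correction. Returns (U statistic of group a, p).
    Identical constant pooled values give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def differential_expression(
    adata: AnnData,
    cells: pd.DataFrame,
    cell_type: str,
    group_a: str,
    group_b: str,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.1,
    alpha: float = 0.05,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Per-gene Wilcoxon DE between two groups within one cell type.

    Genes are tested only when detected (count > 0) in at least ``min_pct``
    of the cells of either group. log2FC is computed on depth-normalized
    means back-transformed from the log layer:
    ``log2((mean expm1(a) + eps) / (mean expm1(b) + eps))``, eps = 1e-9.
    ``significant`` flags the upregulated list: BH-adjusted p < ``alpha``
    and log2FC > ``logfc_threshold``.

    With ``per_sample=True`` the Wilcoxon test is run on per-sample mean
    expression instead of pooled cells, guarding against pseudoreplication.
    """
    mask_t = (cells["cell_type"] == cell_type).to_numpy()
    in_a = mask_t & (cells["group"] == group_a).to_numpy()
    in_b = mask_t & (cells["group"] == group_b).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError(f"both groups need cells of type {cell_type!r}")
    Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    Ya, Yb = Y[in_a.nonzero()[0]], Y[in_b.nonzero()[0]]
    pct_a = np.asarray((Ya > 0).mean(axis=0)).ravel()
    pct_b = np.asarray((Yb > 0).mean(axis=0)).ravel()
    testable = (pct_a >= min_pct) | (pct_b >= min_pct)
    if not testable.any():
        logger.warning("differential_expression: no gene passes min_pct=%.2f", min_pct)
        return pd.DataFrame(
            columns=["gene", "log2fc", "pct_a", "pct_b", "p_raw", "p_adj", "significant"]
        )

    eps = 1e-9
    mean_a = np.asarray(np.expm1(Ya.todense()).mean(axis=0)).ravel()
    mean_b = np.asarray(np.expm1(Yb.todense()).mean(axis=0)).ravel()
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))

    if per_sample:
        samples = cells["sample_id"].to_numpy(dtype=object)
        dense = np.asarray(Y.todense())
        va = _per_sample_means(dense, in_a, samples)
        vb = _per_sample_means(dense, in_b, samples)
    else:
        va, vb = np.asarray(Ya.todense()), np.asarray(Yb.todense())

    genes = np.asarray(adata.var_names)
    rows = []
    for g_idx in np.flatnonzero(testable):
        _, p = wilcoxon_rank_sum(va[:, g_idx], vb[:, g_idx])
        rows.append((genes[g_idx], log2fc[g_idx], pct_a[g_idx], pct_b[g_idx], p))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "pct_a", "pct_b", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["significant"] = (out["p_adj"] < alpha) & (out["log2fc"] > logfc_threshold)
    return out.sort_values("p_adj", kind="mergesort").reset_index(drop=True)


def _per_sample_means(dense: np.ndarray, mask: np.ndarray, samples: np.ndarray) -> np.ndarray:
    out = []
    for sid in pd.unique(samples[mask]):
        sel = mask & (samples == sid)
        out.append(dense[sel].mean(axis=0))
    return np.vstack(out)


def hypergeometric_enrichment(
    hit_genes, pathways: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per pathway.

    Fold enrichment is (overlap/hits) / (pathway/universe); p-values are
    BH-adjusted across pathways.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes) & universe
    rows = []
    for name, genes in pathways.items():
        pw = set(genes) & universe
        overlap = len(hits & pw)
        if hits and pw:
            fold = (overlap / len(hits)) / (len(pw) / len(universe))
        else:
            fold = float("nan")
        # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|pathway|, N=|hits|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(pw), len(hits)))
        rows.append((name, len(pw), overlap, fold, p))
    out = pd.DataFrame(rows, columns=["pathway", "n_pathway", "overlap", "fold_enrichment", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"])
    return out


@dataclass
class LRPairResult:
    ligand: str
    receptor: str
    interaction_score: float
    p_raw: float


def lr_permutation_test(
    adata: AnnData,
    cells: pd.DataFrame,
    sender_type: str,
    receiver_type: str,
    pairs=DEFAULT_LR_PAIRS,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for ligand-receptor co-expression across two types.

    The interaction score of a pair is the mean of (mean normalized ligand
    expression in the sender type) and (mean normalized receptor expression
    in the receiver type). The null shuffles the sender/receiver labels
    among the union of the two populations; p = (1 + #{null >= observed}) /
    (1 + n_perm), BH-adjusted across pairs. Pairs whose genes are absent
    from the panel are skipped with a warning.
    """
    labels = cells["cell_type"].to_numpy(dtype=object)
    snd = labels == sender_type
    rcv = labels == receiver_type
    if not snd.any() or not rcv.any():
        raise ValueError("sender and receiver types must both be present")
    union = np.flatnonzero(snd | rcv)
    is_sender = snd[union]
    n_snd = int(is_sender.sum())

    Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    kept, lig_vec, rec_vec = [], [], []
    for lig, rec in pairs:
        if lig not in adata.var_names or rec not in adata.var_names:
            logger.warning("lr_permutation_test: skipping pair %s-%s (gene absent)", lig, rec)
            continue
        kept.append((lig, rec))
        lig_vec.append(np.asarray(Y[union, adata.var_names.get_loc(lig)].todense()).ravel())
        rec_vec.append(np.asarray(Y[union, adata.var_names.get_loc(rec)].todense()).ravel())
    if not kept:
        return pd.DataFrame(columns=["ligand", "receptor", "interaction_score", "p_raw", "p_adj"])
    L = np.vstack(lig_vec)  # pairs x union-cells
    R = np.vstack(rec_vec)

    def score(sender_mask: np.ndarray) -> np.ndarray:
        return 0.5 * (L[:, sender_mask].mean(axis=1) + R[:, ~sender_mask].mean(axis=1))

    observed = score(is_sender)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept), dtype=np.int64)
    perm_mask = np.zeros(len(union), dtype=bool)
    for _ in range(n_perm):
        perm_mask[:] = False
        perm_mask[rng.choice(len(union), size=n_snd, replace=False)] = True
        exceed += score(perm_mask) >= observed
    p_raw = (1 + exceed) / (1 + n_perm)
    out = pd.DataFrame(
        {
            "ligand": [k[0] for k in kept],
            "receptor": [k[1] for k in kept],
            "interaction_score": observed,
            "p_raw": p_raw,
        }
    )
    out["p_adj"] = bh_adjust(out["p_raw"])
    return out
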
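"""Cell- and sample-level QC, normalization, marker-argmax annotation.

Cells are kept in a pandas DataFrame (one row per segmented cell, with
coordinates in micrometres and the QC covariates ``n_genes``,
``n_transcripts`` and ``pct_mito``); expression lives in an
:class:`anndata.AnnData` with cells as observations, raw counts in ``X``
and the log-normalized layer in ``layers["lognorm"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

#: columns every cell table must carry
REQUIRED_CELL_COLUMNS = (
    "cell_id",
    "sample_id",
    "group",
    "x_um",
    "y_um",
    "cell_type",
    "n_genes",
    "n_transcripts",
    "pct_mito",
)

LOGNORM_LAYER = "lognorm"


@dataclass
class FilterReport:
    """Counts of cells removed by each QC criterion (non-exclusive)."""

    n_input: int
    n_retained: int
    n_low_genes: int
    n_high_mito: int
    n_low_transcripts: int
    removed_ids: pd.Index = field(repr=False, default_factory=lambda: pd.Index([]))


def compute_qc_covariates(adata: AnnData, mito_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-cell detected genes, total transcripts and mitochondrial fraction.

    ``pct_mito`` is a fraction in [0, 1]; cells with zero transcripts get 0.
    """
    X = sp.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_transcripts = np.asarray(X.sum(axis=1)).ravel()
    if mito_genes:
        mask = adata.var_names.isin(mito_genes)
        mito_counts = np.asarray(X[:, mask].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros_like(n_transcripts)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_transcripts > 0, mito_counts / np.maximum(n_transcripts, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_transcripts": n_transcripts.astype(int),
            "pct_mito": pct,
        },
        index=adata.obs_names,
    )


def filter_cells(
    cells: pd.DataFrame,
    adata: AnnData | None = None,
    *,
    min_genes: int = 50,
    max_mito: float = 0.20,
    min_transcripts: int = 100,
) -> tuple[pd.DataFrame, AnnData | None, FilterReport]:
    """Remove low-quality cells.

    A cell is removed iff ``n_genes < min_genes`` OR ``pct_mito > max_mito``
    OR ``n_transcripts < min_transcripts`` (strict inequalities: a cell
    sitting exactly on every threshold is retained). The expression matrix,
    if given, is subset to the retained cells; its rows must match the cell
    table one-to-one.
    """
    if adata is not None:
        if adata.n_obs != len(cells) or not np.array_equal(
            np.asarray(adata.obs_names), cells["cell_id"].to_numpy(dtype=object)
        ):
            raise ValueError("expression matrix cells do not match the cell table")
    low_genes = cells["n_genes"].to_numpy() < min_genes
    high_mito = cells["pct_mito"].to_numpy() > max_mito
    low_tx = cells["n_transcripts"].to_numpy() < min_transcripts
    drop = low_genes | high_mito | low_tx
    keep = ~drop
    report = FilterReport(
        n_input=len(cells),
        n_retained=int(keep.sum()),
        n_low_genes=int(low_genes.sum()),
        n_high_mito=int(high_mito.sum()),
        n_low_transcripts=int(low_tx.sum()),
        removed_ids=pd.Index(cells.loc[drop, "cell_id"]),
    )
    logger.info(
        "filter_cells: %d -> %d (low_genes=%d, high_mito=%d, low_transcripts=%d)",
        report.n_input,
        report.n_retained,
        report.n_low_genes,
        report.n_high_mito,
        report.n_low_transcripts,
    )
    filtered = cells.loc[keep].reset_index(drop=True)
    return filtered, (adata[keep.nonzero()[0]].copy() if adata is not None else None), report


def sample_qc(cells: pd.DataFrame, min_cells: int = 3000) -> pd.Series:
    """Pass/fail per sample: fail iff the retained-cell count is < min_cells.

    Expects :func:`filter_cells` to have been applied already.
    """
    counts = cells.groupby("sample_id", observed=True).size()
    passed = counts >= min_cells
    for sid, ok in passed.items():
        if not ok:
            logger.warning("sample %s fails QC: %d cells < %d", sid, counts[sid], min_cells)
    passed.name = "pass"
    return passed


def normalize_expression(adata: AnnData, scale: float = 10_000.0) -> AnnData:
    """Library-size normalize and natural-log transform the counts.

    Each entry becomes ``ln(1 + scale * count / cell_total)``. Cells with
    zero total counts are left all-zero (with a warning). The result is
    stored in ``adata.layers["lognorm"]`` in place and also returned.
    """
    X = sp.csr_matrix(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts; normalized values set to 0", zero.sum())
    inv = np.where(zero, 0.0, scale / np.maximum(totals, 1e-300))
    Y = sp.diags(inv) @ X
    Y.data = np.log1p(Y.data)
    adata.layers[LOGNORM_LAYER] = Y.tocsr()
    return adata


def annotate_cells(adata: AnnData, marker_map: dict[str, list[str]]) -> pd.Series:
    """Assign each cell the type whose markers have highest mean expression.

    The per-type score is the mean of the log-normalized expression of that
    type's marker genes (markers absent from the panel are ignored; a type
    whose markers are all absent is an error). Ties are broken by
    lexicographic type name and logged.
    """
    if not marker_map:
        raise ValueError("marker_map is empty")
    if LOGNORM_LAYER not in adata.layers:
        normalize_expression(adata)
    Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    types = sorted(marker_map)
    scores = np.zeros((adata.n_obs, len(types)))
    for j, t in enumerate(types):
        mask = adata.var_names.isin(marker_map[t])
        if not mask.any():
            raise ValueError(f"no marker genes of type {t!r} found in the panel")
        scores[:, j] = np.asarray(Y[:, mask].mean(axis=1)).ravel()
    best = scores.argmax(axis=1)  # argmax returns the first (lexicographically smallest) tie
    n_ties = int((np.sum(scores == scores.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.info("annotate_cells: %d cells had tied marker scores (lexicographic tie-break)", n_ties)
    labels = pd.Series([types[b] for b in best], index=adata.obs_names, name="cell_type")
    return labels
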
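"""Radius neighbor graphs and permutation-based spatial statistics.

The neighborhood convention follows the paracrine-signaling range used
throughout: two cells are neighbors when their Euclidean distance is at
most 20 um. Colocalization of two cell types is tested against a null in
which type labels are randomly permuted over the fixed cell positions, so
tissue architecture (density, compartments) is preserved exactly and only
label-position association is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .preprocess import LOGNORM_LAYER

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_UM = 20.0


@dataclass
class NeighborGraph:
    """Radius-based adjacency among the cells of one sample.

    Edges are stored once with ``i < j`` (the graph is undirected and has
    no self-edges); ``dist`` holds the Euclidean distance of each edge.
    """

    sample_id: str
    radius: float
    n_cells: int
    i: np.ndarray
    j: np.ndarray
    dist: np.ndarray
    _adj: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.i)

    def adjacency(self) -> sp.csr_matrix:
        """Boolean symmetric adjacency matrix (cached)."""
        if self._adj is None:
            data = np.ones(2 * self.n_edges, dtype=bool)
            rows = np.concatenate([self.i, self.j])
            cols = np.concatenate([self.j, self.i])
            self._adj = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_cells, self.n_cells)
            )
        return self._adj

    def has_neighbor_of(self, candidate_mask: np.ndarray) -> np.ndarray:
        """For every cell, whether it has >=1 neighbor in ``candidate_mask``."""
        return np.asarray(self.adjacency() @ candidate_mask.astype(np.int64)).ravel() > 0


def build_neighbor_graph(
    cells: pd.DataFrame, radius: float = DEFAULT_RADIUS_UM, sample_id: str | None = None
) -> NeighborGraph:
    """Exact radius query over cell coordinates (um) via a k-d tree.

    Duplicate coordinates are allowed and yield distance-0 edges.
    """
    if len(cells) == 0:
        raise ValueError("cannot build a neighbor graph over zero cells")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite cell coordinates")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dist = np.sqrt(((xy[i] - xy[j]) ** 2).sum(axis=1))
    else:
        i = j = np.empty(0, dtype=int)
        dist = np.empty(0, dtype=float)
    sid = sample_id if sample_id is not None else str(cells["sample_id"].iloc[0])
    return NeighborGraph(sample_id=sid, radius=radius, n_cells=len(cells), i=i, j=j, dist=dist)


@dataclass
class ProximityResult:
    """Observed cross-type neighbor enrichment against a label-permutation null."""

    sample_id: str
    type_pair: tuple[str, str]
    observed_enrichment: float
    null_mean: float
    null_sd: float
    proximity_score: float
    p_raw: float
    p_adj: float | None
    n_perm: int
    seed: int


def _type_masks(cells: pd.DataFrame, type_a: str, type_b: str) -> tuple[np.ndarray, np.ndarray]:
    labels = cells["cell_type"].to_numpy(dtype=object)
    mask_a = labels == type_a
    mask_b = labels == type_b
    if not mask_a.any():
        raise ValueError(f"no cells of type {type_a!r}")
    if not mask_b.any():
        raise ValueError(f"no cells of type {type_b!r}")
    return mask_a, mask_b


def adjacency_fraction(
    graph: NeighborGraph, cells: pd.DataFrame, type_a: str, type_b: str
) -> float:
    """Fraction of ``type_a`` cells with >=1 ``type_b`` neighbor in the graph.

    ``type_a`` must be present (else the fraction is undefined); an absent
    ``type_b`` gives 0.0.
    """
    labels = cells["cell_type"].to_numpy(dtype=object)
    mask_a = labels == type_a
    if not mask_a.any():
        raise ValueError(f"no cells of type {type_a!r}")
    mask_b = labels == type_b
    if not mask_b.any():
        return 0.0
    has_b = graph.has_neighbor_of(mask_b)
    return float(has_b[mask_a].mean())


def adjacency_per_100(
    graph: NeighborGraph, cells: pd.DataFrame, type_a: str, type_b: str
) -> float:
    """Number of ``type_a`` cells adjacent to ``type_b``, per 100 ``type_b`` cells."""
    labels = cells["cell_type"].to_numpy(dtype=object)
    mask_b = labels == type_b
    n_b = int(mask_b.sum())
    if n_b == 0:
        raise ValueError(f"no cells of type {type_b!r}")
    mask_a = labels == type_a
    n_adj = int((graph.has_neighbor_of(mask_b) & mask_a).sum())
    return 100.0 * n_adj / n_b


def _cross_pair_fraction(gi: np.ndarray, gj: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Fraction of graph edges joining one type-a and one type-b cell."""
    ab = (mask_a[gi] & mask_b[gj]) | (mask_b[gi] & mask_a[gj])
    return ab.mean()


def neighborhood_enrichment(
    graph: NeighborGraph,
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> ProximityResult:
    """Permutation test for colocalization of two cell types.

    The observed enrichment is the number of a-b neighbor pairs divided by
    the total number of neighbor pairs in the tissue. The null shuffles the
    full cell-type label vector over the fixed positions ``n_perm`` times;
    the proximity score is observed / null mean, and the one-tailed p-value
    is ``(1 + #{null >= observed}) / (1 + n_perm)`` (add-one so p is never
    zero).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges; enrichment is undefined")
    mask_a, mask_b = _type_masks(cells, type_a, type_b)
    observed = _cross_pair_fraction(graph.i, graph.j, mask_a, mask_b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(graph.n_cells)
    for k in range(n_perm):
        perm = rng.permutation(idx)
        null[k] = _cross_pair_fraction(graph.i, graph.j, mask_a[perm], mask_b[perm])
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else float("nan")
    score = float(observed / null_mean) if null_mean > 0 else float("inf")
    p_raw = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return ProximityResult(
        sample_id=graph.sample_id,
        type_pair=(type_a, type_b),
        observed_enrichment=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        proximity_score=score,
        p_raw=p_raw,
        p_adj=None,
        n_perm=n_perm,
        seed=seed,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MarkerAdjacencyResult:
    """Adjacency enrichment of marker-positive vs marker-negative source cells."""

    marker: str
    source_type: str
    target_type: str
    n_pos: int
    n_neg: int
    p_adjacent_pos: float
    p_adjacent_neg: float
    ratio: float  # +inf when the negative stratum has zero adjacency
    fisher_p: float
    degenerate: bool  # True when a stratum is empty (ratio undefined)
    table: tuple[tuple[int, int], tuple[int, int]]


def marker_adjacency_ratio(
    graph: NeighborGraph,
    cells: pd.DataFrame,
    adata: AnnData,
    source_type: str,
    marker: str,
    target_type: str,
    positivity_threshold: float = 0.0,
) -> MarkerAdjacencyResult:
    """How much more often marker+ source cells sit near the target type.

    Source cells are split on normalized expression of ``marker`` >
    ``positivity_threshold``; the ratio is
    P(adjacent to >=1 target | marker+) / P(adjacent | marker-), with a
    one-sided Fisher exact test on the 2x2 positivity x adjacency table.
    """
    if marker not in adata.var_names:
        raise ValueError(f"marker {marker!r} not in panel")
    labels = cells["cell_type"].to_numpy(dtype=object)
    src = labels == source_type
    if not src.any():
        raise ValueError(f"no cells of type {source_type!r}")
    tgt = labels == target_type
    Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    expr = np.asarray(Y[:, adata.var_names.get_loc(marker)].todense()).ravel()
    pos = expr > positivity_threshold
    adj = graph.has_neighbor_of(tgt)

    pos_src, neg_src = src & pos, src & ~pos
    n_pos, n_neg = int(pos_src.sum()), int(neg_src.sum())
    a = int((pos_src & adj).sum())  # marker+, adjacent
    b = n_pos - a
    c = int((neg_src & adj).sum())  # marker-, adjacent
    d = n_neg - c
    degenerate = n_pos == 0 or n_neg == 0
    p_pos = a / n_pos if n_pos else float("nan")
    p_neg = c / n_neg if n_neg else float("nan")
    if degenerate:
        ratio = float("nan")
        fisher_p = float("nan")
    else:
        ratio = p_pos / p_neg if p_neg > 0 else (float("inf") if p_pos > 0 else float("nan"))
        _, fisher_p = fisher_exact([[a, b], [c, d]], alternative="greater")
    if degenerate:
        logger.warning("marker_adjacency_ratio: empty stratum for %s in %s", marker, source_type)
    return MarkerAdjacencyResult(
        marker=marker,
        source_type=source_type,
        target_type=target_type,
        n_pos=n_pos,
        n_neg=n_neg,
        p_adjacent_pos=p_pos,
        p_adjacent_neg=p_neg,
        ratio=ratio,
        fisher_p=float(fisher_p),
        degenerate=degenerate,
        table=((a, b), (c, d)),
    )


def type_area_fraction(cells: pd.DataFrame, cell_type: str) -> float:
    """Tissue occupancy of a type as a percentage of all cells.

    A cell-count proxy for occupied area: cells of the type / all cells,
    returned as a percentage.
    """
    if len(cells) == 0:
        raise ValueError("no cells")
    return 100.0 * float((cells["cell_type"] == cell_type).mean())
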
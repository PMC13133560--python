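"""Synthetic spatial single-cell cohorts with planted crosstalk structure.

Generates Xenium-style cohorts of nasal-mucosa tissue sections: a targeted
~400-gene panel, nine cell types with epithelial-surface/stromal zonation,
clustered fibroblast networks, CD4+ T cells placed with a controlled
probability of sitting within the 20-um paracrine radius of a fibroblast,
negative-binomial counts, pro-Th2 ligand upregulation in T-adjacent
fibroblasts of the allergic (AR) group, Th2 cytokine expression in T cells
coupled to the ligand score of their nearest fibroblast, and sample-level
clinical severity coupled to the crosstalk score.

The default presets encode the study conditions the analysis is meant to
operate under (group compositions, adjacency fractions, ligand effect
sizes, coupling strengths); ``null_config`` gives a fully exchangeable
tissue with every planted effect switched off, used for calibration of the
permutation machinery.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.spatial import cKDTree

from .preprocess import compute_qc_covariates

logger = logging.getLogger(__name__)

GROUPS = ("AR", "control")

CELL_TYPES = (
    "B",
    "CD4_T",
    "CD8_T",
    "DC",
    "endothelial",
    "epithelial",
    "fibroblast",
    "macrophage",
    "mast",
)

#: canonical marker genes per cell type (CD3E is shared by both T lineages)
MARKER_GENES: dict[str, list[str]] = {
    "epithelial": ["EPCAM", "KRT18", "MUC5AC"],
    "fibroblast": ["COL1A1", "PDGFRA", "DCN"],
    "endothelial": ["PECAM1", "VWF", "CDH5"],
    "macrophage": ["CD68", "CD163", "MRC1"],
    "DC": ["LYZ", "CD1C", "CLEC9A"],
    "mast": ["TPSAB1", "CMA1", "KIT"],
    "B": ["MS4A1", "CD79A", "IGHD"],
    "CD4_T": ["CD3E", "CD4", "FOXP3"],
    "CD8_T": ["CD3E", "CD8A", "GZMB"],
}

PRO_TH2_LIGANDS = ("TSLP", "ICOSL", "OX40L", "CCL17", "POSTN")
CORE_TH2_SET = ("IL4", "IL5", "IL13", "IL9")
MITO_GENES = ("MT-CO1", "MT-ND1", "MT-ATP6", "MT-CYB", "MT-ND4")
#: T-cell receptors for the fibroblast ligands (OX40 = TNFRSF4)
RECEPTOR_GENES = ("IL7R", "TNFRSF4", "ICOS")
N_GATA3_TARGETS = 42
#: total panel size of the targeted assay being emulated
DEFAULT_PANEL_SIZE = 412


# ---------------------------------------------------------------------------
# panel


@dataclass
class PanelManifest:
    """Gene panel with functional roles.

    ``genes`` has columns ``gene_id``, ``role`` (marker / th2_cytokine /
    pro_th2_ligand / gata3_target / mito / background) and ``cell_type``
    (marker genes only, comma-joined when shared).
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.genes["gene_id"]
        if ids.duplicated().any():
            raise ValueError("panel gene ids are not unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def by_role(self, role: str) -> list[str]:
        return list(self.genes.loc[self.genes["role"] == role, "gene_id"])

    @property
    def gata3_targets(self) -> list[str]:
        return self.by_role("gata3_target")

    @property
    def mito_genes(self) -> list[str]:
        return self.by_role("mito")

    @property
    def marker_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        markers = self.genes[self.genes["role"] == "marker"]
        for _, row in markers.iterrows():
            for t in row["cell_type"].split(","):
                out.setdefault(t, []).append(row["gene_id"])
        return out


def generate_panel(n_background: int | None = None, seed: int = 0) -> PanelManifest:
    """Build the gene-panel manifest.

    The role-required genes (markers for the nine cell types, the core Th2
    cytokines, the five pro-Th2 ligands, a 42-member GATA3-target stand-in
    set, mitochondrial genes, the mediator IL33 and the T-cell receptors)
    are always present; ``n_background`` anonymous background genes pad the
    panel (default: up to the 412-gene assay size).
    """
    rows: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for t in CELL_TYPES:
        for g in MARKER_GENES[t]:
            if g in seen:
                # shared marker: extend its cell_type annotation
                for i, (gid, role, ct) in enumerate(rows):
                    if gid == g:
                        rows[i] = (gid, role, ct + "," + t)
                continue
            rows.append((g, "marker", t))
            seen.add(g)
    for g in CORE_TH2_SET:
        rows.append((g, "th2_cytokine", ""))
    for g in PRO_TH2_LIGANDS:
        rows.append((g, "pro_th2_ligand", ""))
    for i in range(N_GATA3_TARGETS):
        rows.append((f"GATA3-TGT-{i + 1:02d}", "gata3_target", ""))
    for g in MITO_GENES:
        rows.append((g, "mito", ""))
    for g in ("IL33", "GATA3", *RECEPTOR_GENES):
        rows.append((g, "background", ""))
    n_required = len(rows)
    if n_background is None:
        n_background = max(0, DEFAULT_PANEL_SIZE - n_required)
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    for i in range(n_background):
        rows.append((f"BG{i + 1:04d}", "background", ""))
    genes = pd.DataFrame(rows, columns=["gene_id", "role", "cell_type"])
    return PanelManifest(genes=genes)


# ---------------------------------------------------------------------------
# configuration


def _per_group(ar, control) -> dict:
    return {"AR": ar, "control": control}


@dataclass
class SimConfig:
    """Tunable parameters of the cohort generator.

    Group-level defaults encode the AR/control study conditions: fibroblast
    occupancy 34.2 +/- 3.1% vs 15.6 +/- 2.4% of cells, CD4 T adjacency to
    fibroblasts 62.3 +/- 4.5% vs 28.7 +/- 3.8%, pro-Th2 ligand log2 effects
    in T-adjacent AR fibroblasts, and a ligand-score -> Th2 coupling with
    clinical severity tracking the sample crosstalk score. Distances are
    um; fractions are in [0, 1].
    """

    n_samples_per_group: int = 10
    cells_per_sample: int = 4800
    tissue_width_um: float = 1000.0
    tissue_height_um: float = 1000.0
    epithelial_band_um: float = 150.0
    zonation: bool = True
    fibroblast_clustering: bool = True
    fibroblast_cluster_size: int = 120
    fibroblast_cluster_sd_um: float = 60.0
    # adjacent CD4 T cells aggregate around a small subset of "niche hub"
    # fibroblasts, concentrating T contact on few stromal cells
    niche_hub_fraction: float = 0.022
    radius_um: float = 20.0

    fibroblast_fraction_by_group: dict = field(default_factory=lambda: _per_group(0.342, 0.156))
    fibroblast_fraction_sd_by_group: dict = field(default_factory=lambda: _per_group(0.031, 0.024))
    # target fraction of CD4 T cells within radius of >=1 fibroblast;
    # None places CD4 T cells uniformly (no attraction, the exchangeable null)
    cd4_adjacency_by_group: dict | None = field(default_factory=lambda: _per_group(0.623, 0.287))
    cd4_adjacency_sd_by_group: dict = field(default_factory=lambda: _per_group(0.045, 0.038))
    epithelial_fraction: float = 0.22
    cd4_fraction_by_group: dict = field(default_factory=lambda: _per_group(0.11, 0.09))
    other_type_weights: dict = field(
        default_factory=lambda: {
            "endothelial": 0.10,
            "macrophage": 0.08,
            "DC": 0.04,
            "mast": 0.03,
            "B": 0.05,
            "CD8_T": 0.06,
        }
    )

    # counts model
    dispersion: float = 0.10  # NB variance = m + dispersion * m^2
    target_transcripts: float = 815.0  # expected non-mito transcripts per cell
    depth_sd: float = 0.16  # lognormal sd of the per-cell depth factor
    debris_fraction: float = 0.04  # cells with collapsed depth (fail QC)
    debris_depth_factor: float = 0.06
    mito_beta: tuple = (2.0, 30.0)  # bulk of the per-cell mito fraction
    mito_outlier_fraction: float = 0.02  # high-mito tail removed by the >20% filter

    # planted effects: AR fibroblasts switch to an "activated" pro-Th2 state
    # with probability depending on T-cell adjacency; activated cells scale
    # their mediator means by 2**log2fc. The per-gene activation effects are
    # calibrated so the AR-vs-control group-level fibroblast log2FC lands on
    # the reported mediator panel (TSLP 1.82 ... POSTN 0.98).
    fibroblast_activation_prob: dict = field(
        default_factory=lambda: {"adjacent": 0.50, "far": 0.010}
    )
    ligand_activation_log2fc: dict = field(
        default_factory=lambda: {
            "TSLP": 4.3,
            "IL33": 4.0,
            "CCL17": 3.6,
            "ICOSL": 3.4,
            "OX40L": 3.2,
            "POSTN": 3.1,
        }
    )
    ligand_group_log2fc: dict = field(default_factory=dict)  # AR-wide fibroblast shift
    th2_coupling_slope_by_group: dict = field(default_factory=lambda: _per_group(0.125, 0.0))
    th2_coupling_noise_sd: float = 0.15

    # clinical coupling: metric = intercept + slope * crosstalk + N(0, noise_sd)
    ige_intercept: float = 10.0
    ige_slope: float = 60.0
    ige_noise_sd: float = 173.0
    spt_intercept: float = 1.5
    spt_slope: float = 1.1
    spt_noise_sd: float = 3.7

    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_sample < 0:
            raise ValueError("cells_per_sample must be >= 0")
        for g, f in self.fibroblast_fraction_by_group.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fibroblast fraction for {g} outside [0, 1]")
        if self.cd4_adjacency_by_group is not None:
            for g, a in self.cd4_adjacency_by_group.items():
                if not 0 <= a <= 1:
                    raise ValueError(f"adjacency fraction for {g} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "mito_beta" in d:
            d["mito_beta"] = tuple(d["mito_beta"])
        return cls(**d)


def null_config(**overrides) -> SimConfig:
    """Exchangeable tissue with every planted effect switched off.

    No zonation or clustering, equal group compositions, uniform CD4 T
    placement, no ligand upregulation, no Th2 or clinical coupling: any
    label-position association arises by chance alone.
    """
    cfg = SimConfig(
        zonation=False,
        fibroblast_clustering=False,
        fibroblast_fraction_by_group=_per_group(0.20, 0.20),
        fibroblast_fraction_sd_by_group=_per_group(0.0, 0.0),
        cd4_adjacency_by_group=None,
        cd4_fraction_by_group=_per_group(0.10, 0.10),
        fibroblast_activation_prob={"adjacent": 0.0, "far": 0.0},
        ligand_activation_log2fc={},
        ligand_group_log2fc={},
        th2_coupling_slope_by_group=_per_group(0.0, 0.0),
        ige_slope=0.0,
        spt_slope=0.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# expression model

_MARKER_MEAN = 10.0
_OFF_MEAN = 0.02
_LIGAND_BASELINE = {"TSLP": 0.07, "ICOSL": 0.15, "OX40L": 0.13, "CCL17": 0.16, "POSTN": 0.30, "IL33": 0.18}
_TH2_BASELINE = {"IL4": 8.0, "IL5": 6.5, "IL13": 7.0, "IL9": 2.0}
_GATA3_MEAN = 8.0
_RECEPTOR_MEAN = {"IL7R": 1.2, "TNFRSF4": 0.8, "ICOS": 0.9}
_RECEPTOR_CD8_MEAN = 0.25
_G3T_T_MEAN = 0.12
_G3T_OFF_MEAN = 0.03
#: log-normal skew of background-gene abundance: a targeted panel detects
#: ~125 of ~412 genes at ~850 transcripts, so a few genes carry most mass
_BG_LOG_SD = 2.1
#: total expected counts carried by the background block, per cell
_BG_TOTAL = 690.0


def _background_relative_mean(gene_id: str) -> float:
    """Deterministic per-gene relative abundance (stable across runs/seeds)."""
    g = np.random.default_rng(zlib.crc32(gene_id.encode()))
    return float(np.exp(_BG_LOG_SD * g.standard_normal()))


_MEANS_CACHE: dict = {}


def baseline_means(panel: PanelManifest, config: SimConfig) -> pd.DataFrame:
    """Per-type expected counts per gene (non-mito), scaled to target depth.

    Background genes get a gene-specific mean shared by every type and
    sample, so between-group contrasts on them are null by construction.
    The result depends only on the panel and the depth target and is cached.
    """
    key = (zlib.crc32("|".join(panel.gene_ids).encode()), float(config.target_transcripts))
    if key in _MEANS_CACHE:
        return _MEANS_CACHE[key]
    genes = [g for g in panel.gene_ids if g not in set(panel.mito_genes)]
    M = pd.DataFrame(_OFF_MEAN, index=genes, columns=list(CELL_TYPES), dtype=float)
    marker_map = panel.marker_map
    for t, markers in marker_map.items():
        for g in markers:
            M.loc[g, t] = _MARKER_MEAN
    for g, m in _LIGAND_BASELINE.items():
        if g in M.index:
            M.loc[g, "fibroblast"] = m
    for g, m in _TH2_BASELINE.items():
        if g in M.index:
            M.loc[g, "CD4_T"] = m
    if "GATA3" in M.index:
        M.loc["GATA3", "CD4_T"] = _GATA3_MEAN
    for g, m in _RECEPTOR_MEAN.items():
        if g in M.index:
            M.loc[g, "CD4_T"] = m
            M.loc[g, "CD8_T"] = _RECEPTOR_CD8_MEAN
    for g in panel.gata3_targets:
        M.loc[g, :] = _G3T_OFF_MEAN
        M.loc[g, "CD4_T"] = _G3T_T_MEAN
    bg = panel.genes.loc[
        (panel.genes["role"] == "background")
        & ~panel.genes["gene_id"].isin(list(_LIGAND_BASELINE) + list(_RECEPTOR_MEAN) + ["GATA3"]),
        "gene_id",
    ].tolist()
    if bg:
        rel = np.array([_background_relative_mean(g) for g in bg])
        M.loc[bg, :] = (_BG_TOTAL * rel / rel.sum())[:, None]
    # scale every type to the same expected library size
    M = M * (config.target_transcripts / M.sum(axis=0))
    _MEANS_CACHE[key] = M
    return M


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# spatial placement


def _stroma_bounds(config: SimConfig) -> tuple[float, float, float, float]:
    top = config.tissue_height_um - (config.epithelial_band_um if config.zonation else 0.0)
    return 0.0, config.tissue_width_um, 0.0, top


def _uniform_points(rng, n, x0, x1, y0, y1) -> np.ndarray:
    return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])


def _place_fibroblasts(rng, n, config: SimConfig) -> np.ndarray:
    x0, x1, y0, y1 = _stroma_bounds(config)
    if y1 <= y0 or x1 <= x0:
        raise ValueError("tissue too small to place cells")
    if not config.fibroblast_clustering:
        return _uniform_points(rng, n, x0, x1, y0, y1)
    n_clusters = max(1, int(round(n / config.fibroblast_cluster_size)))
    centers = _uniform_points(rng, n_clusters, x0, x1, y0, y1)
    assign = rng.integers(0, n_clusters, n)
    pts = centers[assign] + rng.normal(0.0, config.fibroblast_cluster_sd_um, (n, 2))
    pts[:, 0] = np.clip(pts[:, 0], x0, x1)
    pts[:, 1] = np.clip(pts[:, 1], y0, y1)
    return pts


def _place_adjacent(rng, n, fib_xy, radius, bounds, max_rounds=200) -> np.ndarray:
    """Points uniform in a radius-disc around a random fibroblast, inside stroma."""
    x0, x1, y0, y1 = bounds
    out = np.empty((0, 2))
    need = n
    for _ in range(max_rounds):
        if need == 0:
            break
        idx = rng.integers(0, len(fib_xy), need)
        theta = rng.uniform(0, 2 * np.pi, need)
        rad = radius * np.sqrt(rng.uniform(0, 1, need))
        cand = fib_xy[idx] + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
        ok = (cand[:, 0] >= x0) & (cand[:, 0] <= x1) & (cand[:, 1] >= y0) & (cand[:, 1] <= y1)
        out = np.vstack([out, cand[ok]])
        need = n - len(out)
    if need > 0:
        raise ValueError("could not place fibroblast-adjacent cells inside the tissue")
    return out[:n]


def _place_nonadjacent(rng, n, fib_tree, radius, bounds, max_rounds=200) -> np.ndarray:
    """Uniform stroma points with no fibroblast within ``radius``."""
    x0, x1, y0, y1 = bounds
    out = np.empty((0, 2))
    need = n
    for _ in range(max_rounds):
        if need == 0:
            break
        cand = _uniform_points(rng, max(4 * need, 256), x0, x1, y0, y1)
        d, _ = fib_tree.query(cand, k=1, distance_upper_bound=radius)
        out = np.vstack([out, cand[np.isinf(d)]])
        need = max(0, n - len(out))
    if need > 0:
        raise ValueError(
            "could not place fibroblast-distant cells: fibroblast coverage too dense "
            "for the requested adjacency fraction"
        )
    return out[:n]


# ---------------------------------------------------------------------------
# tissue generation


@dataclass
class TissueSample:
    """One simulated tissue section with its ground truth."""

    sample_id: str
    group: str
    cells: pd.DataFrame
    adata: AnnData
    truth: dict = field(default_factory=dict)


def _type_counts(n: int, group: str, config: SimConfig, rng) -> tuple[dict[str, int], float]:
    f_mean = config.fibroblast_fraction_by_group[group]
    f_sd = config.fibroblast_fraction_sd_by_group.get(group, 0.0)
    f_s = float(np.clip(rng.normal(f_mean, f_sd) if f_sd > 0 else f_mean, 0.01, 0.90))
    cd4 = config.cd4_fraction_by_group[group]
    epi = config.epithelial_fraction if config.zonation else config.epithelial_fraction
    counts = {
        "fibroblast": int(round(f_s * n)),
        "epithelial": int(round(epi * n)),
        "CD4_T": int(round(cd4 * n)),
    }
    rest = n - sum(counts.values())
    w = pd.Series(config.other_type_weights, dtype=float)
    w = w / w.sum()
    alloc = (w * rest).round().astype(int)
    alloc.iloc[0] += rest - int(alloc.sum())  # absorb rounding remainder
    counts.update(alloc.to_dict())
    return counts, f_s


def generate_tissue(
    config: SimConfig,
    panel: PanelManifest,
    sample_id: str,
    group: str,
    seed: int,
) -> TissueSample:
    """Generate one tissue section (cell table + genes-in-columns AnnData).

    Placement: epithelial cells in the surface band, fibroblasts as a
    clustered stromal network, other types uniform in the stroma, and CD4+
    T cells split into a fibroblast-adjacent contingent (uniform within the
    paracrine radius of a random niche-hub fibroblast) and a distant
    contingent (rejection-sampled to have no fibroblast within the radius)
    according to the group's planted adjacency fraction.

    Counts: negative binomial around cell-type mean profiles with a
    log-normal per-cell depth factor. AR fibroblasts switch to an activated
    pro-Th2 state with an adjacency-dependent probability; activated cells
    scale their mediator means by ``2**log2fc``. Each CD4+ T cell's Th2
    gene means are scaled by ``exp(slope * L + noise)`` where ``L`` is the
    realized ligand score of its nearest fibroblast within the radius.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n = config.cells_per_sample
    gene_ids = panel.gene_ids
    if n == 0:
        cells = pd.DataFrame(
            columns=[
                "cell_id", "sample_id", "group", "x_um", "y_um", "cell_type",
                "n_genes", "n_transcripts", "pct_mito",
            ]
        )
        adata = AnnData(
            X=sp.csr_matrix((0, len(gene_ids)), dtype=np.int64),
            var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        )
        return TissueSample(sample_id, group, cells, adata)

    counts_by_type, f_s = _type_counts(n, group, config, rng)
    bounds = _stroma_bounds(config)
    x0, x1, y0, y1 = bounds
    if (x1 - x0) * (config.tissue_height_um - y0) < n * 1.0:
        raise ValueError("tissue too small to place the requested number of cells")

    # --- positions -------------------------------------------------------
    fib_xy = _place_fibroblasts(rng, counts_by_type["fibroblast"], config)
    fib_tree = cKDTree(fib_xy) if len(fib_xy) else None

    n_cd4 = counts_by_type["CD4_T"]
    if config.cd4_adjacency_by_group is None or fib_tree is None:
        a_s = float("nan")
        cd4_xy = _uniform_points(rng, n_cd4, *bounds)
    else:
        a_mean = config.cd4_adjacency_by_group[group]
        a_sd = config.cd4_adjacency_sd_by_group.get(group, 0.0)
        a_s = float(np.clip(rng.normal(a_mean, a_sd) if a_sd > 0 else a_mean, 0.01, 0.99))
        n_adj = int(round(a_s * n_cd4))
        # adjacent T cells aggregate around a small subset of hub fibroblasts
        n_hubs = max(1, int(round(config.niche_hub_fraction * len(fib_xy))))
        hubs = rng.choice(len(fib_xy), size=n_hubs, replace=False)
        adj_xy = _place_adjacent(rng, n_adj, fib_xy[hubs], config.radius_um, bounds)
        far_xy = _place_nonadjacent(rng, n_cd4 - n_adj, fib_tree, config.radius_um, bounds)
        cd4_xy = np.vstack([adj_xy, far_xy])

    if config.zonation:
        epi_xy = _uniform_points(
            rng, counts_by_type["epithelial"],
            0.0, config.tissue_width_um,
            config.tissue_height_um - config.epithelial_band_um, config.tissue_height_um,
        )
    else:
        epi_xy = _uniform_points(rng, counts_by_type["epithelial"], *bounds)

    types: list[str] = []
    xys: list[np.ndarray] = []
    for t in CELL_TYPES:
        k = counts_by_type[t]
        if t == "fibroblast":
            xy = fib_xy
        elif t == "CD4_T":
            xy = cd4_xy
        elif t == "epithelial":
            xy = epi_xy
        else:
            xy = _uniform_points(rng, k, *bounds)
        types.extend([t] * k)
        xys.append(xy)
    xy_all = np.vstack(xys)
    type_arr = np.asarray(types, dtype=object)
    n_total = len(type_arr)

    # --- expression ------------------------------------------------------
    M = baseline_means(panel, config)
    nonmito_genes = list(M.index)
    depth = rng.lognormal(-config.depth_sd**2 / 2.0, config.depth_sd, n_total)
    debris = rng.random(n_total) < config.debris_fraction
    depth[debris] *= config.debris_depth_factor

    col_of_type = {t: k for k, t in enumerate(M.columns)}
    type_cols = np.asarray([col_of_type[t] for t in type_arr])
    mean_mat = M.to_numpy()[:, type_cols].T * depth[:, None]  # cells x genes

    # activated pro-Th2 state in AR fibroblasts (adjacency-biased)
    is_fib = type_arr == "fibroblast"
    fib_rows = np.flatnonzero(is_fib)
    activated = np.zeros(len(fib_rows), dtype=bool)
    if group == "AR" and len(fib_rows):
        for g, lfc in config.ligand_group_log2fc.items():
            if g in M.index:
                mean_mat[np.ix_(fib_rows, [nonmito_genes.index(g)])] *= 2.0**lfc
        if config.ligand_activation_log2fc and len(fib_xy):
            if n_cd4 > 0:
                cd4_tree = cKDTree(cd4_xy)
                d, _ = cd4_tree.query(fib_xy, k=1, distance_upper_bound=config.radius_um)
                t_adjacent_fib = np.isfinite(d)
            else:
                t_adjacent_fib = np.zeros(len(fib_xy), dtype=bool)
            p_act = np.where(
                t_adjacent_fib,
                config.fibroblast_activation_prob.get("adjacent", 0.0),
                config.fibroblast_activation_prob.get("far", 0.0),
            )
            activated = rng.random(len(fib_xy)) < p_act
            rows = fib_rows[activated]
            for g, lfc in config.ligand_activation_log2fc.items():
                if g in M.index:
                    mean_mat[np.ix_(rows, [nonmito_genes.index(g)])] *= 2.0**lfc

    # draw all non-CD4 counts first so realized fibroblast ligand scores
    # can drive the T-cell coupling
    X = np.zeros((n_total, len(nonmito_genes)), dtype=np.int64)
    is_cd4 = type_arr == "CD4_T"
    non_cd4 = ~is_cd4
    X[non_cd4] = _nb_draw(rng, mean_mat[non_cd4], config.dispersion)

    # mito counts (needed for the totals entering normalization)
    a_b, b_b = config.mito_beta
    mito_frac = rng.beta(a_b, b_b, n_total)
    outlier = rng.random(n_total) < config.mito_outlier_fraction
    mito_frac[outlier] = rng.uniform(0.25, 0.50, int(outlier.sum()))
    mito_total_mean = mito_frac / (1.0 - mito_frac) * mean_mat.sum(axis=1)
    Xm = rng.poisson(mito_total_mean[:, None] / len(MITO_GENES), (n_total, len(MITO_GENES)))

    # realized ligand score of each CD4 T cell's nearest fibroblast
    lig_cols = [nonmito_genes.index(g) for g in PRO_TH2_LIGANDS]
    L = np.zeros(n_total)
    nearest_fib = np.full(n_total, -1, dtype=int)
    if n_cd4 > 0 and len(fib_xy):
        totals_fib = X[is_fib].sum(axis=1) + Xm[is_fib].sum(axis=1)
        lognorm_fib = np.log1p(
            1e4 * X[np.ix_(is_fib, lig_cols)] / np.maximum(totals_fib, 1)[:, None]
        )
        fib_scores = lognorm_fib.sum(axis=1)
        d, idx = fib_tree.query(cd4_xy, k=1, distance_upper_bound=config.radius_um)
        has_fib = np.isfinite(d)
        cd4_rows = np.flatnonzero(is_cd4)
        L[cd4_rows[has_fib]] = fib_scores[idx[has_fib]]
        nearest_fib[cd4_rows[has_fib]] = fib_rows[idx[has_fib]]

    slope = config.th2_coupling_slope_by_group[group]
    eps = rng.normal(0.0, config.th2_coupling_noise_sd, n_total)
    log_factor = slope * L + eps
    coupled_full = [g for g in CORE_TH2_SET if g in M.index]
    coupled_gata3 = [g for g in ("GATA3",) if g in M.index]
    coupled_half = [g for g in (*panel.gata3_targets, *RECEPTOR_GENES) if g in M.index]
    cd4_rows_all = np.flatnonzero(is_cd4)
    for cols, power in ((coupled_full, 1.0), (coupled_gata3, 0.85), (coupled_half, 0.5)):
        ci = [nonmito_genes.index(g) for g in cols]
        mean_mat[np.ix_(cd4_rows_all, ci)] *= np.exp(power * log_factor[cd4_rows_all])[:, None]
    X[is_cd4] = _nb_draw(rng, mean_mat[is_cd4], config.dispersion)

    # --- assemble --------------------------------------------------------
    col_order = {g: i for i, g in enumerate(nonmito_genes)}
    full = np.zeros((n_total, len(gene_ids)), dtype=np.int64)
    for j, g in enumerate(gene_ids):
        if g in col_order:
            full[:, j] = X[:, col_order[g]]
    for j, g in enumerate(MITO_GENES):
        full[:, gene_ids.index(g)] = Xm[:, j]

    cell_ids = [f"{sample_id}_c{i:05d}" for i in range(n_total)]
    adata = AnnData(
        X=sp.csr_matrix(full),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    qc = compute_qc_covariates(adata, mito_genes=list(MITO_GENES))
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "group": group,
            "x_um": xy_all[:, 0],
            "y_um": xy_all[:, 1],
            "cell_type": type_arr,
            "n_genes": qc["n_genes"].to_numpy(),
            "n_transcripts": qc["n_transcripts"].to_numpy(),
            "pct_mito": qc["pct_mito"].to_numpy(),
        }
    )
    paired = L[is_cd4] > 0
    truth = {
        "n_activated_fibroblasts": int(activated.sum()),
        "fibroblast_fraction": f_s,
        "cd4_adjacency": a_s,
        "counts_by_type": counts_by_type,
        "mean_ligand_score": float(L[is_cd4][paired].mean()) if paired.any() else float("nan"),
        "ligand_scores": L[is_cd4],
        "n_debris": int(debris.sum()),
    }
    return TissueSample(sample_id, group, cells, adata, truth)


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    config: SimConfig, panel: PanelManifest, seed: int | None = None
) -> tuple[list[TissueSample], pd.DataFrame]:
    """Generate an AR + control cohort and its clinical table.

    Per-sample clinical severity is ``intercept + slope * crosstalk +
    Gaussian noise`` (truncated positive), where the crosstalk score is the
    sample's mean realized fibroblast ligand score over CD4 T-fibroblast
    pairs. Deterministic given the seed.
    """
    if config.n_samples_per_group < 1:
        raise ValueError("n_samples_per_group must be >= 1")
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    n_total = 2 * config.n_samples_per_group
    children = ss.spawn(n_total + 1)
    clin_rng = np.random.default_rng(children[-1])

    samples: list[TissueSample] = []
    k = 0
    for group in GROUPS:
        for i in range(config.n_samples_per_group):
            sid = f"{group}_{i + 1:02d}"
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            samples.append(generate_tissue(config, panel, sid, group, sub_seed))
            k += 1

    rows = []
    for s in samples:
        c = s.truth.get("mean_ligand_score", float("nan"))
        c_eff = 0.0 if not np.isfinite(c) else c
        ige = config.ige_intercept + config.ige_slope * c_eff
        spt = config.spt_intercept + config.spt_slope * c_eff
        if config.ige_noise_sd > 0:
            ige += clin_rng.normal(0.0, config.ige_noise_sd)
        if config.spt_noise_sd > 0:
            spt += clin_rng.normal(0.0, config.spt_noise_sd)
        rows.append((s.sample_id, s.group, max(ige, 0.36), max(spt, 0.0)))
        s.truth["crosstalk_score"] = c_eff
    clinical = pd.DataFrame(rows, columns=["sample_id", "group", "serum_IgE", "spt_wheal"])
    return samples, clinical
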
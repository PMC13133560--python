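"""Planted-effect recovery on preset cohorts.

Utilities that generate cohorts under the default (study-condition) presets
and push them through the full analysis path, returning the statistics the
presets were calibrated to: group composition and adjacency, the
adjacency-stratified IL4 fold, the TSLP+ fibroblast adjacency enrichment,
the single-cell ligand-score correlations, and the crosstalk-clinical
correlations. Used by the validation suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import fisher_exact

from . import association, preprocess, scoring, spatial_stats, synthetic_data
from .preprocess import LOGNORM_LAYER
from .synthetic_data import PanelManifest, SimConfig, TissueSample


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _prep(sample: TissueSample):
    """QC, normalize and build the neighbor graph for one sample."""
    cells, adata, _ = preprocess.filter_cells(sample.cells, sample.adata)
    preprocess.normalize_expression(adata)
    graph = spatial_stats.build_neighbor_graph(cells, 20.0, sample.sample_id)
    return cells, adata, graph


def generate_ar_samples(
    config: SimConfig, panel: PanelManifest, n_samples: int, seed: int
) -> list[TissueSample]:
    """AR-group tissue sections with deterministically derived sub-seeds."""
    seeds = _spawn_seeds(seed, n_samples)
    return [
        synthetic_data.generate_tissue(config, panel, f"AR_{i + 1:02d}", "AR", s)
        for i, s in enumerate(seeds)
    ]


def spatial_composition(
    seed: int,
    n_samples_per_group: int = 10,
    cells_per_sample: int = 4800,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Per-sample fibroblast occupancy (% of cells) and CD4 T adjacency (%).

    Generates a full AR + control cohort under the preset, applies QC and
    measures both statistics with the pipeline estimators.
    """
    cfg = config or SimConfig()
    cfg.n_samples_per_group = n_samples_per_group
    cfg.cells_per_sample = cells_per_sample
    panel = synthetic_data.generate_panel()
    samples, _ = synthetic_data.generate_cohort(cfg, panel, seed=seed)
    rows = []
    for s in samples:
        cells, _, _ = preprocess.filter_cells(s.cells, None)
        graph = spatial_stats.build_neighbor_graph(cells, cfg.radius_um, s.sample_id)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "fibroblast_pct": spatial_stats.type_area_fraction(cells, "fibroblast"),
                "cd4_adjacency_pct": 100.0
                * spatial_stats.adjacency_fraction(graph, cells, "CD4_T", "fibroblast"),
            }
        )
    return pd.DataFrame(rows)


def coupling_statistics(
    seed: int,
    n_samples: int = 10,
    cells_per_sample: int = 4800,
    config: SimConfig | None = None,
) -> dict[str, float]:
    """Recover the planted coupling effects from one AR cohort.

    Returns the adjacency-stratified IL4 fold (stratum means pooled over
    samples), the TSLP+/TSLP- fibroblast adjacency enrichment ratio (2x2
    tables summed over samples, with its Fisher p), and the pooled
    single-cell Pearson correlations of the fibroblast ligand score with
    IL4 and GATA3 expression of the paired CD4 T cell.
    """
    cfg = config or SimConfig()
    cfg.cells_per_sample = cells_per_sample
    panel = synthetic_data.generate_panel()
    samples = generate_ar_samples(cfg, panel, n_samples, seed)

    sum_adj = np.zeros(2)  # [adjacent, nonadjacent] IL4 expm1 totals
    n_adj = np.zeros(2, dtype=int)
    table = np.zeros((2, 2), dtype=int)  # TSLP +/- x adjacent yes/no
    lig_all, il4_all, gata3_all = [], [], []
    for s in samples:
        cells, adata, graph = _prep(s)
        con = association.adjacent_expression_contrast(cells, graph, adata, "IL4")
        sum_adj += np.array(
            [con.mean_adjacent * con.n_adjacent, con.mean_nonadjacent * con.n_nonadjacent]
        )
        n_adj += np.array([con.n_adjacent, con.n_nonadjacent])
        mar = spatial_stats.marker_adjacency_ratio(
            graph, cells, adata, "fibroblast", "TSLP", "CD4_T"
        )
        table += np.array(mar.table)
        lig = scoring.fibroblast_ligand_score(cells, graph, adata)
        Y = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
        pos = pd.Series(np.arange(len(cells)), index=cells["cell_id"])
        sel = pos.reindex(lig["t_cell_id"]).to_numpy()
        for gene, acc in (("IL4", il4_all), ("GATA3", gata3_all)):
            col = adata.var_names.get_loc(gene)
            acc.append(np.asarray(Y[sel, col].todense()).ravel())
        lig_all.append(lig["ligand_score"].to_numpy())

    il4_fold = (sum_adj[0] / n_adj[0]) / (sum_adj[1] / n_adj[1])
    (a, b), (c, d) = table
    tslp_ratio = (a / (a + b)) / (c / (c + d))
    _, tslp_p = fisher_exact(table, alternative="greater")
    L = np.concatenate(lig_all)
    r_il4 = association.pearson_correlation(L, np.concatenate(il4_all)).pearson_r
    r_gata3 = association.pearson_correlation(L, np.concatenate(gata3_all)).pearson_r
    return {
        "il4_fold": float(il4_fold),
        "tslp_adjacency_ratio": float(tslp_ratio),
        "tslp_fisher_p": float(tslp_p),
        "ligand_il4_r": float(r_il4),
        "ligand_gata3_r": float(r_gata3),
        "n_pairs": int(len(L)),
    }


def clinical_recovery(
    seed: int,
    n_samples_per_group: int = 15,
    cells_per_sample: int = 4800,
    config: SimConfig | None = None,
) -> dict[str, float]:
    """Sample-level crosstalk vs clinical correlations on a preset cohort.

    Crosstalk scores are recomputed by the pipeline (mean fibroblast ligand
    score over each sample's CD4 T-fibroblast pairs after QC), then
    correlated with the generated serum IgE and SPT wheal values.
    """
    cfg = config or SimConfig()
    cfg.n_samples_per_group = n_samples_per_group
    cfg.cells_per_sample = cells_per_sample
    panel = synthetic_data.generate_panel()
    samples, clinical = synthetic_data.generate_cohort(cfg, panel, seed=seed)
    rows = []
    for s in samples:
        cells, adata, graph = _prep(s)
        lig = scoring.fibroblast_ligand_score(cells, graph, adata)
        cs = scoring.sample_crosstalk_score(lig, s.sample_id)
        rows.append({"sample_id": s.sample_id, "mean_ligand_score": cs.mean_ligand_score})
    scores = pd.DataFrame(rows)
    res = association.clinical_association(scores, clinical)
    return {
        "ige_r": res["serum_IgE"].pearson_r,
        "spt_r": res["spt_wheal"].pearson_r,
        "n_samples": len(scores),
    }
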
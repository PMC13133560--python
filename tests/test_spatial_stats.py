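"""Neighbor graphs, permutation enrichment (vs brute force), BH, Fisher ratios."""

import itertools
import math

import numpy as np
import pytest

from fibrotalk import spatial_stats
from fibrotalk.spatial_stats import (
    adjacency_fraction,
    adjacency_per_100,
    bh_adjust,
    build_neighbor_graph,
    marker_adjacency_ratio,
    neighborhood_enrichment,
    type_area_fraction,
)

from conftest import make_adata, make_cells


class TestNeighborGraph:
    def test_hand_computed_edges(self):
        cells = make_cells([(0, 0), (10, 0), (50, 0)], ["a", "a", "a"])
        g = build_neighbor_graph(cells, radius=20)
        assert g.n_edges == 1
        assert (g.i[0], g.j[0]) == (0, 1)
        assert g.dist[0] == pytest.approx(10.0)

    def test_zero_radius_connects_only_coincident_cells(self):
        cells = make_cells([(0, 0), (0, 0), (1, 0)], ["a", "b", "c"])
        g = build_neighbor_graph(cells, radius=0)
        assert g.n_edges == 1
        assert g.dist[0] == 0.0

    def test_single_cell_graph_is_empty(self):
        g = build_neighbor_graph(make_cells([(0, 0)], ["a"]), radius=20)
        assert g.n_edges == 0

    def test_no_cells_errors(self):
        import pandas as pd

        with pytest.raises(ValueError):
            build_neighbor_graph(make_cells(np.empty((0, 2)), []), radius=20)

    def test_all_edges_within_radius(self, ar_sample):
        _, _, _, g = ar_sample
        assert (g.dist <= g.radius + 1e-12).all()
        assert (g.i < g.j).all()  # stored once, no self-edges


class TestAdjacency:
    def test_hand_case(self):
        cells = make_cells(
            [(0, 0), (10, 0), (100, 0)], ["CD4_T", "fibroblast", "fibroblast"]
        )
        g = build_neighbor_graph(cells, radius=20)
        assert adjacency_fraction(g, cells, "CD4_T", "fibroblast") == 1.0

    def test_absent_partner_gives_zero(self):
        cells = make_cells([(0, 0), (10, 0)], ["CD4_T", "CD4_T"])
        g = build_neighbor_graph(cells, radius=20)
        assert adjacency_fraction(g, cells, "CD4_T", "fibroblast") == 0.0

    def test_absent_source_errors(self):
        cells = make_cells([(0, 0)], ["fibroblast"])
        g = build_neighbor_graph(cells, radius=20)
        with pytest.raises(ValueError):
            adjacency_fraction(g, cells, "CD4_T", "fibroblast")

    def test_per_100_arithmetic(self):
        # 2 adjacent T cells among 50 fibroblasts -> 4.0
        xy = [(i * 5.0, 0.0) for i in range(50)] + [(0, 10), (245, 10), (1000, 1000)]
        types = ["fibroblast"] * 50 + ["CD4_T"] * 3
        cells = make_cells(xy, types)
        g = build_neighbor_graph(cells, radius=20)
        assert adjacency_per_100(g, cells, "CD4_T", "fibroblast") == pytest.approx(4.0)

    def test_per_100_zero_fibroblasts_errors(self):
        cells = make_cells([(0, 0)], ["CD4_T"])
        g = build_neighbor_graph(cells, radius=20)
        with pytest.raises(ValueError):
            adjacency_per_100(g, cells, "CD4_T", "fibroblast")


def exhaustive_enrichment_p(xy, n_a, radius):
    """Brute-force permutation p over all labelings of n_a type-a cells.

    Returns (per-labeling stats, exact one-tailed p for the labeling that
    puts type a on the FIRST n_a positions), where the p-value is the
    proportion of labelings with cross-pair fraction >= the observed one.
    """
    n = len(xy)
    g = build_neighbor_graph(make_cells(xy, ["x"] * n), radius=radius)
    edges = list(zip(g.i, g.j))

    def stat(a_set):
        cross = sum((i in a_set) != (j in a_set) for i, j in edges)
        return cross / len(edges)

    observed = stat(set(range(n_a)))
    stats = [stat(set(c)) for c in itertools.combinations(range(n), n_a)]
    p_exact = np.mean([s >= observed for s in stats])
    return observed, np.mean(stats), p_exact


class TestNeighborhoodEnrichment:
    def test_six_cell_toy_matches_exhaustive_enumeration(self):
        # two type-a cells sit together; compare the MC permutation p and
        # null mean with full enumeration over all C(6,2)=15 labelings
        xy = [(0, 0), (10, 0), (15, 5), (100, 0), (108, 6), (115, 0)]
        types = ["a", "a", "b", "b", "b", "b"]
        cells = make_cells(xy, types)
        g = build_neighbor_graph(cells, radius=20)
        observed, null_mean, p_exact = exhaustive_enrichment_p(xy, 2, 20)
        res = neighborhood_enrichment(g, cells, "a", "b", n_perm=4000, seed=0)
        assert res.observed_enrichment == pytest.approx(observed)
        assert res.null_mean == pytest.approx(null_mean, rel=0.05)
        assert res.p_raw == pytest.approx(p_exact, abs=0.03)

    def test_segregated_types_score_zero(self):
        xy = [(0, 0), (5, 0), (500, 0), (505, 0)]
        cells = make_cells(xy, ["a", "a", "b", "b"])
        g = build_neighbor_graph(cells, radius=20)
        res = neighborhood_enrichment(g, cells, "a", "b", n_perm=200, seed=1)
        assert res.observed_enrichment == 0.0
        assert res.proximity_score == 0.0
        assert res.p_raw > 0.9

    def test_symmetric_in_type_pair(self):
        xy = [(0, 0), (10, 0), (15, 5), (100, 0), (108, 6), (115, 0)]
        cells = make_cells(xy, ["a", "a", "b", "b", "b", "b"])
        g = build_neighbor_graph(cells, radius=20)
        r1 = neighborhood_enrichment(g, cells, "a", "b", n_perm=500, seed=3)
        r2 = neighborhood_enrichment(g, cells, "b", "a", n_perm=500, seed=3)
        assert r1.observed_enrichment == r2.observed_enrichment
        assert r1.p_raw == r2.p_raw

    def test_edgeless_graph_errors(self):
        cells = make_cells([(0, 0), (500, 0)], ["a", "b"])
        g = build_neighbor_graph(cells, radius=20)
        with pytest.raises(ValueError):
            neighborhood_enrichment(g, cells, "a", "b", n_perm=10, seed=0)

    def test_p_never_zero_and_in_range(self, ar_sample):
        _, cells, _, g = ar_sample
        res = neighborhood_enrichment(g, cells, "fibroblast", "CD4_T", n_perm=99, seed=5)
        assert 0 < res.p_raw <= 1
        assert res.p_raw >= 1.0 / 100.0
        assert res.proximity_score > 1.0  # planted colocalization

    def test_planted_colocalization_is_detected(self, ar_sample):
        _, cells, _, g = ar_sample
        res = neighborhood_enrichment(g, cells, "fibroblast", "CD4_T", n_perm=199, seed=7)
        assert res.p_raw == pytest.approx(1.0 / 200.0)


class TestBHAdjust:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_never_decreases_and_caps_at_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=60)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_preserves_input_order(self):
        p = [0.9, 0.001, 0.5, 0.04]
        adj = bh_adjust(p)
        # order of outputs corresponds to order of inputs
        assert adj[1] == adj.min()
        assert adj[0] == adj.max()


def fisher_upper_tail(table):
    """Closed-form one-sided Fisher p: hypergeometric sum over the upper tail."""
    (a, b), (c, d) = table
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += math.comb(row1, k) * math.comb(n - row1, col1 - k) / denom
    return p


class TestMarkerAdjacency:
    def build_dataset(self, n_pos_adj, n_pos_far, n_neg_adj, n_neg_far):
        """Fibroblasts on a line; CD4 T placed next to the 'adjacent' ones."""
        xy, types, marker_counts = [], [], []
        for k, (n_cells, positive, adjacent) in enumerate(
            [(n_pos_adj, 1, True), (n_pos_far, 1, False),
             (n_neg_adj, 0, True), (n_neg_far, 0, False)]
        ):
            for i in range(n_cells):
                x = 100.0 * len(xy)
                xy.append((x, 0.0))
                types.append("fibroblast")
                marker_counts.append(positive)
                if adjacent:
                    xy.append((x, 10.0))
                    types.append("CD4_T")
                    marker_counts.append(0)
        cells = make_cells(xy, types)
        counts = np.zeros((len(xy), 2), dtype=int)
        counts[:, 0] = marker_counts
        counts[:, 1] = 50  # filler gene so totals are nonzero
        adata = make_adata(counts, gene_names=["TSLP", "FILLER"],
                           cell_ids=list(cells.cell_id))
        return cells, adata

    def test_fisher_p_matches_hypergeometric_sum(self):
        # 2x2 table (8,2 / 3,7)
        cells, adata = self.build_dataset(8, 2, 3, 7)
        g = build_neighbor_graph(cells, radius=20)
        res = marker_adjacency_ratio(g, cells, adata, "fibroblast", "TSLP", "CD4_T")
        assert res.table == ((8, 2), (3, 7))
        assert res.ratio == pytest.approx((8 / 10) / (3 / 10))
        assert res.fisher_p == pytest.approx(fisher_upper_tail(((8, 2), (3, 7))), rel=1e-9)

    def test_degenerate_all_positive_flagged(self):
        cells, adata = self.build_dataset(5, 5, 0, 0)
        g = build_neighbor_graph(cells, radius=20)
        res = marker_adjacency_ratio(g, cells, adata, "fibroblast", "TSLP", "CD4_T")
        assert res.degenerate

    def test_infinite_ratio_when_negatives_never_adjacent(self):
        cells, adata = self.build_dataset(4, 0, 0, 6)
        g = build_neighbor_graph(cells, radius=20)
        res = marker_adjacency_ratio(g, cells, adata, "fibroblast", "TSLP", "CD4_T")
        assert res.ratio == np.inf

    def test_missing_marker_errors(self, ar_sample):
        _, cells, adata, g = ar_sample
        with pytest.raises(ValueError):
            marker_adjacency_ratio(g, cells, adata, "fibroblast", "NOPE", "CD4_T")


class TestTypeAreaFraction:
    def test_all_cells_one_type(self):
        cells = make_cells([(0, 0), (1, 1)], ["fibroblast", "fibroblast"])
        assert type_area_fraction(cells, "fibroblast") == 100.0

    def test_arithmetic(self):
        types = ["fibroblast"] * 342 + ["epithelial"] * 658
        cells = make_cells([(i, 0) for i in range(1000)], types)
        assert type_area_fraction(cells, "fibroblast") == pytest.approx(34.2)
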
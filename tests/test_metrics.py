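"""Graph metrics against closed forms and brute-force oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from periconn.adjacency import binarize
from periconn.atlas import default_atlas
from periconn.metrics import (
    betweenness_centrality,
    clustering_coefficients,
    hemispheric_summary,
    hierarchical_complexity,
    neighbourhood_complexity,
    nodal_metric_table,
    node_degrees,
    sensorimotor_slice,
    shortest_path_tallies,
    to_length_graph,
)

from conftest import adjacency_from_edges, random_adjacency
from oracles import (
    brute_betweenness,
    brute_clustering,
    brute_hierarchical_complexity,
    brute_neighbourhood_complexity,
    brute_tallies,
)


def cycle(n, weight=1.0):
    return adjacency_from_edges(n, [(i, (i + 1) % n, weight) for i in range(n)])


def complete(n, weight=1.0):
    return adjacency_from_edges(
        n, [(i, j, weight) for i in range(n) for j in range(i + 1, n)]
    )


class TestDegrees:
    def test_star(self, star_5):
        np.testing.assert_array_equal(node_degrees(star_5), [4, 1, 1, 1, 1])

    def test_empty(self):
        A = adjacency_from_edges(4, [])
        assert node_degrees(A).sum() == 0

    def test_matches_row_count_oracle(self, rng):
        A = random_adjacency(rng, 20, p=0.4)
        expected = [(A.weights[i] > 0).sum() for i in range(20)]
        np.testing.assert_array_equal(node_degrees(A), expected)


class TestShortestPathTallies:
    def test_path_graph(self, path_graph_3):
        tallies = shortest_path_tallies(path_graph_3)
        t = tallies[(0, 2)]
        assert t.rho == 1
        assert t.via == {1: 1}

    def test_four_cycle_opposite_corners(self):
        tallies = shortest_path_tallies(cycle(4))
        assert tallies[(0, 2)].rho == 2
        assert tallies[(0, 2)].via == {1: 1, 3: 1}

    def test_unreachable_pairs_zero(self):
        A = adjacency_from_edges(4, [(0, 1, 1.0)])  # 2, 3 isolated
        tallies = shortest_path_tallies(A)
        assert tallies[(0, 2)].rho == 0

    def test_symmetry_of_rho(self, rng):
        A = random_adjacency(rng, 6, p=0.6)
        tallies = shortest_path_tallies(A)
        for h in range(6):
            for j in range(h + 1, 6):
                assert tallies[(h, j)].rho == tallies[(j, h)].rho

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = random_adjacency(rng, rng.integers(4, 7), p=0.55)
        tallies = shortest_path_tallies(A)
        expected = brute_tallies(A)
        for pair, (rho, via) in expected.items():
            assert tallies[pair].rho == rho
            assert tallies[pair].via == via


class TestBetweenness:
    def test_leaves_are_zero(self, star_5):
        b = betweenness_centrality(star_5)
        np.testing.assert_array_equal(b[1:], 0.0)

    def test_star_center(self, star_5):
        # 12 ordered leaf pairs all pass through the center
        raw = betweenness_centrality(star_5, normalized=False)
        assert raw[0] == pytest.approx(12.0)
        norm = betweenness_centrality(star_5, normalized=True)
        assert norm[0] == pytest.approx(1.0)

    def test_raw_equals_normalized_scaled(self, rng):
        A = random_adjacency(rng, 8, p=0.5)
        raw = betweenness_centrality(A, normalized=False)
        norm = betweenness_centrality(A, normalized=True)
        np.testing.assert_allclose(raw, norm * 7 * 6, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        A = random_adjacency(rng, 7, p=0.6)
        perm = rng.permutation(7)
        B = type(A)(
            tuple(A.labels[i] for i in perm), A.weights[np.ix_(perm, perm)]
        )
        np.testing.assert_allclose(
            betweenness_centrality(B), betweenness_centrality(A)[perm], atol=1e-10
        )

    def test_normalized_needs_three_nodes(self):
        A = adjacency_from_edges(2, [(0, 1, 1.0)])
        with pytest.raises(ValueError):
            betweenness_centrality(A, normalized=True)

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_brute_force(self, seed, normalized):
        rng = np.random.default_rng(100 + seed)
        A = random_adjacency(rng, int(rng.integers(4, 8)), p=0.55)
        got = betweenness_centrality(A, normalized=normalized)
        want = brute_betweenness(A, normalized=normalized)
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestClustering:
    def test_unit_triangle(self, triangle):
        c, cw = clustering_coefficients(triangle)
        np.testing.assert_allclose(c, 1.0)
        assert cw == pytest.approx(1.0)

    def test_star_has_no_closed_triplets(self, star_5):
        c, cw = clustering_coefficients(star_5)
        assert cw == 0.0

    def test_degree_below_two_is_zero(self, path_graph_3):
        c, _ = clustering_coefficients(path_graph_3)
        assert c[0] == 0.0 and c[2] == 0.0

    def test_homogeneous_in_weight_scale(self, rng):
        A = random_adjacency(rng, 8, p=0.6)
        kappa = 3.7
        B = type(A)(A.labels, A.weights * kappa)
        c_a, _ = clustering_coefficients(A)
        c_b, _ = clustering_coefficients(B)
        np.testing.assert_allclose(c_b, kappa * c_a, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_triangle_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        A = random_adjacency(rng, int(rng.integers(4, 8)), p=0.6)
        c, cw = clustering_coefficients(A)
        np.testing.assert_allclose(c, brute_clustering(A), rtol=1e-10)
        assert cw == pytest.approx(c.mean())

    def test_binary_graph_recovers_classic_coefficient(self, rng):
        A = binarize(random_adjacency(rng, 12, p=0.5))
        c, _ = clustering_coefficients(A)
        G = nx.from_numpy_array(A.weights)
        classic = nx.clustering(G)
        np.testing.assert_allclose(c, [classic[i] for i in range(12)], atol=1e-12)

    def test_rescaled_matches_networkx_weighted(self, rng):
        A = random_adjacency(rng, 10, p=0.6)
        c, _ = clustering_coefficients(A, rescale=True)
        G = nx.from_numpy_array(A.weights)
        nxc = nx.clustering(G, weight="weight")
        np.testing.assert_allclose(c, [nxc[i] for i in range(10)], atol=1e-12)


class TestHierarchicalComplexity:
    @pytest.mark.parametrize("G", [cycle(6), complete(5), cycle(8, weight=3.0)])
    def test_regular_graphs_zero(self, G):
        assert hierarchical_complexity(G) == 0.0

    def test_path_graphs_ordered_vs_mixed(self):
        # P4: both degree-2 nodes see sequence (1, 2) -> fully ordered.
        p4 = adjacency_from_edges(4, [(i, i + 1, 1.0) for i in range(3)])
        assert hierarchical_complexity(p4) == 0.0
        # P5: degree-2 sequences mix (1,2) and (2,2) -> R = 1/12 by hand.
        p5 = adjacency_from_edges(5, [(i, i + 1, 1.0) for i in range(4)])
        assert hierarchical_complexity(p5) == pytest.approx(1 / 12)

    def test_isomorphism_invariance(self, rng):
        A = random_adjacency(rng, 8, p=0.5)
        perm = rng.permutation(8)
        B = type(A)(tuple(A.labels[i] for i in perm), A.weights[np.ix_(perm, perm)])
        assert hierarchical_complexity(B) == pytest.approx(hierarchical_complexity(A))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_definition_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        A = random_adjacency(rng, int(rng.integers(4, 9)), p=0.5)
        assert hierarchical_complexity(A) == pytest.approx(
            brute_hierarchical_complexity(A)
        )


class TestNeighbourhoodComplexity:
    def test_regular_graph_all_zero(self):
        nc, mean = neighbourhood_complexity(cycle(6))
        np.testing.assert_array_equal(nc, 0.0)
        assert mean == 0.0

    def test_unique_degree_excluded(self, star_5):
        nc, mean = neighbourhood_complexity(star_5)
        assert np.isnan(nc[0])  # the center's degree class is a singleton
        # the four leaves all see the same sequence (4,)
        np.testing.assert_array_equal(nc[1:], 0.0)

    def test_consistent_with_hierarchical(self, rng):
        for seed in range(10):
            A = random_adjacency(np.random.default_rng(400 + seed), 9, p=0.5)
            nc, _ = neighbourhood_complexity(A)
            k = node_degrees(A)
            D = np.unique(k).size
            total = np.nansum(nc)
            assert hierarchical_complexity(A) == pytest.approx(total / D)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_definition_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        A = random_adjacency(rng, int(rng.integers(4, 9)), p=0.5)
        nc, _ = neighbourhood_complexity(A)
        want = brute_neighbourhood_complexity(A)
        np.testing.assert_allclose(nc, want, equal_nan=True, atol=1e-12)


class TestTables:
    def test_nodal_table_shape_and_slice(self, rng):
        atlas = default_atlas()
        A = random_adjacency(rng, 47, p=0.4)
        A = type(A)(atlas.all_labels, A.weights)
        table = nodal_metric_table(A, "subj1")
        assert len(table) == 47
        sliced = sensorimotor_slice(table, atlas)
        assert len(sliced) == 8
        assert set(sliced["node_label"]) == set(atlas.node_labels)
        # slice values equal lookups in the full table
        full = table.set_index("node_label")
        for _, row in sliced.iterrows():
            assert row["clustering"] == full.loc[row["node_label"], "clustering"]

    def test_slice_missing_label_raises(self, rng):
        atlas = default_atlas()
        table = pd.DataFrame({"subject_id": ["s"], "node_label": ["bogus"]})
        with pytest.raises(KeyError):
            sensorimotor_slice(table, atlas)

    def test_hemispheric_summary_means(self, rng):
        A = random_adjacency(rng, 10, p=0.6)
        table = nodal_metric_table(A, "s1")
        out = hemispheric_summary(table, R=0.42)
        assert out["hierarchical_complexity"] == 0.42
        assert out["betweenness"] == pytest.approx(table["betweenness_raw"].mean())
        for key in ("betweenness", "clustering"):
            col = {"betweenness": "betweenness_raw", "clustering": "clustering"}[key]
            assert table[col].min() <= out[key] <= table[col].max()

    def test_hemispheric_summary_constant_values(self):
        table = pd.DataFrame(
            {
                "subject_id": "s",
                "node_label": [f"n{i}" for i in range(5)],
                "betweenness_raw": 7.0,
                "clustering": 2.0,
                "neighbourhood_complexity": 0.5,
            }
        )
        out = hemispheric_summary(table, R=1.0)
        assert out["betweenness"] == 7.0
        assert out["clustering"] == 2.0
        assert out["neighbourhood_complexity"] == 0.5


def test_length_transform_variants(path_graph_3):
    G_inv = to_length_graph(path_graph_3, "inverse")
    G_unit = to_length_graph(path_graph_3, "unit")
    assert G_inv[0][1]["length"] == 1.0
    assert G_unit[0][1]["length"] == 1.0
    with pytest.raises(ValueError):
        to_length_graph(path_graph_3, "bogus")
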
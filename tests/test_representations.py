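import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from mkmd import (
    ContactNetwork,
    RepresentationConfig,
    betti_numbers,
    cartography_profile,
    centrality_profile,
    extract_all,
    graph_energies,
    heat_content_invariants,
    heat_trace,
    protein_size,
    spectral_density,
)
from mkmd.errors import ConfigurationError, DegenerateInputError
from mkmd.representations import (
    heat_content,
    read_representations_csv,
    write_representations_csv,
)

# ---------------------------------------------------------------------------
# independent oracles


def flag_betti_oracle(net: ContactNetwork, max_dim: int) -> np.ndarray:
    """Homology ranks of the clique complex over Q via signed boundary
    matrices and floating-point rank (no torsion in these tiny cases)."""
    adj = {i: set() for i in range(net.node_count)}
    for i, j in net.edges:
        adj[i].add(j)
        adj[j].add(i)

    def is_clique(nodes):
        return all(b in adj[a] for a, b in itertools.combinations(nodes, 2))

    simplices = [
        sorted(
            tuple(c)
            for c in itertools.combinations(range(net.node_count), k + 1)
            if is_clique(c)
        )
        for k in range(max_dim + 2)
    ]
    ranks = [0] * (max_dim + 2)
    for k in range(1, max_dim + 2):
        if not simplices[k]:
            continue
        index = {s: i for i, s in enumerate(simplices[k - 1])}
        mat = np.zeros((len(simplices[k - 1]), len(simplices[k])))
        for j, s in enumerate(simplices[k]):
            for drop in range(len(s)):
                face = s[:drop] + s[drop + 1 :]
                mat[index[face], j] = (-1) ** drop
        ranks[k] = np.linalg.matrix_rank(mat)
    return np.array(
        [len(simplices[k]) - ranks[k] - ranks[k + 1] for k in range(max_dim + 1)]
    )


def union_find_components(net: ContactNetwork) -> int:
    parent = list(range(net.node_count))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in net.edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(net.node_count)})


# ---------------------------------------------------------------------------


class TestBettiNumbers:
    @pytest.mark.parametrize(
        "fixture, expected",
        [("path5", (1, 0)), ("cycle4", (1, 1)), ("triangle", (1, 0))],
    )
    def test_known_complexes(self, fixture, expected, request):
        net = request.getfixturevalue(fixture)
        np.testing.assert_array_equal(betti_numbers(net, 1), expected)

    def test_matches_boundary_rank_oracle_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            edges = frozenset(
                (i, j)
                for i in range(7)
                for j in range(i + 1, 7)
                if rng.random() < 0.45
            )
            net = ContactNetwork(7, edges)
            np.testing.assert_array_equal(
                betti_numbers(net, 2), flag_betti_oracle(net, 2)
            )

    def test_b0_equals_union_find_components(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            edges = frozenset(
                (i, j)
                for i in range(8)
                for j in range(i + 1, 8)
                if rng.random() < 0.25
            )
            net = ContactNetwork(8, edges)
            assert betti_numbers(net, 0)[0] == union_find_components(net)

    def test_negative_max_dim_raises(self, triangle):
        with pytest.raises(ValueError):
            betti_numbers(triangle, -1)


class TestCentralityProfile:
    def test_star_betweenness_mean(self, star5):
        cfg = RepresentationConfig(
            centrality_measures=("betweenness",), centrality_aggregates=("mean",)
        )
        # exhaustive enumeration: all 6 leaf pairs route through the hub
        assert centrality_profile(star5, cfg)[0] == pytest.approx(0.2)

    def test_complete_graph_degree_sd_zero(self, complete5):
        cfg = RepresentationConfig(
            centrality_measures=("degree",), centrality_aggregates=("mean", "std")
        )
        assert centrality_profile(complete5, cfg)[1] == pytest.approx(0.0)

    def test_single_edge_closeness(self, single_edge):
        cfg = RepresentationConfig(
            centrality_measures=("closeness",), centrality_aggregates=("mean", "std")
        )
        np.testing.assert_allclose(centrality_profile(single_edge, cfg), [1.0, 0.0])

    def test_unknown_measure_raises(self, star5):
        cfg = RepresentationConfig(centrality_measures=("pagerankk",))
        with pytest.raises(ConfigurationError):
            centrality_profile(star5, cfg)


class TestGraphEnergies:
    def test_k2_energies_by_hand(self, single_edge):
        # adjacency eigenvalues +/-1 -> E=2; Laplacian {0,2} with 2m/n=1 -> LE=2
        np.testing.assert_allclose(graph_energies(single_edge), [2.0, 2.0])

    def test_empty_graph_zero(self, edgeless3):
        np.testing.assert_allclose(graph_energies(edgeless3), [0.0, 0.0])


class TestCartography:
    def test_two_cliques_ultra_peripheral(self):
        edges = set()
        for base in (0, 4):
            for i, j in itertools.combinations(range(base, base + 4), 2):
                edges.add((i, j))
        net = ContactNetwork(8, frozenset(edges))
        profile = cartography_profile(net)
        fractions = profile[:7]
        assert fractions.sum() == pytest.approx(1.0)
        # modules = the cliques, all participation 0, no hubs -> role R1
        assert fractions[0] == pytest.approx(1.0)

    def test_role_fractions_sum_to_one(self, random_net):
        assert cartography_profile(random_net)[:7].sum() == pytest.approx(1.0)

    def test_complete_graph_single_module(self, complete5):
        profile = cartography_profile(complete5)
        assert profile[:7].sum() == pytest.approx(1.0)
        assert profile[7] == pytest.approx(0.0, abs=1e-12)  # one module: Q=0

    def test_edgeless_raises(self, edgeless3):
        with pytest.raises(DegenerateInputError):
            cartography_profile(edgeless3)


class TestHeatDescriptors:
    def test_heat_content_series_matches_expm_oracle(self, random_net):
        g = nx.Graph()
        g.add_nodes_from(range(random_net.node_count))
        g.add_edges_from(random_net.edges)
        lap = nx.normalized_laplacian_matrix(
            g, nodelist=range(random_net.node_count)
        ).toarray()
        t = 1e-3
        oracle = expm(-lap * t).sum()
        coeffs = heat_content_invariants(random_net, order=5)
        q0 = heat_content(random_net, 0.0)
        series = q0 + sum(c * t ** (m + 1) for m, c in enumerate(coeffs))
        assert series == pytest.approx(oracle, rel=1e-6)

    def test_heat_trace_at_zero_is_node_count(self, random_net):
        assert heat_trace(random_net, [0.0])[0] == pytest.approx(random_net.node_count)

    def test_heat_trace_large_t_counts_components(self):
        net = ContactNetwork(5, frozenset([(0, 1), (2, 3)]))  # 3 components
        assert heat_trace(net, [200.0])[0] == pytest.approx(3.0, abs=1e-9)

    def test_c4_heat_trace_closed_form(self, cycle4):
        # Laplacian spectrum of the 4-cycle is {0, 2, 2, 4}
        expected = 1 + 2 * math.exp(-2) + math.exp(-4)
        assert heat_trace(cycle4, [1.0])[0] == pytest.approx(expected, abs=1e-12)

    def test_heat_trace_strictly_decreasing(self, random_net):
        values = heat_trace(random_net, [0.0, 0.5, 1.0, 2.0, 5.0])
        assert np.all(np.diff(values) < 0)

    def test_negative_time_raises(self, cycle4):
        with pytest.raises(ValueError):
            heat_trace(cycle4, [-1.0])


class TestSpectralDensity:
    def test_density_integrates_to_one(self, random_net):
        grid = np.linspace(-1.0, 3.0, 600)
        density = spectral_density(random_net, grid)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=0.01)

    def test_edgeless_graph_peaks_at_zero(self, edgeless3):
        grid = np.linspace(0, 2, 50)
        density = spectral_density(edgeless3, grid)
        assert np.argmax(density) == 0

    def test_isomorphic_graphs_identical(self, cycle4):
        relabeled = ContactNetwork(4, frozenset([(1, 2), (2, 3), (0, 3), (0, 1)]))
        grid = np.linspace(0, 2, 50)
        np.testing.assert_allclose(
            spectral_density(cycle4, grid), spectral_density(relabeled, grid)
        )

    def test_bad_bandwidth_raises(self, cycle4):
        with pytest.raises(ValueError):
            spectral_density(cycle4, [0.0, 1.0], bandwidth=0.0)


class TestExtractAll:
    def test_dims_consistent_across_patterns(self, cycle4, random_net):
        cfg = RepresentationConfig()
        a, b = extract_all(cycle4, cfg), extract_all(random_net, cfg)
        assert a.dims == b.dims == cfg.dims

    def test_isomorphism_invariance(self, random_net):
        perm = np.random.default_rng(1).permutation(random_net.node_count)
        edges = frozenset(
            tuple(sorted((int(perm[i]), int(perm[j])))) for i, j in random_net.edges
        )
        twin = ContactNetwork(random_net.node_count, edges)
        cfg = RepresentationConfig()
        a, b = extract_all(random_net, cfg), extract_all(twin, cfg)
        for rep_id in (1, 3, 5, 6, 7, 8):  # label-independent invariants
            np.testing.assert_allclose(a[rep_id], b[rep_id], atol=1e-8)

    def test_cycle_and_path_differ_in_betti(self):
        cycle = ContactNetwork(4, frozenset([(0, 1), (1, 2), (2, 3), (0, 3)]))
        path = ContactNetwork(4, frozenset([(0, 1), (1, 2), (2, 3)]))
        cfg = RepresentationConfig()
        assert not np.array_equal(extract_all(cycle, cfg)[1], extract_all(path, cfg)[1])

    def test_protein_size(self, random_net):
        np.testing.assert_array_equal(protein_size(random_net), [6.0])

    def test_csv_round_trip(self, tmp_path, cycle4, random_net):
        cfg = RepresentationConfig()
        patterns = [extract_all(cycle4, cfg), extract_all(random_net, cfg)]
        path = tmp_path / "reps.csv"
        write_representations_csv(patterns, path, cfg)
        again = read_representations_csv(path)
        for orig, back in zip(patterns, again):
            for rep_id in orig.vectors:
                np.testing.assert_allclose(back[rep_id], orig[rep_id], rtol=1e-12)
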
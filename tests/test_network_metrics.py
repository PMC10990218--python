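import networkx as nx
import numpy as np
import pytest
from scipy import sparse

from _oracles import brute_betweenness, brute_modularity, power_iteration_pagerank
from conftest import random_digraph
from lda2net import (
    TopicNetwork,
    Vocabulary,
    barrat_cc,
    edge_betweenness,
    filter_network,
    modularity,
    node_centralities,
)


class TestNodeCentralities:
    def test_directed_star_degrees(self):
        G = nx.DiGraph()
        for leaf in "abc":
            G.add_edge("hub", leaf, weight=1.0)
        tab = node_centralities(G)
        assert tab.loc["hub", "out_degree"] == 3
        assert tab.loc["hub", "in_degree"] == 0
        assert tab.loc["a", "in_degree"] == 1

    def test_symmetric_two_cycle_pagerank(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=2.0)
        G.add_edge("b", "a", weight=2.0)
        tab = node_centralities(G)
        assert tab["pagerank"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_path_betweenness_counts_the_middle_node(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("b", "c", weight=1.0)
        tab = node_centralities(G)
        assert tab.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_weighted_degree_is_strength(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=2.5)
        G.add_edge("c", "a", weight=1.0)
        tab = node_centralities(G)
        assert tab.loc["a", "weighted_degree"] == pytest.approx(3.5)

    def test_pagerank_sums_to_one(self, planted):
        tab = node_centralities(planted["networks"][0])
        assert tab["pagerank"].sum() == pytest.approx(1.0, abs=1e-8)
        assert (tab.drop(columns="betweenness") >= 0).all().all()

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            node_centralities(nx.DiGraph())


class TestOracleAgreement:
    """Betweenness and PageRank match exhaustive oracles on random graphs."""

    @pytest.mark.parametrize("seed", range(10))
    def test_betweenness_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        G = random_digraph(rng, int(rng.integers(3, 9)))
        node_oracle, edge_oracle = brute_betweenness(G)
        tab = node_centralities(G)
        for n, expected in node_oracle.items():
            assert tab.loc[n, "betweenness"] == pytest.approx(expected, abs=1e-9)
        eb = edge_betweenness(G)
        for e, expected in edge_oracle.items():
            assert eb[e] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_pagerank_matches_power_iteration(self, seed):
        rng = np.random.default_rng(100 + seed)
        G = random_digraph(rng, int(rng.integers(3, 9)))
        oracle = power_iteration_pagerank(G)
        tab = node_centralities(G)
        for n, expected in oracle.items():
            assert tab.loc[n, "pagerank"] == pytest.approx(expected, abs=1e-6)


class TestEdgeBetweenness:
    def test_bridge_edge_has_maximal_score(self, two_triangles):
        eb = edge_betweenness(two_triangles)
        assert max(eb, key=eb.get) == ("c", "x")

    def test_single_edge(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=1.0)
        assert edge_betweenness(G)[("a", "b")] == pytest.approx(1.0)

    def test_complete_symmetric_triangle_is_uniform(self):
        G = nx.DiGraph()
        for a in "abc":
            for b in "abc":
                if a != b:
                    G.add_edge(a, b, weight=1.0)
        eb = edge_betweenness(G)
        assert len(set(round(v, 9) for v in eb.values())) == 1


class TestBarrat:
    def _triangle(self, w_ab, w_bc, w_ca):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=w_ab)
        G.add_edge("b", "c", weight=w_bc)
        G.add_edge("c", "a", weight=w_ca)
        return G

    def test_uniform_triangle_is_fully_clustered(self):
        per_node, global_cc = barrat_cc(self._triangle(1, 1, 1))
        assert per_node.to_numpy() == pytest.approx([1.0, 1.0, 1.0])
        assert global_cc == pytest.approx(1.0)

    def test_path_graph_has_no_triangles(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("b", "c", weight=2.0)
        per_node, global_cc = barrat_cc(G)
        assert (per_node == 0).all()
        assert global_cc == 0.0

    def test_weighted_triangle_nodes_are_saturated(self):
        # every triangle node with exactly two neighbors has coefficient 1,
        # whatever the weights: the weighted term cancels against s_i
        per_node, global_cc = barrat_cc(self._triangle(1.0, 1.0, 2.0))
        assert per_node.to_numpy() == pytest.approx([1.0, 1.0, 1.0])
        assert global_cc == pytest.approx(1.0)

    def test_weighted_hand_formula_with_off_triangle_neighbor(self):
        # triangle a-b-c (w_ab=1, w_ac=2) plus pendant edge a-d (w_ad=3):
        # c_a = (w_ab + w_ac) / (s_a * (k_a - 1)) = 3 / (6 * 2)
        G = self._triangle(1.0, 99.0, 2.0)
        G["b"]["c"]["weight"] = 99.0  # b-c weight does not enter c_a
        G.add_edge("a", "d", weight=3.0)
        per_node, _ = barrat_cc(G)
        assert per_node["a"] == pytest.approx(3.0 / (6.0 * 2.0))
        assert per_node["d"] == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_uniform_weights_reduce_to_unweighted_clustering(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(4, 10))
        und = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        G = nx.DiGraph()
        G.add_nodes_from(und.nodes)
        for u, v in und.edges:
            G.add_edge(u, v, weight=1.0)
        per_node, _ = barrat_cc(G)
        expected = nx.clustering(und)
        for node in und.nodes:
            assert per_node[node] == pytest.approx(expected[node], abs=1e-12)


class TestModularity:
    def test_single_block_is_zero(self, two_triangles):
        nodes = list(two_triangles.nodes)
        assert modularity(two_triangles, [nodes]) == pytest.approx(0.0)

    def test_two_disconnected_triangles_by_component(self):
        G = nx.DiGraph()
        for a, b in [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]:
            G.add_edge(a, b, weight=1.0)
        q = modularity(G, [{"a", "b", "c"}, {"x", "y", "z"}])
        assert q == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_definition_on_random_partitions(self, seed):
        rng = np.random.default_rng(300 + seed)
        G = random_digraph(rng, 7)
        from lda2net.network_metrics import symmetrize

        H = symmetrize(G)
        H.remove_edges_from(nx.selfloop_edges(H))
        nodes = list(H.nodes)
        labels = rng.integers(0, 3, size=len(nodes))
        blocks = [
            {n for n, l in zip(nodes, labels) if l == c}
            for c in range(3)
            if (labels == c).any()
        ]
        q = modularity(H, blocks)
        assert -1.0 <= q <= 1.0
        assert q == pytest.approx(brute_modularity(H, blocks), abs=1e-12)

    def test_invalid_partition_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            modularity(two_triangles, [{"a", "b"}])  # does not cover
        with pytest.raises(ValueError):
            modularity(
                two_triangles,
                [{"a", "b", "c", "x"}, {"x", "y", "z"}],  # overlapping
            )


class TestFilterNetwork:
    def _network(self, n_words=200, n_edges=100, seed=0):
        rng = np.random.default_rng(seed)
        words = [f"w{i:03d}x" for i in range(n_words)]
        vocab = Vocabulary(words)
        rows = rng.integers(0, n_words, n_edges)
        cols = (rows + 1 + rng.integers(0, n_words - 1, n_edges)) % n_words
        vals = rng.uniform(0.1, 1.0, n_edges)
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_words, n_words))
        M = rng.dirichlet(np.ones(n_words), size=1)
        return TopicNetwork(0, A, vocab), M

    def test_top_percentile_node_count(self):
        net, M = self._network()
        kept = filter_network(net, node_pct=1, edge_pct=100, M=M)
        # nodes kept: the top 1% of 200 ranked words = 2 words (up to ties)
        node_cut = np.percentile(M[0], 99)
        assert int((M[0] >= node_cut).sum()) == 2

    def test_identity_at_full_percentiles(self, planted):
        net = planted["networks"][0]
        M = planted["M"]
        out = filter_network(net, 100, 100, M)
        assert (out.adjacency != net.adjacency).nnz == 0

    def test_edge_percentile_rank_and_cut(self):
        net, M = self._network()
        out = filter_network(net, node_pct=100, edge_pct=10, M=M)
        data = net.adjacency.tocoo().data
        cut = np.percentile(data, 90)
        assert out.n_edges == int((data >= cut).sum())

    def test_invalid_percentiles_rejected(self):
        net, M = self._network()
        with pytest.raises(ValueError):
            filter_network(net, 0, 50, M)
        with pytest.raises(ValueError):
            filter_network(net, 50, 101, M)
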
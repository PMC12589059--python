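import networkx as nx
import numpy as np
import pytest

from ddsn.communities import (
    filter_communities,
    hierarchical_communities,
    modularity,
    vertex_similarity,
)
from ddsn.errors import CoverageError, ParameterError, UnknownDrugError
from ddsn.network import SimilarityNetwork
from helpers import network_from_weights


def random_network(rng, n_max=10, p=0.4, w_max=5):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"D{i}" for i in range(n)]
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                weights[(nodes[i], nodes[j])] = int(rng.integers(1, w_max + 1))
    return network_from_weights(weights, extra_nodes=nodes)


class TestVertexSimilarity:
    def test_identical_neighborhoods(self):
        net = network_from_weights(
            {("a", "c"): 2, ("a", "d"): 2, ("b", "c"): 2, ("b", "d"): 2}
        )
        assert vertex_similarity(net, "a", "b") == pytest.approx(1.0)

    def test_orthogonal(self):
        net = network_from_weights({("a", "c"): 1, ("b", "d"): 1})
        assert vertex_similarity(net, "a", "b") == 0.0

    def test_path_interior_hand_value(self):
        # b and c of a-b-c-d: profiles (1, 0 | 1) and (0, 1 | 1) over
        # {a, d, mutual}; cosine = 1 / (sqrt2 * sqrt2) = 1/2.
        net = network_from_weights({("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1})
        assert vertex_similarity(net, "b", "c") == pytest.approx(0.5)
        assert vertex_similarity(net, "a", "b") == pytest.approx(1 / np.sqrt(2))

    def test_symmetry_and_errors(self):
        net = network_from_weights({("a", "b"): 3})
        assert vertex_similarity(net, "a", "b") == vertex_similarity(net, "b", "a")
        with pytest.raises(UnknownDrugError):
            vertex_similarity(net, "a", "zz")


class TestModularity:
    def test_single_cluster_is_zero(self, clique_bridge):
        assert modularity(clique_bridge, [clique_bridge.drugs]) == pytest.approx(0.0)

    def test_singletons_hand_value(self):
        # 3-node path, all singletons: Q = -sum (k_i/2m)^2 = -(1+4+1)/16
        net = network_from_weights({("a", "b"): 1, ("b", "c"): 1})
        q = modularity(net, [{"a"}, {"b"}, {"c"}])
        assert q == pytest.approx(-0.375)

    def test_clique_bridge_hand_value(self, clique_bridge):
        split = [
            {"a1", "a2", "a3", "a4"},
            {"b1", "b2", "b3", "b4"},
        ]
        assert modularity(clique_bridge, split) == pytest.approx(11 / 26)

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_network(rng)
            if not net.weights:  # networkx modularity is undefined on m = 0
                continue
            nodes = sorted(net.drugs)
            k = int(rng.integers(1, len(nodes) + 1))
            labels = rng.integers(0, k, size=len(nodes))
            parts = [
                {n for n, lab in zip(nodes, labels) if lab == c}
                for c in range(k)
            ]
            parts = [p for p in parts if p]
            ours = modularity(net, parts)
            theirs = nx.community.modularity(net.to_networkx(), parts, weight="weight")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_coverage_error(self, clique_bridge):
        with pytest.raises(CoverageError):
            modularity(clique_bridge, [{"a1", "a2"}])


class TestHierarchicalCommunities:
    def test_two_cliques_recovered(self, clique_bridge):
        part = hierarchical_communities(clique_bridge)
        assert sorted(sorted(c) for c in part.clusters) == [
            ["a1", "a2", "a3", "a4"],
            ["b1", "b2", "b3", "b4"],
        ]
        assert part.modularity == pytest.approx(11 / 26)

    def test_triangle_stays_whole(self):
        net = network_from_weights({("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1})
        part = hierarchical_communities(net)
        assert len(part.clusters) == 1
        assert part.modularity == pytest.approx(0.0)

    def test_isolated_nodes_never_merge(self):
        net = network_from_weights({}, extra_nodes=["x", "y"])
        part = hierarchical_communities(net)
        assert part.sizes == (1, 1)

    def test_empty_network_rejected(self):
        with pytest.raises(ParameterError):
            hierarchical_communities(SimilarityNetwork(drugs=frozenset()))

    def test_deterministic(self):
        rng = np.random.default_rng(17)
        net = random_network(rng, n_max=12)
        p1 = hierarchical_communities(net, seed=0)
        p2 = hierarchical_communities(net, seed=99)
        assert p1.clusters == p2.clusters
        assert p1.modularity == p2.modularity

    def test_partition_covers_all_drugs(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            net = random_network(rng)
            part = hierarchical_communities(net)
            union = set().union(*part.clusters)
            assert union == set(net.drugs)
            assert sum(part.sizes) == len(net.drugs)

    def test_numbering_by_descending_size(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            net = random_network(rng)
            part = hierarchical_communities(net)
            assert list(part.sizes) == sorted(part.sizes, reverse=True)

    def test_cut_is_modularity_optimal_vs_exhaustive(self):
        """The chosen dendrogram cut attains the maximum Q over all cuts,
        with Q independently recomputed via networkx on every prefix."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            net = random_network(rng, n_max=10)
            if not net.weights:  # Q ≡ 0 on an edgeless graph; nothing to cut
                continue
            part = hierarchical_communities(net)
            g = net.to_networkx()
            dend = part.dendrogram
            all_q = [
                nx.community.modularity(
                    g, [set(c) for c in dend.partition_at(k)], weight="weight"
                )
                for k in range(len(dend.merges) + 1)
            ]
            assert part.modularity == pytest.approx(max(all_q), abs=1e-9)
            assert part.modularity == pytest.approx(all_q[part.cut], abs=1e-12)

    def test_no_merge_across_components(self):
        net = network_from_weights(
            {("a", "b"): 5, ("c", "d"): 5}  # two separate dumbbells
        )
        part = hierarchical_communities(net)
        for cluster in part.clusters:
            assert cluster in ({"a", "b"}, {"c", "d"})


class TestFilterCommunities:
    def test_roster_34_to_12(self):
        """The documented exclusion rules leave 12 of 34 communities."""
        from ddsn.synthetic import cluster_roster_example

        net, part = cluster_roster_example()
        filtered = filter_communities(part, net, min_size=8, require_main_component=True)
        assert len(filtered.clusters) == 12
        reasons = sorted(e.reason for e in filtered.excluded)
        assert reasons.count("disconnected") == 16
        assert reasons.count("too-small") == 6

    def test_identity_when_all_pass(self, clique_bridge):
        part = hierarchical_communities(clique_bridge)
        filtered = filter_communities(part, clique_bridge, min_size=4)
        assert filtered.clusters == part.clusters
        assert filtered.excluded == ()

    def test_noop_filter(self, clique_bridge):
        part = hierarchical_communities(clique_bridge)
        filtered = filter_communities(
            part, clique_bridge, min_size=1, require_main_component=False
        )
        assert filtered.clusters == part.clusters

    def test_min_size_validated(self, clique_bridge):
        part = hierarchical_communities(clique_bridge)
        with pytest.raises(ParameterError):
            filter_communities(part, clique_bridge, min_size=0)

    def test_survivors_renumbered_by_size(self):
        from ddsn.synthetic import cluster_roster_example

        net, part = cluster_roster_example()
        filtered = filter_communities(part, net)
        assert list(filtered.sizes) == sorted(filtered.sizes, reverse=True)
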
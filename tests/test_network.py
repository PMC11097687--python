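"""Time-free correlation network: weights, argmin links, hubs."""

import numpy as np
import pytest

from vilinet import (
    CorrelationNetwork,
    InjuryNode,
    ModelParams,
    build_network,
    in_degree_distribution,
    pagerank_centrality,
    pairwise_weight,
    threshold_network,
    top_fraction,
)
from vilinet.types import DegenerateGeometryError, InvalidParameterError

from conftest import brute_force_parents


def node(i, r, c, m):
    return InjuryNode(id=i, centroid_row=r, centroid_col=c, area_m=m)


class TestPairwiseWeight:
    def test_hand_evaluation(self):
        # l=5, df=2, m=4, alpha=2, C=1, dm=1 -> 25/16
        w = pairwise_weight(
            node(0, 0, 0, 4), node(1, 3, 4, 1), ModelParams(alpha=2, df=2)
        )
        assert w == pytest.approx(1.5625)

    def test_df_zero_removes_distance(self):
        params = ModelParams(alpha=2, df=0)
        w1 = pairwise_weight(node(0, 0, 0, 4), node(1, 0, 7, 1), params)
        w2 = pairwise_weight(node(0, 0, 0, 4), node(1, 0, 900, 1), params)
        assert w1 == w2 == pytest.approx(1 / 16)

    def test_scaling_constant_is_linear(self):
        a, b = node(0, 0, 0, 4), node(1, 3, 4, 1)
        w1 = pairwise_weight(a, b, ModelParams(alpha=2, df=2, C=1))
        w2 = pairwise_weight(a, b, ModelParams(alpha=2, df=2, C=2))
        assert w2 == pytest.approx(2 * w1)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            pairwise_weight(
                node(0, 1, 1, 4), node(1, 1, 1, 2), ModelParams(alpha=2, df=2)
            )


class TestBuildNetwork:
    def test_collinear_chain(self):
        # spacing 1 and 2, equal areas: ends link to the middle; the middle
        # links to its nearer neighbor
        nodes = [node(0, 0, 0, 10), node(1, 0, 1, 10), node(2, 0, 3, 10)]
        net = build_network(nodes, ModelParams(alpha=2, df=2))
        parents = {c: p for c, p, _ in net.edges}
        assert parents == {0: 1, 2: 1, 1: 0}

    def test_two_nodes_mutual_parents(self):
        nodes = [node(0, 0, 0, 10), node(1, 0, 5, 20)]
        net = build_network(nodes, ModelParams(alpha=2, df=2))
        parents = {c: p for c, p, _ in net.edges}
        assert parents == {0: 1, 1: 0}

    def test_single_node_trivial(self):
        net = build_network([node(0, 0, 0, 10)], ModelParams(alpha=2, df=2))
        assert net.edges == [] and net.root_ids == [0]

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_matches_brute_force(self, seed, random_nodes):
        rng = np.random.default_rng(seed)
        nodes = random_nodes(int(rng.integers(2, 51)), seed=seed)
        params = ModelParams(alpha=2.2, df=1.7)
        net = build_network(nodes, params)
        assert [(c, p) for c, p, _ in net.edges] == brute_force_parents(
            nodes, params
        )

    def test_tie_breaks_prefer_larger_parent(self):
        # two candidate parents at the same distance with equal weights
        # except for area: the larger-area parent wins
        nodes = [
            node(0, 0, 0, 100),
            node(1, 0, 10, 100),
            node(2, 0, 5, 50),  # equidistant from both ends
        ]
        params = ModelParams(alpha=0.0 + 2.0, df=0)  # df=0: distance drops out
        # with df=0 weight depends only on area: both ends weight equally
        net = build_network(nodes, params)
        parents = {c: p for c, p, _ in net.edges}
        assert parents[2] in (0, 1)
        assert parents[2] == 0  # equal areas -> smaller id

    def test_argmin_invariant_to_global_rescaling(self, random_nodes):
        nodes = random_nodes(40, seed=3)
        p1 = ModelParams(alpha=2.5, df=1.8, C=1.0, delta_m=1.0)
        p2 = ModelParams(alpha=2.5, df=1.8, C=7.3, delta_m=0.2)
        e1 = [(c, p) for c, p, _ in build_network(nodes, p1).edges]
        e2 = [(c, p) for c, p, _ in build_network(nodes, p2).edges]
        assert e1 == e2
        scaled = [
            InjuryNode(n.id, 3.7 * n.centroid_row, 3.7 * n.centroid_col,
                       n.area_m)
            for n in nodes
        ]
        e3 = [(c, p) for c, p, _ in build_network(scaled, p1).edges]
        assert e1 == e3


class TestThresholdNetwork:
    def _net(self, weights):
        nodes = [node(i, 0, i + 1, 10) for i in range(len(weights) + 1)]
        edges = [(i, len(weights), w) for i, w in enumerate(weights)]
        return CorrelationNetwork(nodes=nodes, edges=edges, root_ids=[])

    def test_full_percentile_keeps_all(self):
        net = self._net([1.0, 2.0, 3.0, 4.0])
        assert len(threshold_network(net, 100).edges) == 4

    def test_zero_percentile_keeps_minimum(self):
        net = self._net([1.0, 2.0, 3.0, 4.0])
        kept = threshold_network(net, 0).edges
        assert [w for _, _, w in kept] == [1.0]

    def test_midpoint_interpolation_convention(self):
        net = self._net([1.0, 2.0, 3.0, 4.0])
        kept = threshold_network(net, 50).edges
        assert sorted(w for _, _, w in kept) == [1.0, 2.0]

    def test_monotone_in_percentile(self, random_nodes):
        nodes = random_nodes(60, seed=8)
        net = build_network(nodes, ModelParams(alpha=2.0, df=1.5))
        counts = [
            len(threshold_network(net, pct).edges)
            for pct in (0, 10, 25, 50, 75, 90, 100)
        ]
        assert counts == sorted(counts)
        assert counts[-1] == len(net.edges)

    def test_hubs_gain_links_preferentially(self, random_nodes):
        # rich-get-richer signature: as the threshold percentile rises and
        # more correlations are admitted, the top-in-degree node gains more
        # of them than a typical node does
        gains_hub, gains_rest = [], []
        for seed in range(5):
            nodes = random_nodes(150, seed=seed)
            net = build_network(nodes, ModelParams(alpha=2.0, df=1.8))
            deg = in_degree_distribution(net)
            hub = net.nodes[int(np.argmax(deg))].id
            thin = threshold_network(net, 25)

            def gain(nid, full=net, cut=thin):
                before = sum(1 for _, p, _ in cut.edges if p == nid)
                after = sum(1 for _, p, _ in full.edges if p == nid)
                return after - before
            gains_hub.append(gain(hub))
            rest = [gain(n.id) for n in net.nodes if n.id != hub]
            gains_rest.append(np.mean(rest))
        assert np.mean(gains_hub) > np.mean(gains_rest)


class TestInDegrees:
    def test_star(self):
        nodes = [node(i, 0, i + 1, 10) for i in range(5)] + [node(5, 1, 3, 10)]
        edges = [(i, 5, 1.0) for i in range(5)]
        net = CorrelationNetwork(nodes=nodes, edges=edges, root_ids=[5])
        deg = in_degree_distribution(net)
        assert deg[5] == 5 and list(deg[:5]) == [0] * 5
        assert deg.sum() == len(net.edges)

    def test_two_node_symmetry(self):
        nodes = [node(0, 0, 0, 10), node(1, 0, 5, 10)]
        net = build_network(nodes, ModelParams(alpha=2, df=2))
        assert list(in_degree_distribution(net)) == [1, 1]


class TestPageRank:
    def test_edgeless_uniform(self):
        nodes = [node(i, 0, i + 1, 10) for i in range(8)]
        net = CorrelationNetwork(nodes=nodes, edges=[], root_ids=[0])
        scores = pagerank_centrality(net)
        assert all(v == pytest.approx(1 / 8) for v in scores.scores.values())

    def test_directed_cycle_uniform(self):
        nodes = [node(i, 0, i + 1, 10) for i in range(3)]
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0)]
        net = CorrelationNetwork(nodes=nodes, edges=edges, root_ids=[])
        scores = pagerank_centrality(net)
        assert all(
            v == pytest.approx(1 / 3, abs=1e-9) for v in scores.scores.values()
        )

    def test_sum_and_lower_bound(self, random_nodes):
        nodes = random_nodes(50, seed=5)
        net = build_network(nodes, ModelParams(alpha=2.3, df=1.6))
        scores = pagerank_centrality(net, damping=0.85)
        values = np.array(list(scores.scores.values()))
        assert values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(values >= (1 - 0.85) / len(nodes) - 1e-12)

    def test_invalid_damping(self):
        net = CorrelationNetwork(nodes=[node(0, 0, 0, 1)], edges=[],
                                 root_ids=[0])
        with pytest.raises(InvalidParameterError):
            pagerank_centrality(net, damping=1.0)


class TestTopFraction:
    def _scores(self, values):
        from vilinet.types import CentralityScores

        return CentralityScores(scores={i: v for i, v in enumerate(values)})

    def test_fraction_one_returns_all(self):
        s = self._scores([0.5, 0.3, 0.2])
        assert top_fraction(s, 1.0) == {0, 1, 2}

    def test_half_percent_of_200_is_one(self):
        s = self._scores(np.linspace(1, 0, 200))
        assert top_fraction(s, 0.005) == {0}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.random(50)
        s1 = self._scores(values)
        from vilinet.types import CentralityScores

        shuffled = list(enumerate(values))
        rng.shuffle(shuffled)
        s2 = CentralityScores(scores=dict(shuffled))
        assert top_fraction(s1, 0.1) == top_fraction(s2, 0.1)
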
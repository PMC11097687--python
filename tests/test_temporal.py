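"""Simulated event times, time-extended network, aftershock rates."""

import numpy as np
import pytest

from vilinet import (
    CorrelationNetwork,
    InjuryNode,
    ModelParams,
    assign_times,
    build_time_network,
    centrality_overlap,
    compare_gamma,
    ensemble_run,
    pagerank_centrality,
    secondary_event_rates,
)
from vilinet.types import (
    CentralityScores,
    InvalidInputError,
    InvalidParameterError,
    PowerLawFit,
)

from conftest import brute_force_timed_parents


def node(i, r, c, m):
    return InjuryNode(id=i, centroid_row=r, centroid_col=c, area_m=m)


PARAMS = ModelParams(alpha=2.0, df=1.8)


class TestAssignTimes:
    def test_single_event(self):
        asg = assign_times([node(0, 0, 0, 10)], seed=0)
        assert len(asg.times) == 1 and list(asg.times.values())[0] > 0

    def test_times_increase_along_order(self):
        nodes = [node(i, 0, i + 1, 10) for i in range(50)]
        asg = assign_times(nodes, seed=3)
        ts = [asg.times[int(i)] for i in asg.order]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_mean_interval_calibration(self):
        nodes = [node(i, 0, i + 1, 10) for i in range(10_001)]
        asg = assign_times(nodes, mean_interval_s=2.0, seed=11)
        ts = np.sort(np.fromiter(asg.times.values(), float))
        intervals = np.diff(ts)
        assert abs(intervals.mean() - 2.0) <= 0.06  # 3*sigma/sqrt(n)

    def test_invalid_mean(self):
        with pytest.raises(InvalidParameterError):
            assign_times([node(0, 0, 0, 1)], mean_interval_s=0.0)

    def test_empty(self):
        asg = assign_times([], seed=0)
        assert asg.times == {} and len(asg.order) == 0


class TestBuildTimeNetwork:
    def test_two_events_later_links_to_earlier(self):
        nodes = [node(0, 0, 0, 10), node(1, 0, 5, 10)]
        asg = assign_times(nodes, seed=1)
        net = build_time_network(nodes, asg, PARAMS)
        first = int(asg.order[0])
        assert net.root_ids == [first]
        assert len(net.edges) == 1
        child, parent, _ = net.edges[0]
        assert parent == first and child == int(asg.order[1])

    def test_equidistant_equal_sizes_link_to_predecessor(self):
        # equilateral triangle, equal areas: t_ij alone decides -> each
        # event links to the one just before it
        nodes = [
            node(0, 0.0, 0.0, 10),
            node(1, 0.0, 2.0, 10),
            node(2, np.sqrt(3), 1.0, 10),
        ]
        asg = assign_times(nodes, seed=7)
        net = build_time_network(nodes, asg, PARAMS)
        order = [int(i) for i in asg.order]
        parents = {c: p for c, p, _ in net.edges}
        assert parents[order[1]] == order[0]
        assert parents[order[2]] == order[1]

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_matches_brute_force(self, seed, random_nodes):
        rng = np.random.default_rng(seed)
        nodes = random_nodes(int(rng.integers(2, 31)), seed=seed)
        asg = assign_times(nodes, seed=seed + 1)
        net = build_time_network(nodes, asg, PARAMS)
        assert [(c, p) for c, p, _ in net.edges] == brute_force_timed_parents(
            nodes, asg.times, PARAMS
        )

    def test_single_root_and_edge_count(self, random_nodes):
        nodes = random_nodes(40, seed=2)
        asg = assign_times(nodes, seed=5)
        net = build_time_network(nodes, asg, PARAMS)
        assert len(net.root_ids) == 1
        assert len(net.edges) == len(nodes) - 1

    def test_causality(self, random_nodes):
        nodes = random_nodes(40, seed=9)
        asg = assign_times(nodes, seed=10)
        net = build_time_network(nodes, asg, PARAMS)
        assert all(
            asg.times[c] > asg.times[p] for c, p, _ in net.edges
        )


class TestEnsembleRun:
    def test_reproducible(self, random_nodes):
        nodes = random_nodes(25, seed=4)
        e1 = ensemble_run(nodes, PARAMS, n_reps=3, seed=42,
                          fit_in_degrees=False)
        e2 = ensemble_run(nodes, PARAMS, n_reps=3, seed=42,
                          fit_in_degrees=False)
        for (a1, n1, _), (a2, n2, _) in zip(e1, e2):
            assert a1.times == a2.times
            assert n1.edges == n2.edges

    def test_single_rep_matches_direct_build(self, random_nodes):
        nodes = random_nodes(20, seed=6)
        from vilinet.temporal import replicate_seeds

        (asg, net, _), = ensemble_run(nodes, PARAMS, n_reps=1, seed=9,
                                      fit_in_degrees=False)
        rng = replicate_seeds(9, 1)[0]
        asg2 = assign_times(nodes, 2.0, rng)
        assert asg.times == asg2.times
        net2 = build_time_network(nodes, asg2, PARAMS)
        assert net.edges == net2.edges


def _fit(alpha):
    return PowerLawFit(alpha_hat=alpha, xmin_hat=1.0, n_tail=100, ks_D=0.02,
                       variant="discrete", xmin_fixed=True, p_value=0.5)


class TestCompareGamma:
    def test_identical_fits_null(self):
        res = compare_gamma(_fit(2.0), [_fit(2.0)] * 20, n_boot=1000, seed=0)
        assert res["difference"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_shifted_ensemble_ci_excludes_zero(self):
        rng = np.random.default_rng(1)
        fits = [_fit(3.0 + rng.normal(0, 0.05)) for _ in range(30)]
        res = compare_gamma(_fit(2.0), fits, n_boot=1000, seed=0)
        assert res["ci_low"] > 0

    def test_single_replicate_flagged(self):
        res = compare_gamma(_fit(2.0), [_fit(2.5)], n_boot=100, seed=0)
        assert "degenerate-ci" in res["flags"]


class TestCentralityOverlap:
    def _scores(self, values):
        return CentralityScores(scores={i: float(v) for i, v in enumerate(values)})

    def test_identical_scores_full_overlap(self):
        rng = np.random.default_rng(0)
        base = self._scores(rng.random(200))
        res = centrality_overlap(base, [base] * 3, top_frac_no_time=0.01,
                                 top_frac_time_grid=np.array([0.01, 0.5, 1.0]),
                                 n_boot=100, seed=1)
        assert np.all(res["mean"] == 1.0)

    def test_full_fraction_is_always_one(self):
        rng = np.random.default_rng(2)
        base = self._scores(rng.random(100))
        other = self._scores(rng.random(100))
        res = centrality_overlap(base, [other], top_frac_no_time=0.05,
                                 top_frac_time_grid=np.array([1.0]),
                                 n_boot=100, seed=1)
        assert res["mean"][0] == 1.0

    def test_overlap_nondecreasing_in_fraction(self):
        rng = np.random.default_rng(3)
        base = self._scores(rng.random(300))
        ens = [self._scores(rng.random(300)) for _ in range(5)]
        grid = np.linspace(0.02, 1.0, 25)
        res = centrality_overlap(base, ens, top_frac_no_time=0.02,
                                 top_frac_time_grid=grid, n_boot=100, seed=4)
        assert np.all(np.diff(res["mean"]) >= -1e-12)

    def test_mismatched_ids_rejected(self):
        a = self._scores([0.1, 0.2])
        b = CentralityScores(scores={5: 0.3, 6: 0.7})
        with pytest.raises(InvalidInputError):
            centrality_overlap(a, [b])

    def test_permuted_scores_track_chance_line(self):
        rng = np.random.default_rng(8)
        n = 400
        base_values = rng.random(n)
        base = self._scores(base_values)
        perms = []
        for _ in range(50):
            perms.append(self._scores(rng.permutation(base_values)))
        grid = np.array([0.1, 0.25, 0.5])
        res = centrality_overlap(base, perms, top_frac_no_time=0.01,
                                 top_frac_time_grid=grid, n_boot=100, seed=9)
        k = 4  # ceil(0.01 * 400)
        for f, m in zip(grid, res["mean"]):
            se = np.sqrt(f * (1 - f) / (k * len(perms)))
            assert abs(m - f) <= 3 * se + 1e-9


class TestSecondaryEventRates:
    def test_omori_style_hand_example(self):
        nodes = [node(0, 0, 0, 100)] + [
            node(i, 0, i * 3.0, 100) for i in range(1, 5)
        ]
        times = {0: 0.0, 1: 1.0, 2: 2.0, 3: 4.0, 4: 8.0}
        from vilinet.types import TemporalAssignment

        asg = TemporalAssignment(order=np.array([0, 1, 2, 3, 4]),
                                 times=times, mean_interval_s=2.0)
        edges = [(i, 0, 1.0) for i in range(1, 5)]
        net = CorrelationNetwork(nodes=nodes, edges=edges, root_ids=[0])
        curves = secondary_event_rates(
            [net], [asg], bin_edges=np.array([1.0, 2.0, 4.0, 8.0, 16.0]),
            n_boot=100, seed=0,
        )
        agg = curves[-1]
        assert agg.magnitude_class == "all"
        np.testing.assert_allclose(agg.rate_per_s, [1, 0.5, 0.25, 0.125])
        # log-log slope of the decay is -1 (Omori-like with p = 1)
        centers = np.sqrt(agg.bin_edges_s[:-1] * agg.bin_edges_s[1:])
        slope = np.polyfit(np.log(centers), np.log(agg.rate_per_s), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_no_edges_zero_rates(self):
        nodes = [node(0, 0, 0, 10)]
        from vilinet.types import TemporalAssignment

        asg = TemporalAssignment(order=np.array([0]), times={0: 1.0},
                                 mean_interval_s=2.0)
        net = CorrelationNetwork(nodes=nodes, edges=[], root_ids=[0])
        curves = secondary_event_rates([net], [asg], n_boot=10, seed=0)
        assert all(np.all(c.rate_per_s == 0) for c in curves)

    def test_counts_conserved_across_bins(self, random_nodes):
        nodes = random_nodes(60, seed=12)
        ens = ensemble_run(nodes, PARAMS, n_reps=4, seed=3,
                           fit_in_degrees=False)
        nets = [n for _, n, _ in ens]
        asgs = [a for a, _, _ in ens]
        curves = secondary_event_rates(nets, asgs, n_boot=100, seed=1)
        agg = curves[-1]
        total_edges = sum(len(n.edges) for n in nets)
        assert agg.n_events == total_edges
        # mean rate * width summed over bins * n_reps recovers the count
        widths = np.diff(agg.bin_edges_s)
        recovered = (agg.rate_per_s * widths).sum() * len(nets)
        assert recovered == pytest.approx(total_edges)

    def test_larger_magnitude_class_has_higher_rates(self):
        # parents of magnitude 3 attract more children than magnitude 2
        rng = np.random.default_rng(5)
        nodes = []
        for i in range(120):
            area = 1000.0 if i < 110 else 100_000.0
            nodes.append(node(i, float(rng.uniform(0, 300)),
                              float(rng.uniform(0, 300)), area))
        ens = ensemble_run(nodes, ModelParams(alpha=2.0, df=1.8), n_reps=10,
                           seed=6, fit_in_degrees=False)
        curves = secondary_event_rates([n for _, n, _ in ens],
                                       [a for a, _, _ in ens],
                                       n_boot=100, seed=2)
        by_class = {c.magnitude_class: c for c in curves}
        assert 3 in by_class and 5 in by_class
        lo, hi = by_class[3], by_class[5]
        # compare matched bins where both classes have events
        both = (lo.rate_per_s > 0) & (hi.rate_per_s > 0)
        assert both.any()
        assert hi.rate_per_s[both].mean() > lo.rate_per_s[both].mean()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InvalidInputError):
            secondary_event_rates([], [])
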
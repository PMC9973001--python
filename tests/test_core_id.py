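import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corepair.core_id import (function_weights, keystoneness, pair_scores,
                              project_adjacency, rank_core)
from corepair.data_io import OtuTable
from corepair.network import FieldNetwork


def _net_from_graph(graph, groups=None):
    for node in graph.nodes:
        graph.nodes[node]["group"] = (groups[node] if groups
                                      else "bacteria")
    k = graph.number_of_nodes()
    edges = pd.DataFrame(
        [(str(u), str(v), 1.0, 0.0) for u, v in graph.edges],
        columns=["otu_i", "otu_j", "rho", "p"])
    return FieldNetwork("test", graph, 0.8, k * (k - 1) // 2, edges)


def brute_force_betweenness(graph, w, functional_set):
    """Exhaustive shortest-path enumeration oracle for keystoneness."""
    F = dict.fromkeys(graph, 0.0)
    mf = sorted(functional_set)
    for k, l in itertools.combinations(mf, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, k, l))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        interior_counts = {}
        for path in paths:
            for node in path[1:-1]:
                interior_counts[node] = interior_counts.get(node, 0) + 1
        for node, count in interior_counts.items():
            F[node] += w[k] * w[l] * count / sigma
    return F


class TestFunctionWeights:
    def _table(self, values, groups):
        otus = [f"o{i}" for i in range(values.shape[1])]
        frame = pd.DataFrame(values, index=[f"S{i}"
                                            for i in range(len(values))],
                             columns=otus)
        frame = frame.div(frame.sum(axis=1), axis=0)
        return OtuTable(frame, dict(zip(otus, groups)))

    def test_zero_group_effects_reduce_to_direct_correlation(self):
        rng = np.random.default_rng(0)
        values = rng.random((30, 4)) + 0.1
        table = self._table(values, ["archaea", "bacteria", "fungi",
                                     "algae"])
        metric = pd.Series(rng.random(30), index=table.sample_ids)
        out = function_weights(table, metric, {})
        for otu in table.otu_ids:
            r = stats.pearsonr(table.abundance[otu], metric)[0]
            assert out.loc[otu, "w"] == pytest.approx(r, abs=1e-12)
            assert out.loc[otu, "r"] == pytest.approx(r, abs=1e-12)

    def test_hand_computed_amplification(self):
        """r_s = 0.5 for a bacterial OTU and a single nonzero
        T(archaea, bacteria) = 0.4 give w = 0.5 + 0.5 * 0.4 = 0.7."""
        n = 40
        metric_values = np.linspace(0.0, 1.0, n)
        rng = np.random.default_rng(1)
        # build an abundance column with exact Pearson r = 0.5 against
        # the metric via Gram-Schmidt
        target = metric_values - metric_values.mean()
        noise = rng.standard_normal(n)
        noise -= noise.mean()
        noise -= (noise @ target) / (target @ target) * target
        x = 0.5 * target / np.linalg.norm(target) + \
            np.sqrt(1 - 0.25) * noise / np.linalg.norm(noise)
        x = x - x.min() + 0.1
        # a second OTU keeps the table 2-column; closure is skipped by
        # constructing relative abundances directly
        frame = pd.DataFrame({"b1": x, "other": 1.0 - x},
                             index=[f"S{i}" for i in range(n)])
        # closure changed b1's correlation; renormalize b1 back
        table = OtuTable.__new__(OtuTable)
        table.abundance = pd.DataFrame(
            {"b1": x, "other": rng.random(n) + 0.1},
            index=[f"S{i}" for i in range(n)])
        table.taxonomy = {"b1": "bacteria", "other": "fungi"}
        table.is_relative = False
        table.lineage = {}
        metric = pd.Series(metric_values, index=table.abundance.index)
        effects = {("archaea", "bacteria"): 0.4}
        out = function_weights(table, metric, effects)
        assert out.loc["b1", "r"] == pytest.approx(0.5, abs=1e-9)
        assert out.loc["b1", "w"] == pytest.approx(0.7, abs=1e-9)

    def test_negating_metric_negates_r(self):
        rng = np.random.default_rng(2)
        values = rng.random((25, 3)) + 0.1
        table = self._table(values, ["archaea", "bacteria", "fungi"])
        metric = pd.Series(rng.random(25), index=table.sample_ids)
        out_pos = function_weights(table, metric, {})
        out_neg = function_weights(table, -metric, {})
        assert np.allclose(out_pos["r"], -out_neg["r"], atol=1e-12)


class TestKeystoneness:
    def test_path_graph_single_geodesic(self):
        graph = nx.path_graph(["k", "i", "l"])
        net = _net_from_graph(graph)
        w = {"k": 1.0, "i": 1.0, "l": 1.0}
        out = keystoneness(net, w, functional_set=["k", "l"])
        assert out.loc["i", "F"] == pytest.approx(1.0)
        assert out.loc["k", "F"] == 0.0
        assert out.loc["l", "F"] == 0.0
        assert out.loc["i", "B_std"] == 1.0

    def test_unit_weights_equal_classic_betweenness(self):
        """On random graphs, unit-weight keystoneness with the full
        functional set equals unnormalized betweenness centrality."""
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            graph = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(
                0, 2**31)))
            net = _net_from_graph(nx.relabel_nodes(
                graph, {i: f"n{i}" for i in graph.nodes}))
            w = {v: 1.0 for v in net.graph.nodes}
            out = keystoneness(net, w)
            ref = nx.betweenness_centrality(net.graph, normalized=False)
            for v in net.graph.nodes:
                assert out.loc[v, "F"] == pytest.approx(ref[v], abs=1e-9)

    def test_weighted_oracle_on_random_graphs(self):
        """Weighted keystoneness matches exhaustive path enumeration with
        heterogeneous weights and a restricted functional set."""
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = int(rng.integers(5, 10))
            graph = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(
                0, 2**31)))
            graph = nx.relabel_nodes(graph, {i: f"n{i}"
                                             for i in graph.nodes})
            net = _net_from_graph(graph)
            w = {v: float(rng.normal(0.5, 0.5)) for v in graph.nodes}
            mf = sorted(graph.nodes)[: max(3, n - 2)]
            out = keystoneness(net, w, functional_set=mf)
            ref = brute_force_betweenness(graph, w, mf)
            for v in graph.nodes:
                assert out.loc[v, "F"] == pytest.approx(ref[v], abs=1e-9)

    def test_weight_rescaling_leaves_b_std_unchanged(self):
        rng = np.random.default_rng(5)
        graph = nx.gnp_random_graph(8, 0.5, seed=11)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in graph.nodes})
        net = _net_from_graph(graph)
        w = {v: float(rng.random() + 0.1) for v in graph.nodes}
        out1 = keystoneness(net, w)
        out2 = keystoneness(net, {v: 2.0 * x for v, x in w.items()})
        assert np.allclose(out2["F"], 4.0 * out1["F"], atol=1e-9)
        assert np.allclose(out2["B_std"], out1["B_std"], atol=1e-12)

    def test_constant_keystoneness_standardizes_to_zero(self):
        graph = nx.Graph()
        graph.add_nodes_from(["a", "b"])   # no edges: all F = 0
        net = _net_from_graph(graph)
        out = keystoneness(net, {"a": 1.0, "b": 1.0})
        assert (out["B_std"] == 0.0).all()


class TestAdjacencyProjection:
    def test_triangle(self):
        net = _net_from_graph(nx.complete_graph(["a", "b", "c"]))
        proj = project_adjacency(net)
        assert (proj.degrees == 2).all()
        idx = {o: i for i, o in enumerate(proj.otus)}
        for a, b in itertools.combinations("abc", 2):
            assert proj.shared[idx[a], idx[b]] == 1

    def test_star(self):
        net = _net_from_graph(nx.star_graph(["c", "l1", "l2", "l3", "l4"]))
        proj = project_adjacency(net)
        idx = {o: i for i, o in enumerate(proj.otus)}
        assert proj.degrees[idx["c"]] == 4
        for a, b in itertools.combinations(["l1", "l2", "l3", "l4"], 2):
            assert proj.shared[idx[a], idx[b]] == 1

    def test_shared_neighbors_match_set_intersection(self):
        graph = nx.gnp_random_graph(10, 0.4, seed=21)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in graph.nodes})
        net = _net_from_graph(graph)
        proj = project_adjacency(net)
        idx = {o: i for i, o in enumerate(proj.otus)}
        for a, b in itertools.combinations(graph.nodes, 2):
            expected = len(set(graph[a]) & set(graph[b]))
            assert proj.shared[idx[a], idx[b]] == expected


class TestPairScores:
    def _keystones(self, net, b_std):
        nodes = list(net.graph.nodes)
        return pd.DataFrame({
            "otu_id": nodes, "group": ["bacteria"] * len(nodes),
            "w": 1.0, "F": 0.0,
            "B_std": [b_std.get(v, 1.0) for v in nodes],
            "functional_set_member": True}).set_index("otu_id")

    def test_worked_example(self):
        """R_i = 3, R_j = 2, S_ij = 1, N_I = 5 gives C = 2 and T = 1."""
        graph = nx.Graph()
        # i: neighbors j, p, q (R_i = 3); j: neighbors i, p (R_j = 2)
        graph.add_edges_from([("i", "j"), ("i", "p"), ("i", "q"),
                              ("j", "p")])
        graph.add_node("r")   # isolated fifth node -> N_I = 5
        net = _net_from_graph(graph)
        scores = pair_scores(net, self._keystones(net, {}))
        row = scores.set_index(["otu_i", "otu_j"]).loc[("i", "j")]
        assert row["R_i"] == 3 and row["R_j"] == 2
        assert row["S_ij"] == 1 and row["N_I"] == 5
        assert row["C"] == 2
        assert row["T"] == 1
        assert row["C"] - row["T"] == 3 * 2 - 5 * 1

    def test_no_shared_neighbors_limits(self):
        graph = nx.Graph()
        graph.add_edges_from([("i", "j"), ("i", "a"), ("j", "b")])
        net = _net_from_graph(graph)
        scores = pair_scores(net, self._keystones(net, {}))
        row = scores.set_index(["otu_i", "otu_j"]).loc[("i", "j")]
        assert row["S_ij"] == 0
        assert row["T"] == 0
        assert row["C"] == row["R_i"] * row["R_j"]

    def test_zero_b_std_zeroes_indices(self):
        graph = nx.Graph()
        graph.add_edges_from([("i", "j"), ("i", "a")])
        net = _net_from_graph(graph)
        scores = pair_scores(net, self._keystones(net, {"i": 0.0}))
        for _, row in scores.iterrows():
            if "i" in (row["otu_i"], row["otu_j"]):
                assert row["R_checker"] == 0.0
                assert row["R_together"] == 0.0

    def test_identity_on_random_graphs(self):
        """C - T = R_i R_j - N_I S_ij holds exactly on random graphs."""
        rng = np.random.default_rng(6)
        for trial in range(25):
            n = int(rng.integers(5, 30))
            p = float(rng.uniform(0.1, 0.5))
            graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(
                0, 2**31)))
            graph = nx.relabel_nodes(graph, {i: f"n{i}"
                                             for i in graph.nodes})
            net = _net_from_graph(graph)
            scores = pair_scores(net, self._keystones(net, {}))
            lhs = scores["C"] - scores["T"]
            rhs = scores["R_i"] * scores["R_j"] - \
                scores["N_I"] * scores["S_ij"]
            assert (lhs == rhs).all()


class TestRankCore:
    def _pairs(self, rows):
        frame = pd.DataFrame(rows, columns=[
            "otu_i", "otu_j", "group_pair", "interaction_type", "C", "T",
            "R_checker", "R_together"])
        return frame

    def test_top_k_selection(self):
        rows = [
            ("a1", "b1", "archaea|bacteria", "between", 5, 1, 5.0, 1.0),
            ("a2", "b2", "archaea|bacteria", "between", 3, 1, 3.0, 1.0),
            ("a3", "b3", "archaea|bacteria", "between", 1, 1, 1.0, 1.0),
        ]
        core = rank_core(self._pairs(rows), k_between=2, k_within=10)
        top = core.top_pairs[("checker", "between")]
        assert list(top["otu_i"]) == ["a1", "a2"]

    def test_exact_ties_break_deterministically(self):
        rows = [
            ("z9", "z8", "archaea|bacteria", "between", 4, 1, 2.0, 1.0),
            ("a1", "b1", "archaea|bacteria", "between", 4, 1, 2.0, 1.0),
            ("a1", "b2", "archaea|bacteria", "between", 9, 1, 2.0, 1.0),
        ]
        core1 = rank_core(self._pairs(rows), k_between=2)
        core2 = rank_core(self._pairs(rows.copy()), k_between=2)
        top1 = core1.top_pairs[("checker", "between")]
        # higher raw C wins the tie, then lexicographic ids
        assert list(top1["otu_i"]) == ["a1", "a1"]
        assert list(top1["otu_j"]) == ["b2", "b1"]
        pd.testing.assert_frame_equal(
            top1, core2.top_pairs[("checker", "between")])

    def test_summary_reports_sums_and_core_means(self):
        rows = [
            ("a1", "b1", "archaea|bacteria", "between", 5, 2, 5.0, 2.0),
            ("a2", "b2", "archaea|bacteria", "between", 3, 2, 3.0, 2.0),
            ("f1", "f2", "fungi|fungi", "within", 2, 1, 2.0, 1.0),
        ]
        core = rank_core(self._pairs(rows), k_between=1, k_within=1)
        summary = core.summary.set_index("group_pair")
        assert summary.loc["archaea|bacteria", "sum_checker"] == 8.0
        assert summary.loc["archaea|bacteria", "core_mean_checker"] == 5.0
        assert summary.loc["fungi|fungi", "sum_checker"] == 2.0
        assert sorted(core.members) == ["a1", "b1", "f1", "f2"]

    def test_fewer_pairs_than_k_returns_all(self):
        rows = [("a1", "b1", "archaea|bacteria", "between", 5, 1, 5.0,
                 1.0)]
        core = rank_core(self._pairs(rows), k_between=15, k_within=10)
        assert len(core.top_pairs[("checker", "between")]) == 1

    def test_ranking_invariant_to_uniform_weight_rescaling(
            self, default_study):
        """Scaling every w by a positive constant leaves the core ranking
        unchanged (B' is scale-free)."""
        from corepair.network import build_global_network
        net = build_global_network(default_study["table"])
        rng = np.random.default_rng(7)
        w = {v: float(rng.normal(0.4, 0.2)) for v in net.graph.nodes}
        k1 = keystoneness(net, w)
        k2 = keystoneness(net, {v: 3.7 * x for v, x in w.items()})
        p1 = rank_core(pair_scores(net, k1))
        p2 = rank_core(pair_scores(net, k2))
        for key in p1.top_pairs:
            pd.testing.assert_frame_equal(
                p1.top_pairs[key][["otu_i", "otu_j"]],
                p2.top_pairs[key][["otu_i", "otu_j"]])
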
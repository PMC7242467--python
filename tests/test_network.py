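"""Co-occurrence network construction, topology and subgraph decay."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from assemblage.core import OtuTable
from assemblage.network import (
    build_network,
    filter_otus,
    node_metrics,
    sample_subgraph,
    sample_topology_table,
    topology,
    topology_decay,
)


def make_table(columns: dict[str, list[int]]) -> OtuTable:
    n = len(next(iter(columns.values())))
    return OtuTable(
        pd.DataFrame(columns, index=[f"s{i}" for i in range(n)])
    )


class TestFilterOtus:
    def test_strict_thresholds(self):
        # 10 samples, fixed total 10000 reads per sample via a filler OTU
        n = 10
        cols = {}
        cols["exact_occ"] = [5, 5] + [0] * 8  # exactly 20% occupancy
        cols["ok_occ"] = [5, 5, 5] + [0] * 7  # 30% occupancy, mean RA 0.015%
        # mean RA exactly 0.01%: total 10 reads over 10 samples of 10000
        cols["exact_ra"] = [1] * 10
        cols["filler"] = [0] * 10
        filler = [10000 - sum(v[i] for v in cols.values()) for i in range(n)]
        cols["filler"] = filler
        table = make_table(cols)
        assert (table.sample_totals() == 10000).all()
        kept = filter_otus(table, 0.0001, 0.2)
        assert "exact_occ" not in kept.otu_ids  # 20% is not > 20%
        assert "exact_ra" not in kept.otu_ids  # 0.01% is not > 0.01%
        assert "ok_occ" in kept.otu_ids

    def test_no_survivors_raises_with_counts(self):
        table = make_table(
            {"a": [5] + [1] * 9, "b": [1] * 9 + [5], "c": [2] * 10}
        )
        with pytest.raises(ValueError, match="pass"):
            filter_otus(table, 0.9, 0.9)


class TestBuildNetwork:
    def _correlated_table(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        base = np.arange(1, n + 1) * 10
        cols = {
            "up1": base + rng.integers(0, 2, n),
            "up2": base * 2,
            "down": base[::-1] * 3,
        }
        for i in range(6):
            cols[f"noise{i}"] = rng.integers(1, 100, n)
        return make_table({k: list(map(int, v)) for k, v in cols.items()})

    def test_concordant_and_discordant_edges(self):
        table = make_table(
            {
                "a": list(range(1, 11)),
                "b": [2 * x for x in range(1, 11)],
                "c": [22 - 2 * x for x in range(1, 11)],
                "d": [7] * 5 + [9] * 5,
            }
        )
        net = build_network(table, 0.7, 0.01)
        assert net.edges["a", "b"]["rho"] == pytest.approx(1.0)
        assert net.edges["a", "b"]["sign"] == 1
        assert net.edges["a", "c"]["rho"] == pytest.approx(-1.0)
        assert net.edges["a", "c"]["sign"] == -1

    def test_edges_match_independent_recomputation(self):
        table = self._correlated_table(n=12, seed=3)
        net = build_network(table, 0.7, 0.01)
        x = table.counts.astype(float)
        m = x.shape[1]
        expected = set()
        pvals, pairs = [], []
        for i, j in itertools.combinations(range(m), 2):
            rho, p = spearmanr(x[:, i], x[:, j])
            pairs.append((i, j, rho))
            pvals.append(p)
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for (i, j, rho), p in zip(pairs, adj):
            if abs(rho) > 0.7 and p < 0.01:
                expected.add(
                    frozenset((table.otu_ids[i], table.otu_ids[j]))
                )
        got = {frozenset(e) for e in net.edges}
        assert got == expected

    def test_every_edge_satisfies_both_thresholds(self):
        table = self._correlated_table(n=14, seed=9)
        net = build_network(table, 0.7, 0.01)
        for _, _, data in net.edges(data=True):
            assert abs(data["rho"]) > 0.7
            assert data["p_adjusted"] < 0.01

    def test_constant_otu_skipped_with_warning(self, caplog):
        table = make_table(
            {
                "a": list(range(1, 11)),
                "b": [2 * x for x in range(1, 11)],
                "const": [4] * 10,
            }
        )
        with caplog.at_level("WARNING"):
            net = build_network(table, 0.7, 0.01)
        assert "const" not in net.nodes
        assert "const" in caplog.text

    def test_exact_small_n_pvalue_matches_enumeration(self):
        # n=6 tie-free: exact two-sided p for perfect concordance is 2/6!
        table = make_table(
            {
                "a": [1, 5, 9, 14, 20, 33],
                "b": [2, 7, 11, 15, 22, 40],
                "c": [13, 2, 40, 1, 27, 8],
            }
        )
        from assemblage.network import _spearman_pvalues

        rho, pval, _ = _spearman_pvalues(table.counts.astype(float))
        assert rho[0, 1] == pytest.approx(1.0)
        assert pval[0, 1] == pytest.approx(2 / 720)


class TestTopology:
    def test_triangle_closed_forms(self):
        g = nx.complete_graph(3)
        feats = topology(g)
        assert feats.density == pytest.approx(1.0)
        assert feats.mean_degree == pytest.approx(2.0)
        assert feats.diameter == 1
        assert feats.clustering_coefficient == pytest.approx(1.0)

    def test_two_disjoint_triangles_modularity(self):
        g = nx.union(
            nx.complete_graph(3),
            nx.relabel_nodes(nx.complete_graph(3), {0: 3, 1: 4, 2: 5}),
        )
        feats = topology(g)
        assert feats.modularity == pytest.approx(0.5)

    def test_star_centralizations_are_maximal(self):
        g = nx.star_graph(3)  # 4 nodes
        feats = topology(g)
        assert feats.degree_centralization == pytest.approx(1.0)
        assert feats.betweenness_centralization == pytest.approx(1.0)

    def test_small_graph_metrics_match_brute_force(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(6, 0.6, seed=4)
        if g.number_of_edges() == 0:  # pragma: no cover
            pytest.skip("degenerate draw")
        feats = topology(g)
        n = g.number_of_nodes()
        # density / mean degree by hand
        e = g.number_of_edges()
        assert feats.density == pytest.approx(2 * e / (n * (n - 1)))
        assert feats.mean_degree == pytest.approx(2 * e / n)
        # transitivity by triple enumeration
        triangles = sum(
            1
            for a, b, c in itertools.combinations(g.nodes, 3)
            if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
        )
        triples = sum(
            d * (d - 1) / 2 for _, d in g.degree()
        )
        expected_t = 3 * triangles / triples if triples else 0.0
        assert feats.clustering_coefficient == pytest.approx(expected_t)
        # diameter / average path length on the largest component
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        lengths = [
            nx.shortest_path_length(sub, a, b)
            for a, b in itertools.combinations(sub.nodes, 2)
        ]
        assert feats.diameter == max(lengths)
        assert feats.average_path_length == pytest.approx(np.mean(lengths))

    def test_greedy_modularity_bounded_by_exhaustive_partition(self):
        def partitions(collection):
            if len(collection) == 1:
                yield [collection]
                return
            first = collection[0]
            for smaller in partitions(collection[1:]):
                for i, subset in enumerate(smaller):
                    yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
                yield [[first]] + smaller

        g = nx.gnp_random_graph(7, 0.45, seed=11)
        if g.number_of_edges() < 2:  # pragma: no cover
            pytest.skip("degenerate draw")
        best = max(
            nx.algorithms.community.modularity(g, [set(p) for p in part])
            for part in partitions(list(g.nodes))
        )
        feats = topology(g)
        assert feats.modularity <= best + 1e-12


class TestNodeMetrics:
    def test_path_graph_hand_values(self):
        g = nx.path_graph(["A", "B", "C"])
        metrics = node_metrics(g)
        assert metrics.loc["B", "degree"] == 2
        assert metrics.loc["B", "betweenness"] == pytest.approx(1.0)
        assert metrics.loc["B", "transitivity"] == 0.0

    def test_k3_local_clustering_and_dyad_closeness(self):
        g = nx.complete_graph(3)
        assert (node_metrics(g)["transitivity"] == 1.0).all()
        dyad = nx.Graph([("A", "B")])
        assert node_metrics(dyad).loc["A", "closeness"] == pytest.approx(1.0)


class TestSubgraphs:
    def _net_and_table(self):
        table = make_table(
            {
                "a": list(range(1, 11)),
                "b": [2 * x for x in range(1, 11)],
                "c": [x + 1 for x in range(1, 11)],
                "d": [9, 0, 9, 0, 9, 0, 9, 0, 9, 0],
            }
        )
        net = build_network(table, 0.7, 0.05)
        return net, table

    def test_induced_subgraph_cases(self):
        net, table = self._net_and_table()
        assert set(net.nodes) == {"a", "b", "c"}
        full = sample_subgraph(net, table, "s0")
        assert set(full.nodes) == {"a", "b", "c"}
        assert full.number_of_edges() == net.number_of_edges()
        with pytest.raises(KeyError, match="nope"):
            sample_subgraph(net, table, "nope")

    def test_empty_subgraph_for_absent_otus(self):
        net, table = self._net_and_table()
        extra = OtuTable(
            pd.concat(
                [
                    table.data,
                    pd.DataFrame(
                        [[0, 0, 0, 5]], index=["bare"], columns=table.otu_ids
                    ),
                ]
            )
        )
        sub = sample_subgraph(net, extra, "bare")
        assert sub.number_of_nodes() == 0


class TestTopologyDecay:
    def test_constant_features_not_testable(self):
        feats = pd.DataFrame(
            np.ones((5, 3)),
            index=[f"s{i}" for i in range(5)],
            columns=["a", "b", "c"],
        )
        geo = skbio.DistanceMatrix(
            np.abs(np.subtract.outer(range(5), range(5))).astype(float),
            ids=[f"s{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="no decay testable"):
            topology_decay(feats, geo, 99, seed=1)

    def test_monotone_features_give_significant_positive_r(self):
        n = 10
        coords = np.arange(n, dtype=float)
        geo = skbio.DistanceMatrix(
            np.abs(np.subtract.outer(coords, coords)),
            ids=[f"s{i}" for i in range(n)],
        )
        feats = pd.DataFrame(
            {"f1": coords, "f2": coords**2, "flat": np.ones(n)},
            index=[f"s{i}" for i in range(n)],
        )
        res = topology_decay(feats, geo, 999, seed=2)
        assert res.r > 0
        assert res.p_value <= 0.05

    def test_per_sample_feature_table(self, demo_dataset):
        from assemblage.network import filter_otus

        filtered = filter_otus(demo_dataset.table)
        net = build_network(filtered, 0.7, 0.01)
        feats = sample_topology_table(net, filtered)
        assert feats.shape[1] == 10
        assert (feats["node_count"] >= 1).all()
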
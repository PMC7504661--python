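import itertools

import networkx as nx
import numpy as np
import pytest

from netsig.data_io import PathwayGraph
from netsig.upstream_signaling import (
    CoreSignalingNetwork,
    PathBudgetExceeded,
    SignalingCascade,
    build_core_network,
    compare_groups,
    enumerate_cascades,
    score_and_prune,
    start_nodes,
)


def pathway_from_edges(pid: str, edges) -> PathwayGraph:
    pw = PathwayGraph(pid, pid)
    for u, v in edges:
        pw.add_edge(u, v, 1)
    return pw


def brute_force_simple_paths(g: nx.DiGraph, starts, tf, max_len):
    """Exhaustive DFS over all simple paths, independent of networkx."""
    found = []

    def dfs(node, path):
        if len(path) - 1 > max_len:
            return
        if node == tf and len(path) > 1:
            found.append(tuple(path))
            return
        for nxt in g.successors(node):
            if nxt not in path:
                dfs(nxt, path + [nxt])

    for s in starts:
        if s in g and s != tf:
            dfs(s, [s])
    return sorted(found)


class TestStartNodes:
    def test_chain(self):
        pw = pathway_from_edges("p", [("A", "B"), ("B", "C")])
        assert start_nodes(pw) == {"A"}

    def test_two_roots(self):
        pw = pathway_from_edges("p", [("A", "C"), ("B", "C")])
        assert start_nodes(pw) == {"A", "B"}

    def test_cyclic_pathway_uses_source_scc(self):
        pw = pathway_from_edges("p", [("A", "B"), ("B", "A"), ("B", "C")])
        with pytest.warns(UserWarning, match="source-SCC"):
            assert start_nodes(pw) == {"A", "B"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            start_nodes(PathwayGraph("p", "p"))

    def test_random_dags_match_indegree_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 10))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)), directed=True)
            dag = nx.DiGraph((u, v) for u, v in g.edges if u < v)
            dag.add_nodes_from(g.nodes)
            pw = PathwayGraph("p", "p")
            pw.graph = nx.relabel_nodes(dag, {i: f"n{i}" for i in dag.nodes})
            expected = {n for n in pw.graph.nodes if pw.graph.in_degree(n) == 0}
            assert start_nodes(pw) == expected


class TestEnumerateCascades:
    def test_unreachable_tf_empty(self):
        pw = pathway_from_edges("p", [("A", "B"), ("C", "D")])
        assert enumerate_cascades(pw, {"A"}, "D") == []

    def test_diamond_two_paths(self):
        pw = pathway_from_edges("p", [("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        paths = enumerate_cascades(pw, {"A"}, "D")
        assert paths == [("A", "B", "D"), ("A", "C", "D")]

    def test_absent_tf_rejected(self):
        pw = pathway_from_edges("p", [("A", "B")])
        with pytest.raises(ValueError, match="not in pathway"):
            enumerate_cascades(pw, {"A"}, "Z")

    def test_max_len_cap(self):
        pw = pathway_from_edges("p", [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
        assert enumerate_cascades(pw, {"A"}, "D", max_len=1) == [("A", "D")]

    def test_budget_abort(self):
        # complete bipartite-ish layered graph with an explosion of paths
        layers = [[f"L{i}_{j}" for j in range(4)] for i in range(6)]
        edges = []
        for a, b in zip(layers[:-1], layers[1:]):
            edges.extend(itertools.product(a, b))
        edges.extend((n, "TF") for n in layers[-1])
        pw = pathway_from_edges("p", edges)
        with pytest.raises(PathBudgetExceeded):
            enumerate_cascades(pw, set(layers[0]), "TF", path_budget=100)

    def test_random_graphs_match_exhaustive_dfs(self):
        rng = np.random.default_rng(1)
        for trial in range(200):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.1, 0.4))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            pw = PathwayGraph("p", "p")
            pw.graph = g
            nodes = sorted(g.nodes)
            tf = nodes[-1]
            starts = set(nodes[: max(1, n // 3)])
            max_len = int(rng.integers(2, 13))
            got = enumerate_cascades(pw, starts, tf, max_len=max_len)
            assert got == brute_force_simple_paths(g, sorted(starts), tf, max_len)


class TestScoreAndPrune:
    def test_single_cascade_always_retained(self):
        out = score_and_prune([("p", ("A", "T"))], {"A": 0.1, "T": 0.0})
        assert len(out) == 1 and out[0].score == pytest.approx(0.05)

    def test_mean_score(self):
        out = score_and_prune([("p", ("A", "B", "T"))], {"A": 0.9, "B": 0.8, "T": 0.7})
        assert out[0].score == pytest.approx(0.8)

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        probs = {g: float(rng.random()) for g in genes} | {"T": 0.5}
        cascades = []
        for _ in range(10):
            length = int(rng.integers(1, 5))
            body = list(rng.choice(genes, size=length, replace=False))
            cascades.append(("p", tuple(body + ["T"])))
        out = score_and_prune(cascades, probs, top_k=3)
        scored = sorted(
            ((sum(probs[n] for n in nodes) / len(nodes), len(nodes), nodes) for _, nodes in cascades),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        expected = [nodes for _, _, nodes in scored[:3]]
        assert [c.nodes for c in out] == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        probs = {f"g{i}": float(rng.random()) for i in range(8)} | {"T": 1.0}
        cascades = [("p", (f"g{i}", f"g{(i+1) % 8}", "T")) for i in range(8)]
        a = score_and_prune(cascades, probs, top_k=3)
        b = score_and_prune(list(reversed(cascades)), probs, top_k=3)
        assert a == b

    def test_missing_probability_scored_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no probability"):
            out = score_and_prune([("p", ("A", "T"))], {"T": 1.0})
        assert out[0].score == pytest.approx(0.5)

    def test_top_k_per_pathway_tf_pair(self):
        probs = {f"g{i}": 0.5 for i in range(6)} | {"T1": 1.0, "T2": 1.0}
        cascades = [(f"pw{p}", (f"g{i}", t)) for p in range(2) for t in ("T1", "T2") for i in range(5)]
        out = score_and_prune(cascades, probs, top_k=3)
        assert len(out) == 2 * 2 * 3


class TestCoreNetwork:
    def test_roles_single_cascade(self):
        pw = pathway_from_edges("p", [("A", "B"), ("B", "TF")])
        casc = SignalingCascade("p", ("A", "B", "TF"), "TF", 1.0)
        net = build_core_network([casc], {"TF"}, {"p": pw})
        assert net.roles() == {"A": "start", "B": "transduction", "TF": "tf"}

    def test_shared_edge_merges_with_two_provenances(self):
        pw = pathway_from_edges("p", [("A", "B"), ("B", "TF"), ("C", "B")])
        c1 = SignalingCascade("p", ("A", "B", "TF"), "TF", 1.0)
        c2 = SignalingCascade("p", ("C", "B", "TF"), "TF", 1.0)
        net = build_core_network([c1, c2], {"TF"}, {"p": pw})
        assert len(net.graph["B"]["TF"]["provenance"]) == 2
        assert net.graph.number_of_edges() == 3

    def test_sign_conflict_flagged(self):
        pw1 = pathway_from_edges("p1", [("A", "B")])
        pw2 = PathwayGraph("p2", "p2")
        pw2.add_edge("A", "B", -1)
        c1 = SignalingCascade("p1", ("A", "B"), "B", 1.0)
        c2 = SignalingCascade("p2", ("A", "B"), "B", 1.0)
        net = build_core_network([c1, c2], {"B"}, {"p1": pw1, "p2": pw2})
        assert net.graph["A"]["B"]["sign_conflict"]

    def test_retained_cascades_revalidate_as_paths(self, noiseless_run):
        pathway_map = {pw.pathway_id: pw for pw in noiseless_run.dataset.pathways}
        for cascades in noiseless_run.cascades.values():
            for c in cascades:
                g = pathway_map[c.pathway_id].graph
                assert len(set(c.nodes)) == len(c.nodes)
                assert all(g.has_edge(u, v) for u, v in zip(c.nodes[:-1], c.nodes[1:]))
                assert g.in_degree(c.nodes[0]) == 0
                assert c.nodes[-1] == c.tf

    def test_zero_noise_merge_equals_planted_union(self, noiseless_run):
        truth = noiseless_run.dataset.truth
        planted_edges = set()
        for casc in truth.planted_cascades:
            planted_edges.update(zip(casc[:-1], casc[1:]))
        merged_edges = set()
        for net in noiseless_run.networks.values():
            merged_edges.update(net.graph.edges)
        assert merged_edges == planted_edges


class TestCompareGroups:
    def _net(self, nodes_roles):
        net = CoreSignalingNetwork()
        for n, r in nodes_roles.items():
            net.graph.add_node(n, role=r)
        return net

    def test_identical_networks_all_shared(self):
        n1 = self._net({"A": "start", "T": "tf"})
        n2 = self._net({"A": "start", "T": "tf"})
        out = compare_groups({0: n1, 1: n2})
        assert out["shared"] == {"A", "T"}
        assert out["unique_genes"] == {0: set(), 1: set()}

    def test_disjoint_networks_empty_intersection(self):
        out = compare_groups({0: self._net({"A": "start"}), 1: self._net({"B": "start"})})
        assert out["shared"] == set()
        assert out["unique_genes"] == {0: {"A"}, 1: {"B"}}

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({0: self._net({"A": "start"})})
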
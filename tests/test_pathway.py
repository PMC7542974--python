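from itertools import permutations
from math import comb

import numpy as np
import pandas as pd
import pytest

from metaminer import (PathwayGraph, PathwayLibrary, centrality, enrich,
                       impact, pathway_analysis, read_pathway_library,
                       simulate_pathway_library, write_pathway_library)
from metaminer.pathway import CENTRALITY_ALGORITHMS


def _graph(nodes, edges, pid="p1"):
    return PathwayGraph(pid, pid, "test", list(nodes),
                        [(u, v, False) for u, v in edges])


# -- brute-force oracles ---------------------------------------------------

def _shortest_paths(adj, s, t):
    """All shortest paths s->t by breadth-first enumeration."""
    if s == t:
        return []
    best, paths = None, []
    frontier = [[s]]
    while frontier and best is None or frontier and len(frontier[0]) <= best:
        nxt = []
        for path in frontier:
            for nb in adj[path[-1]]:
                if nb in path:
                    continue
                new = path + [nb]
                if nb == t:
                    if best is None or len(new) == best:
                        best = len(new)
                        paths.append(new)
                else:
                    nxt.append(new)
        frontier = [p for p in nxt if best is None or len(p) < best]
    return [p for p in paths if len(p) == best]


def _betweenness_oracle(nodes, undirected_edges):
    adj = {n: set() for n in nodes}
    for u, v in undirected_edges:
        adj[u].add(v)
        adj[v].add(u)
    score = {n: 0.0 for n in nodes}
    for s, t in permutations(nodes, 2):
        if s >= t:   # each unordered pair once
            continue
        paths = _shortest_paths(adj, s, t)
        if not paths:
            continue
        for node in nodes:
            if node in (s, t):
                continue
            through = sum(node in p for p in paths)
            score[node] += through / len(paths)
    n = len(nodes)
    denom = (n - 1) * (n - 2) / 2
    return {k: (v / denom if denom > 0 else 0.0) for k, v in score.items()}


def _eigenvector_oracle(nodes, undirected_edges):
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in undirected_edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    if not A.any():
        return {node: 0.0 for node in nodes}
    vals, vecs = np.linalg.eigh(A)
    v = np.abs(vecs[:, np.argmax(vals)])
    v = v / v.max()
    return {node: v[idx[node]] for node in nodes}


def _battery():
    """Small graph battery: chains, cycle, star, complete, random DAGs."""
    graphs = [
        _graph("AB", [("A", "B")]),
        _graph("ABC", [("A", "B"), ("B", "C")]),
        _graph("ABCD", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]),
        _graph("ABCDE", [("A", x) for x in "BCDE"]),
        _graph("ABCD", [(u, v) for u in "ABCD" for v in "ABCD" if u < v]),
    ]
    rng = np.random.default_rng(77)
    for k in range(5):
        n = int(rng.integers(4, 8))
        nodes = [chr(65 + i) for i in range(n)]
        edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.45]
        graphs.append(_graph(nodes, edges, pid=f"rand{k}"))
    return graphs


class TestCentrality:
    def test_chain_degrees(self):
        g = _graph("ABC", [("A", "B"), ("B", "C")])
        assert centrality(g, "out_degree") == {"A": 1, "B": 1, "C": 0}
        assert centrality(g, "in_degree") == {"A": 0, "B": 1, "C": 1}
        assert centrality(g, "total_degree") == {"A": 1, "B": 2, "C": 1}

    def test_chain_relative_betweenness(self):
        g = _graph("ABC", [("A", "B"), ("B", "C")])
        scores = centrality(g, "relative_betweenness")
        assert scores == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_eigenvector(self):
        g = _graph("HABCD", [("H", x) for x in "ABCD"])
        scores = centrality(g, "eigenvector")
        assert scores["H"] == pytest.approx(1.0)
        leaves = [scores[x] for x in "ABCD"]
        assert all(l == pytest.approx(leaves[0], abs=1e-8) for l in leaves)
        assert leaves[0] < 1.0

    def test_directed_closeness_chain(self):
        g = _graph("ABC", [("A", "B"), ("B", "C")])
        out = centrality(g, "out_closeness")
        assert out["A"] == pytest.approx(1 / 3)   # d(A,B)+d(A,C) = 3
        assert out["C"] == 0.0                    # reaches nothing
        inc = centrality(g, "in_closeness")
        assert inc["C"] == pytest.approx(1 / 3)
        assert inc["A"] == 0.0

    def test_betweenness_matches_oracle_on_battery(self):
        for g in _battery():
            expected = _betweenness_oracle(
                g.nodes, [(u, v) for u, v, _ in g.edges])
            got = centrality(g, "relative_betweenness")
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-10)

    def test_eigenvector_matches_oracle_on_battery(self):
        for g in _battery():
            expected = _eigenvector_oracle(
                g.nodes, [(u, v) for u, v, _ in g.edges])
            got = centrality(g, "eigenvector")
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-6)

    def test_reversible_edges_equalize_in_out_degree(self):
        g = PathwayGraph("p", "p", "t", ["A", "B", "C"],
                        [("A", "B", True), ("B", "C", True)])
        assert centrality(g, "in_degree") == centrality(g, "out_degree")

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            centrality(_graph("AB", [("A", "B")]), "pagerank")

    def test_undeclared_node_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            _graph("AB", [("A", "C")])


def _library(pathway_nodes):
    pathways = [
        PathwayGraph(f"p{i}", f"p{i}", "test", nodes,
                     [(nodes[j], nodes[j + 1], False)
                      for j in range(len(nodes) - 1)])
        for i, nodes in enumerate(pathway_nodes)]
    return PathwayLibrary("test", pathways)


class TestEnrich:
    def test_hand_hypergeometric(self):
        # universe 20, pathway 5, draws 10, overlap 4:
        # p = sum_{k=4,5} C(5,k) C(15,10-k) / C(20,10)
        nodes = [f"C{i}" for i in range(20)]
        lib = _library([nodes[:5], nodes])
        hits = nodes[:4] + nodes[5:11]
        assert len(hits) == 10
        res = enrich(hits, lib)
        expected = sum(comb(5, k) * comb(15, 10 - k) for k in (4, 5)) \
            / comb(20, 10)
        assert res.loc["p0", "enrichment_p"] == pytest.approx(expected,
                                                              abs=1e-12)

    def test_pathway_equals_universe_p_one(self):
        nodes = [f"C{i}" for i in range(6)]
        lib = _library([nodes])
        res = enrich(nodes, lib)
        assert res.loc["p0", "enrichment_p"] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        nodes = [f"C{i}" for i in range(10)]
        lib = _library([nodes[:5], nodes[5:]])
        res = enrich(nodes[5:], lib)
        assert res.loc["p0", "enrichment_p"] == pytest.approx(1.0)

    def test_pmf_sums_to_one(self):
        from scipy.stats import hypergeom
        total = sum(hypergeom.pmf(k, 20, 5, 10) for k in range(6))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unmappable_hits_rejected(self):
        lib = _library([["C1", "C2"]])
        with pytest.raises(ValueError):
            enrich(["X9"], lib)


class TestImpact:
    def test_no_hits_zero(self):
        g = _graph("ABC", [("A", "B"), ("B", "C")])
        assert impact([], g) == 0.0

    def test_all_hits_one(self):
        g = _graph("ABC", [("A", "B"), ("B", "C")])
        assert impact(["A", "B", "C"], g) == pytest.approx(1.0)

    def test_chain_betweenness_middle_carries_all(self):
        g = _graph("ABC", [("A", "B"), ("B", "C")])
        assert impact(["B"], g, "relative_betweenness") == pytest.approx(1.0)

    def test_monotone_in_hits(self, rng):
        lib, _ = simulate_pathway_library(n_pathways=1, seed=5)
        g = lib.pathways[0]
        hits: list = []
        last = 0.0
        for node in g.nodes:
            hits.append(node)
            current = impact(hits, g)
            assert current >= last - 1e-12
            last = current

    def test_edgeless_graph_falls_back_with_warning(self):
        g = PathwayGraph("p", "p", "t", ["A", "B"], [])
        with pytest.warns(UserWarning, match="fall"):
            assert impact(["A"], g) == pytest.approx(0.5)


class TestPathwayAnalysis:
    def test_algorithm_changes_impact_not_p(self):
        lib, _ = simulate_pathway_library(n_pathways=6, seed=9)
        hits = sorted(lib.universe)[::4]
        a = pathway_analysis(hits, lib, algorithm="eigenvector")
        b = pathway_analysis(hits, lib, algorithm="relative_betweenness")
        pd.testing.assert_series_equal(a["enrichment_p"], b["enrichment_p"])
        assert not np.allclose(a["impact"], b["impact"])

    def test_single_pathway_q_equals_p(self):
        lib = _library([[f"C{i}" for i in range(5)]])
        res = pathway_analysis(["C0", "C1"], lib)
        assert res["enrichment_q"].iloc[0] == res["enrichment_p"].iloc[0]

    def test_empty_hits_rejected(self):
        lib = _library([["C1", "C2"]])
        with pytest.raises(ValueError):
            pathway_analysis([], lib)

    def test_impact_in_unit_interval(self):
        lib, _ = simulate_pathway_library(n_pathways=8, seed=13)
        hits = sorted(lib.universe)[::3]
        for algorithm in CENTRALITY_ALGORITHMS:
            res = pathway_analysis(hits, lib, algorithm=algorithm)
            assert ((res["impact"] >= 0) & (res["impact"] <= 1 + 1e-12)).all()


def test_library_file_roundtrip(tmp_path):
    lib, _ = simulate_pathway_library(n_pathways=3, seed=2)
    path = tmp_path / "synth.txt"
    write_pathway_library(lib, path)
    back = read_pathway_library(path)
    assert len(back) == len(lib)
    for a, b in zip(lib.pathways, back.pathways):
        assert a.pathway_id == b.pathway_id
        assert a.nodes == b.nodes
        assert [(u, v, r) for u, v, r in a.edges] == \
               [(u, v, r) for u, v, r in b.edges]
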
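"""Pathway topology and metabolite-set enrichment analysis.

Each pathway is a directed graph of compound nodes and reaction edges
(reversible edges stored once and expanded to both directions for directed
measures).  Enrichment of a hit list is a one-sided hypergeometric test
against the library universe; pathway impact is the centrality mass of the
hit nodes divided by the total centrality of the pathway, under one of
seven topology algorithms.  The two quantities are independent by
construction: changing the topology algorithm never changes enrichment p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .stats_uni import adjust_pvalues

__all__ = ["PathwayGraph", "PathwayLibrary", "CENTRALITY_ALGORITHMS",
           "centrality", "enrich", "impact", "pathway_analysis",
           "read_pathway_library", "write_pathway_library"]

CENTRALITY_ALGORITHMS = (
    "out_degree", "in_degree", "total_degree", "relative_betweenness",
    "out_closeness", "in_closeness", "total_closeness", "eigenvector",
)


@dataclass
class PathwayGraph:
    pathway_id: str
    name: str
    species: str
    nodes: list[str]
    edges: list[tuple[str, str, bool]]   # (substrate, product, reversible)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v, _ in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge {u}->{v} references an "
                    f"undeclared node")

    def directed(self) -> nx.DiGraph:
        """Directed expansion: reversible edges become two arcs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, rev in self.edges:
            g.add_edge(u, v)
            if rev:
                g.add_edge(v, u)
        return g

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((u, v) for u, v, _ in self.edges)
        return g


@dataclass
class PathwayLibrary:
    species: str
    pathways: list[PathwayGraph] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out.update(p.nodes)
        return out

    def __len__(self) -> int:
        return len(self.pathways)


# -- library file format ---------------------------------------------------
# One text file per species:
#   # pathway <id> <name...>
#   <node id> (one per line)
#   <u> -> <v> [reversible]

def read_pathway_library(path, species: str | None = None) -> PathwayLibrary:
    path = Path(path)
    species = species or path.stem
    pathways: list[PathwayGraph] = []
    current: dict | None = None

    def _flush():
        if current is not None:
            pathways.append(PathwayGraph(
                current["id"], current["name"], species,
                current["nodes"], current["edges"]))

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# pathway"):
            _flush()
            parts = line.split(None, 3)
            if len(parts) < 3:
                raise ValueError(f"malformed pathway header: {line!r}")
            current = {"id": parts[2],
                       "name": parts[3] if len(parts) > 3 else parts[2],
                       "nodes": [], "edges": []}
        elif current is None:
            raise ValueError("library file must start with a '# pathway' header")
        elif "->" in line:
            left, right = line.split("->", 1)
            reversible = "[reversible]" in right
            right = right.replace("[reversible]", "").strip()
            current["edges"].append((left.strip(), right, reversible))
        else:
            current["nodes"].append(line)
    _flush()
    return PathwayLibrary(species, pathways)


def write_pathway_library(library: PathwayLibrary, path) -> None:
    lines = []
    for p in library.pathways:
        lines.append(f"# pathway {p.pathway_id} {p.name}")
        lines.extend(p.nodes)
        for u, v, rev in p.edges:
            lines.append(f"{u} -> {v}" + (" [reversible]" if rev else ""))
    Path(path).write_text("\n".join(lines) + "\n")


# -- centralities ----------------------------------------------------------

def centrality(graph: PathwayGraph, algorithm: str = "eigenvector"
               ) -> dict[str, float]:
    """Per-node centrality under one of the seven topology algorithms.

    Degree and closeness respect edge direction (on the expansion of
    reversible edges); betweenness and eigenvector use the undirected graph.
    Relative betweenness is normalized by (n-1)(n-2)/2; eigenvector is
    scaled to max = 1; closeness is the reciprocal of the summed distances
    to reachable nodes (0 for isolated nodes).
    """
    if not graph.nodes:
        raise ValueError(f"pathway {graph.pathway_id} has no nodes")
    if algorithm not in CENTRALITY_ALGORITHMS:
        raise ValueError(f"unknown centrality algorithm {algorithm!r}")
    dg = graph.directed()
    if algorithm == "out_degree":
        return {n: float(dg.out_degree(n)) for n in graph.nodes}
    if algorithm == "in_degree":
        return {n: float(dg.in_degree(n)) for n in graph.nodes}
    if algorithm == "total_degree":
        return {n: float(dg.in_degree(n) + dg.out_degree(n))
                for n in graph.nodes}
    if algorithm == "relative_betweenness":
        ug = graph.undirected()
        n = len(graph.nodes)
        raw = nx.betweenness_centrality(ug, normalized=False)
        denom = (n - 1) * (n - 2) / 2
        if denom <= 0:
            return {node: 0.0 for node in graph.nodes}
        return {node: raw[node] / denom for node in graph.nodes}
    if algorithm in {"out_closeness", "in_closeness", "total_closeness"}:
        if algorithm == "out_closeness":
            g = dg
        elif algorithm == "in_closeness":
            g = dg.reverse()
        else:
            g = graph.undirected()
        out = {}
        for node in graph.nodes:
            dists = nx.single_source_shortest_path_length(g, node)
            total = sum(d for t, d in dists.items() if t != node)
            out[node] = 1.0 / total if total > 0 else 0.0
        return out
    # eigenvector, undirected power iteration scaled to max = 1
    ug = graph.undirected()
    return _eigenvector_power(ug, graph.nodes)


def _eigenvector_power(g: nx.Graph, nodes: list[str], tol: float = 1e-10,
                       max_iter: int = 10000) -> dict[str, float]:
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in g.edges():
        A[index[u], index[v]] = 1.0
        A[index[v], index[u]] = 1.0
    if not A.any():
        return {node: 0.0 for node in nodes}
    # +I shift guarantees convergence on bipartite graphs without
    # changing the eigenvectors
    A = A + np.eye(n)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        nxt = A @ x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return {node: 0.0 for node in nodes}
        nxt /= norm
        if np.linalg.norm(nxt - x) < tol:
            x = nxt
            break
        x = nxt
    x = np.abs(x)
    peak = x.max()
    if peak > 0:
        x = x / peak
    return {node: float(x[index[node]]) for node in nodes}


# -- enrichment and impact -------------------------------------------------

def enrich(hits: list[str], library: PathwayLibrary,
           correction: str = "fdr",
           universe: set[str] | None = None) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a compound hit list.

    Per pathway, p = P(X >= k) with population the library universe (or the
    supplied ``universe``), successes the pathway's compounds, draws the
    mapped hits, and k the observed overlap.  q is the FDR across pathways.
    """
    uni = universe if universe is not None else library.universe
    mapped = sorted(set(hits) & uni)
    if not mapped:
        raise ValueError("no hit compounds map into the pathway universe")
    N, n_draw = len(uni), len(mapped)
    rows = []
    for p in library.pathways:
        members = set(p.nodes) & uni
        K = len(members)
        k = len(set(mapped) & members)
        # upper tail P(X >= k) = sf(k-1)
        pval = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
        rows.append({"pathway_id": p.pathway_id, "name": p.name,
                     "hits": k, "total": K, "enrichment_p": min(pval, 1.0)})
    result = pd.DataFrame(rows).set_index("pathway_id")
    result["enrichment_q"] = adjust_pvalues(
        result["enrichment_p"].to_numpy(), correction)
    return result


def impact(hits: list[str], graph: PathwayGraph,
           algorithm: str = "eigenvector") -> float:
    """Pathway impact: centrality mass of hit nodes over total centrality.

    When the graph has no edges every centrality is zero; impact then falls
    back to the hit fraction |hits|/|nodes| with a warning.
    """
    scores = centrality(graph, algorithm)
    total = sum(scores.values())
    hit_nodes = set(hits) & set(graph.nodes)
    if total <= 0:
        warnings.warn(
            f"pathway {graph.pathway_id}: all-zero centrality; impact "
            f"falls back to hit fraction", stacklevel=2)
        return len(hit_nodes) / len(graph.nodes) if graph.nodes else 0.0
    return sum(scores[n] for n in hit_nodes) / total


def pathway_analysis(hits: list[str], library: PathwayLibrary,
                     algorithm: str = "eigenvector",
                     correction: str = "fdr") -> pd.DataFrame:
    """Joint enrichment + impact per pathway; bubble-plot-ready table.

    Columns: name, hits, total, enrichment_p, enrichment_q, neg_log10_p,
    impact, algorithm.  Sorted by enrichment p ascending.
    """
    if not hits:
        raise ValueError("empty hit list")
    table = enrich(hits, library, correction)
    impacts = {p.pathway_id: impact(hits, p, algorithm)
               for p in library.pathways}
    table["impact"] = pd.Series(impacts)
    table["neg_log10_p"] = -np.log10(table["enrichment_p"].clip(lower=1e-300))
    table["algorithm"] = algorithm
    return table.sort_values("enrichment_p")
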
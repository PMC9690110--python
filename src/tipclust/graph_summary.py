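"""The "one-cluster" graph: a sparsest single-component summary of B-bar.

The posterior similarity matrix defines a complete weighted graph whose
edge weights are co-clustering probabilities.  Removing as many edges as
possible while keeping the graph in one component leaves n - 1 edges;
among all such spanning trees we keep the one of maximum total weight,
so the strongest co-clustering relations survive.  When some weights are
exactly zero the support graph may be disconnected, in which case a
maximum-weight spanning forest is returned and the component count
reported is > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .consensus import PosteriorSimilarityMatrix

__all__ = ["CoClusterGraph", "one_cluster_graph"]


@dataclass(frozen=True)
class CoClusterGraph:
    edges: tuple[tuple[int, int, float], ...]  # (i, j, weight), i < j
    n_vertices: int
    components: int

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_vertices))
        G.add_weighted_edges_from(self.edges)
        return G


def one_cluster_graph(Bbar: PosteriorSimilarityMatrix | np.ndarray) -> CoClusterGraph:
    """Maximum-weight spanning tree (or forest) of the B-bar graph.

    Zero-weight pairs carry no edge.  Ties between equal-weight edges are
    broken lexicographically by (i, j) so the output is deterministic.
    """
    B = Bbar.values if isinstance(Bbar, PosteriorSimilarityMatrix) else np.asarray(Bbar)
    n = B.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if B[i, j] > 0:
                G.add_edge(i, j, weight=float(B[i, j]))
    # Kruskal on (-weight, i, j): maximum weight, lexicographic tie-break
    order = sorted(G.edges(data="weight"), key=lambda e: (-e[2], e[0], e[1]))
    uf = nx.utils.UnionFind(range(n))
    kept: list[tuple[int, int, float]] = []
    for i, j, w in order:
        if uf[i] != uf[j]:
            uf.union(i, j)
            kept.append((i, j, w))
    components = n - len(kept)
    return CoClusterGraph(edges=tuple(kept), n_vertices=n, components=components)


def write_edge_list(graph: CoClusterGraph, path) -> None:
    """Tab-separated (i, j, weight) edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in graph.edges:
            fh.write(f"{i}\t{j}\t{w:.10g}\n")
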
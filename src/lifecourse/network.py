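"""Neighborhood network of sleep-related terms and childhood adversities.

Nodes are the seed terms (sleep queries plus selected adversities) and
their k nearest neighbors; edges carry cosine similarity as weight.  Node
degree measures a term's connectedness in the neighborhood, which is how
the central adversities are ranked.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .embedding import EmbeddingMatrix
from .similarity import cosine_similarity, knn

__all__ = ["build_network", "rank_central_terms", "strongest_edge",
           "network_edges_frame", "write_graphml"]


def build_network(
    seeds: list[str],
    matrix: EmbeddingMatrix,
    k: int = 10,
    edge_rule: str = "knn",
    threshold: float | None = None,
) -> nx.Graph:
    """Undirected cosine-weighted neighborhood graph around seed terms.

    ``edge_rule="knn"`` (default) draws only seed-to-neighbor edges from the
    k-nearest-neighbor queries.  ``edge_rule="threshold"`` additionally
    connects every node pair whose cosine similarity exceeds ``threshold``.
    Unresolvable seeds raise; node attributes carry the code system and
    whether the node was a seed.
    """
    missing = [s for s in seeds if s not in matrix.vocabulary]
    if missing:
        raise KeyError(f"seed terms not in vocabulary: {missing}")
    if not seeds:
        raise ValueError("empty seed set")

    vocab = matrix.vocabulary
    graph = nx.Graph()
    for seed in seeds:
        graph.add_node(seed, system=vocab.systems[vocab.index[seed]], seed=True)
        for neighbor, sim in knn(seed, matrix, k=k).neighbors:
            if neighbor not in graph:
                graph.add_node(
                    neighbor, system=vocab.systems[vocab.index[neighbor]], seed=False
                )
            if neighbor != seed:
                graph.add_edge(seed, neighbor, weight=float(sim))

    if edge_rule == "threshold":
        if threshold is None:
            raise ValueError("threshold edge rule requires a threshold")
        nodes = sorted(graph.nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if graph.has_edge(a, b):
                    continue
                sim = cosine_similarity(matrix.vector(a), matrix.vector(b))
                if sim >= threshold:
                    graph.add_edge(a, b, weight=float(sim))
    elif edge_rule != "knn":
        raise ValueError(f"unknown edge rule: {edge_rule!r}")
    return graph


def rank_central_terms(graph: nx.Graph) -> list[tuple[str, int]]:
    """Terms by degree, descending; ties broken by label."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    return sorted(graph.degree, key=lambda p: (-p[1], p[0]))


def strongest_edge(graph: nx.Graph) -> tuple[str, str, float]:
    """Edge with the highest cosine similarity (deterministic tie-break)."""
    if graph.number_of_edges() == 0:
        raise ValueError("network has no edges")
    best = max(
        ((min(a, b), max(a, b), d["weight"]) for a, b, d in graph.edges(data=True)),
        key=lambda e: (e[2], e[0], e[1]),
    )
    return best


def network_edges_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = sorted(
        (min(a, b), max(a, b), d["weight"]) for a, b, d in graph.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["source", "target", "cosine_similarity"])


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
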
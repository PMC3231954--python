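"""Shared fixtures and graph builders for the test suite."""

from __future__ import annotations

import random

import pytest

from qclique import Graph, QuerySet


def graph_from_edge_labels(edges, extra=()):
    return Graph.from_edges(edges, extra_vertices=extra)


def complete_graph(n: int) -> Graph:
    labels = [f"v{i}" for i in range(n)]
    adjacency = [set(range(n)) - {i} for i in range(n)]
    return Graph(labels, adjacency)


def path_graph(n: int) -> Graph:
    return Graph.from_edges([(f"v{i}", f"v{i+1}") for i in range(n - 1)])


def cycle_graph(n: int) -> Graph:
    return Graph.from_edges(
        [(f"v{i}", f"v{(i + 1) % n}") for i in range(n)]
    )


def er_graph(n: int, p: float, rng: random.Random) -> Graph:
    """Erdős–Rényi G(n, p) keeping all n vertices (possibly isolated)."""
    edges = [
        (f"v{i}", f"v{j}")
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph.from_edges(edges, extra_vertices=[f"v{i}" for i in range(n)])


def random_query(graph: Graph, rng: random.Random, k: int | None = None) -> QuerySet:
    k = k if k is not None else rng.randint(1, graph.n_vertices)
    return QuerySet(frozenset(rng.sample(range(graph.n_vertices), k)))


def to_networkx(graph: Graph):
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(graph.n_vertices))
    for u in range(graph.n_vertices):
        for v in graph.adjacency[u]:
            if u < v:
                G.add_edge(u, v)
    return G


@pytest.fixture
def two_triangles() -> Graph:
    """Two triangles sharing the single vertex ``hub``."""
    return Graph.from_edges(
        [
            ("hub", "a1"), ("hub", "a2"), ("a1", "a2"),
            ("hub", "b1"), ("hub", "b2"), ("b1", "b2"),
        ]
    )
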
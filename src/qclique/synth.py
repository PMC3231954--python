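"""Synthetic benchmark graphs and planted modules.

The R-MAT generator draws each edge by recursively choosing one quadrant of
the adjacency matrix with probabilities (a, b, c, d); with the skewed
defaults (0.45, 0.15, 0.15, 0.25) this yields sparse graphs with a
heavy-tailed, power-law-like degree distribution resembling protein
functional-association networks.  Defaults follow the benchmark design the
package is validated against: vertices a power of two, average degree 14
(edge_factor 7, i.e. |E| = 7·|V| before isolated-vertex removal).

Self-loops and duplicate draws are rejected and redrawn so the edge count
is exact; the directed quadrant draw is symmetrised by sorting endpoints.
All randomness flows from one explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import required_degree
from .netio import Graph

__all__ = ["RMATParams", "rmat_generate", "remove_isolated", "plant_module"]


@dataclass(frozen=True)
class RMATParams:
    """R-MAT generation parameters: 2**scale vertices,
    edge_factor * 2**scale distinct undirected edges, quadrant
    probabilities (a, b, c, d) summing to 1."""

    scale: int
    edge_factor: int = 7
    a: float = 0.45
    b: float = 0.15
    c: float = 0.15
    d: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.edge_factor < 1:
            raise ValueError("edge_factor must be >= 1")
        total = self.a + self.b + self.c + self.d
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"quadrant probabilities must sum to 1, got {total}")

    @property
    def n_vertices(self) -> int:
        return 1 << self.scale

    @property
    def n_edges(self) -> int:
        return self.edge_factor << self.scale


def rmat_generate(params: RMATParams) -> Graph:
    """Generate an R-MAT graph; deterministic for a given seed.

    Draws are vectorised: each attempt picks one quadrant per bit level,
    assembling the row/column indices of the endpoint pair.  Self-loops and
    already-present undirected edges are rejected until exactly
    ``params.n_edges`` distinct edges exist.  Raises if that many simple
    edges cannot exist.
    """
    n = params.n_vertices
    target = params.n_edges
    if target > n * (n - 1) // 2:
        raise ValueError(
            f"{target} edges requested but a simple graph on {n} vertices "
            f"admits at most {n * (n - 1) // 2}"
        )
    rng = np.random.default_rng(params.seed)
    probs = np.array([params.a, params.b, params.c, params.d])
    weights = 1 << np.arange(params.scale - 1, -1, -1, dtype=np.int64)
    seen: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    while len(edges) < target:
        batch = max(1024, 2 * (target - len(edges)))
        quadrants = rng.choice(4, size=(batch, params.scale), p=probs)
        u = ((quadrants >> 1) * weights).sum(axis=1)
        v = ((quadrants & 1) * weights).sum(axis=1)
        lo = np.minimum(u, v)
        hi = np.maximum(u, v)
        for a, b in zip(lo.tolist(), hi.tolist()):
            if a == b:
                continue
            pair = (a, b)
            if pair in seen:
                continue
            seen.add(pair)
            edges.append(pair)
            if len(edges) == target:
                break
    labels = [f"v{i}" for i in range(n)]
    adjacency: list[set[int]] = [set() for _ in range(n)]
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    return Graph(labels, adjacency)


def remove_isolated(graph: Graph) -> Graph:
    """Induced subgraph on vertices of degree >= 1, preserving labels and
    the relative order of the surviving vertices."""
    keep = [v for v in range(graph.n_vertices) if graph.adjacency[v]]
    remap = {v: i for i, v in enumerate(keep)}
    labels = [graph.labels[v] for v in keep]
    adjacency = [{remap[u] for u in graph.adjacency[v]} for v in keep]
    return Graph(labels, adjacency)


def plant_module(
    graph: Graph,
    size: int,
    gamma,
    query_fraction: float,
    seed: int,
) -> tuple[Graph, frozenset[int], frozenset[int]]:
    """Embed a γ-dense module of ``size`` vertices into a copy of ``graph``.

    Selects ``size`` vertices uniformly at random, then adds internal edges
    until every selected vertex has at least ``required_degree(gamma, size)``
    neighbours inside the set (edges are added between the currently most
    deficient pairs, deterministically given the seed).  The first
    ``ceil(query_fraction * size)`` selected vertices are marked as query
    vertices.  Returns (modified graph, planted set, query additions).
    """
    if size < 2:
        raise ValueError("planted module size must be >= 2")
    if size > graph.n_vertices:
        raise ValueError("planted module larger than the graph")
    need = required_degree(gamma, size)
    g = Fraction(str(gamma)) if isinstance(gamma, float) else Fraction(gamma)
    if not Fraction(1, 2) < g <= 1:
        raise ValueError(f"gamma must lie in (0.5, 1], got {g}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(graph.n_vertices, size=size, replace=False).tolist()
    planted = frozenset(chosen)
    adjacency = [set(a) for a in graph.adjacency]

    def internal_degree(v: int) -> int:
        return len(adjacency[v] & planted)

    while True:
        deficient = sorted(
            (v for v in planted if internal_degree(v) < need),
            key=lambda v: (internal_degree(v), v),
        )
        if not deficient:
            break
        v = deficient[0]
        partners = sorted(
            (u for u in planted if u != v and u not in adjacency[v]),
            key=lambda u: (internal_degree(u), u),
        )
        u = partners[0]  # always exists: a complete set satisfies any gamma
        adjacency[v].add(u)
        adjacency[u].add(v)

    n_query = int(np.ceil(query_fraction * size))
    query_additions = frozenset(chosen[:n_query])
    return Graph(list(graph.labels), adjacency), planted, query_additions
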
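"""Brute-force reference enumerator for small graphs.

Checks every non-empty vertex subset against the density and enrichment
predicates and keeps the subsets that are strict subsets of no other kept
subset.  Feasibility is not anti-monotone — a superset of an infeasible set
can be feasible — so maximality must be (and is) checked against *all* kept
feasible sets, not against single-vertex extensions.  The predicates
(``required_degree``, exact rational enrichment) are shared with the
production enumerator so any disagreement isolates a search bug rather than
a predicate bug.

Intentionally naive; guarded to graphs of at most 22 vertices.  Subset
iteration is vectorised over bitmask arrays so the guard is actually
reachable in tests.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Params, required_degree
from .netio import Graph, QuerySet

__all__ = ["brute_force_maximal", "MAX_ORACLE_VERTICES"]

MAX_ORACLE_VERTICES = 22

_POP16 = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.uint8)


def _popcount(a: np.ndarray) -> np.ndarray:
    return (_POP16[a & 0xFFFF] + _POP16[(a >> np.uint32(16)) & 0xFFFF]).astype(np.int64)


def brute_force_maximal(graph: Graph, Q: QuerySet, params: Params) -> list[Module]:
    """All maximal μ,γ-quasi-cliques of size >= ``params.min_size`` by
    exhaustive subset enumeration.

    Output order matches the production enumerator: size descending, then
    lexicographic sorted-label list.
    """
    n = graph.n_vertices
    if n > MAX_ORACLE_VERTICES:
        raise ValueError(
            f"brute-force oracle refuses graphs with more than "
            f"{MAX_ORACLE_VERTICES} vertices (got {n})"
        )
    if not Q.members:
        raise ValueError("query set must be non-empty")

    adj = [np.uint32(m) for m in graph.adjacency_masks()]
    masks = np.arange(1, 1 << n, dtype=np.uint32)
    size = _popcount(masks)
    req = np.array(
        [0] + [required_degree(params.gamma, s) for s in range(1, n + 1)],
        dtype=np.int64,
    )
    need = req[size]
    ok = size >= params.min_size
    for v in range(n):
        inside = (masks >> np.uint32(v)) & 1
        deg = _popcount(masks & adj[v])
        ok &= (inside == 0) | (deg >= need)
    q_mask = np.uint32(Q.mask())
    n_query = _popcount(masks & q_mask)
    mu = params.mu
    ok &= mu.denominator * n_query >= mu.numerator * size
    feasible = masks[ok]

    # maximality: drop any feasible set strictly contained in another
    order = np.argsort(-size[ok], kind="stable")
    feasible = feasible[order]
    keep: list[int] = []
    if len(feasible):
        accepted = np.empty(len(feasible), dtype=np.uint32)
        n_acc = 0
        for f in feasible:
            if n_acc and np.any((accepted[:n_acc] & f) == f):
                continue  # some larger (or equal-size distinct) accepted superset
            accepted[n_acc] = f
            n_acc += 1
            keep.append(int(f))

    qmembers = Q.members
    modules = []
    for m in keep:
        vs = frozenset(i for i in range(n) if (m >> i) & 1)
        modules.append(Module(vs, len(vs & qmembers)))
    modules.sort(
        key=lambda mod: (
            -len(mod.vertices),
            sorted(graph.labels[v] for v in mod.vertices),
        )
    )
    return modules
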
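"""Backtracking enumeration of maximal dense, enriched modules.

A module is a vertex set S of an undirected graph G in which every member
is adjacent to at least ``ceil(gamma * (|S|-1))`` other members (γ-dense,
γ ∈ (0.5, 1]) and at least ``mu * |S|`` members belong to a user-supplied
query set Q (μ-enriched, μ ∈ (0, 1]).  The enumerator returns exactly the
*maximal* such sets — those with no strict superset that is again dense and
enriched — of at least ``min_size`` vertices.

The search is agglomerative: it seeds a subgraph S from one query vertex at
a time and grows it from a candidate set C, backtracking when S cannot be
extended into a feasible module.  Because density with γ > 0.5 forces every
pair of members to lie within two edges of each other in G, candidates are
restricted to the distance-≤2 neighbourhood of every member (Pei et al.'s
diameter bound).  Three further prunes are applied at every node:

* expansion feasibility — a member v whose combined subgraph/candidate
  adjacency ``s_a(v) + c_a(v)`` falls below the degree a final module of the
  best achievable size would demand proves no supergraph of S within S ∪ C
  can be dense, so the branch stops (after emitting S itself if feasible);
* candidate degree feasibility — a candidate v with
  ``s_a(v) + c_a(v) < ceil(gamma * (|S| + c_a(v)))`` can never reach the
  density bar in any extension and is dropped from C (iterated to a fixed
  point, since removals lower other candidates' ``c_a``);
* enrichment feasibility — if even absorbing every query candidate cannot
  satisfy ``|S∩Q| + |C∩Q| >= mu * (|S| + |C∩Q|)`` the branch is dead, and a
  non-query candidate whose admission would make that bound permanently
  unsatisfiable is dropped.

Feasibility is *not* anti-monotone (a superset of an infeasible set may be
feasible), so discovered sets are only candidate maximal modules; a global
subset filter over everything emitted is the correctness mechanism, and the
bitmap registry's "some discovered module already covers S ∪ C" early
backtrack is purely an optimisation.

γ and μ arithmetic is exact: both are held as rationals and every threshold
comparison is cross-multiplied integer arithmetic, so boundary cases like
integral γ(|S|-1) never depend on floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .bitmap import FlatBitmapIndex, make_index
from .netio import Graph, QuerySet

__all__ = [
    "Params",
    "SearchState",
    "Module",
    "required_degree",
    "is_gamma_dense",
    "is_mu_enriched",
    "initial_candidates",
    "extension_feasible",
    "prune_candidates_density",
    "prune_enrichment",
    "enumerate_dense",
    "maximality_filter",
]


def _as_fraction(value) -> Fraction:
    """Exact rational from float/str/int/Fraction.

    Floats go through their shortest decimal repr, so 0.75 becomes 3/4 and
    0.999 becomes 999/1000 — the values a user means, not the binary ones.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class Params:
    """Run parameters: density γ ∈ (0.5, 1], enrichment μ ∈ (0, 1], and the
    smallest module size worth reporting (singletons are vacuously dense,
    so the default is 2)."""

    gamma: Fraction
    mu: Fraction
    min_size: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", _as_fraction(self.gamma))
        object.__setattr__(self, "mu", _as_fraction(self.mu))
        if not Fraction(1, 2) < self.gamma <= 1:
            raise ValueError(
                f"gamma must lie in (0.5, 1], got {self.gamma}"
            )
        if not 0 < self.mu <= 1:
            raise ValueError(f"mu must lie in (0, 1], got {self.mu}")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass(frozen=True)
class Module:
    """A maximal dense, enriched vertex set."""

    vertices: frozenset[int]
    n_query: int

    def __len__(self) -> int:
        return len(self.vertices)


def required_degree(gamma, size: int) -> int:
    """Minimum within-module degree ``ceil(gamma * (size - 1))``.

    Computed on the rational form of gamma with integer ceiling division,
    so no floating-point comparison is involved.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    g = _as_fraction(gamma)
    return -((-g.numerator * (size - 1)) // g.denominator)


def is_gamma_dense(graph: Graph, S: Iterable[int], gamma) -> bool:
    """True iff every member of S has at least ``required_degree(gamma, |S|)``
    neighbours inside S.  A singleton is vacuously dense."""
    vs = set(S)
    if not vs:
        raise ValueError("S must be non-empty")
    need = required_degree(gamma, len(vs))
    return all(len(graph.adjacency[v] & vs) >= need for v in vs)


def is_mu_enriched(S: Iterable[int], Q: QuerySet | Iterable[int], mu) -> bool:
    """True iff at least ``mu * |S|`` members of S belong to Q
    (cross-multiplied, no floating point)."""
    vs = set(S)
    if not vs:
        raise ValueError("S must be non-empty")
    members = Q.members if isinstance(Q, QuerySet) else set(Q)
    m = _as_fraction(mu)
    return m.denominator * len(vs & set(members)) >= m.numerator * len(vs)


def initial_candidates(graph: Graph, v0: int) -> list[int]:
    """All vertices within distance 2 of ``v0`` (excluding ``v0``),
    ascending by internal index — the candidate universe N²({v0}) \\ {v0}."""
    adj = graph.adjacency
    reach = set(adj[v0])
    for u in adj[v0]:
        reach |= adj[u]
    reach.discard(v0)
    return sorted(reach)


# ---------------------------------------------------------------------------
# SearchState and the spec-level pruning operations
# ---------------------------------------------------------------------------


@dataclass
class SearchState:
    """Snapshot of one search node: current subgraph S, ordered candidates C,
    per-vertex adjacency counts into S (``s_a``) and into C (``c_a``), and
    the query vertex the search was seeded from.  Carries a reference to the
    host graph so the pruning operations can update counts after removals.
    """

    S: set[int]
    C: list[int]
    s_a: dict[int, int]
    c_a: dict[int, int]
    seed: int
    graph: Graph = field(default=None, repr=False, compare=False)

    @classmethod
    def from_sets(cls, graph: Graph, S: Iterable[int], C: Iterable[int], seed: int) -> "SearchState":
        S = set(S)
        C = sorted(set(C) - S)
        if seed not in S:
            raise ValueError("seed must be a member of S")
        s_a, c_a = {}, {}
        cset = set(C)
        for v in S | cset:
            s_a[v] = len(graph.adjacency[v] & S)
            c_a[v] = len(graph.adjacency[v] & cset)
        return cls(S, C, s_a, c_a, seed, graph)

    def recompute_counts(self) -> tuple[dict[int, int], dict[int, int]]:
        """Fresh s_a/c_a from the graph — for checking the incremental ones."""
        cset = set(self.C)
        s_a = {v: len(self.graph.adjacency[v] & self.S) for v in self.S | cset}
        c_a = {v: len(self.graph.adjacency[v] & cset) for v in self.S | cset}
        return s_a, c_a


def extension_feasible(state: SearchState, gamma) -> bool:
    """Expansion-feasibility bound over the members of S (Property 2 style).

    False means no strict supergraph of S built from C can be γ-dense: some
    member's subgraph+candidate adjacency ``s_a(v) + c_a(v)`` already falls
    short of ``required_degree(gamma, |S| + c_a(v))``, the degree demanded
    at the best size v can reach, so the search should emit S (if S itself
    qualifies) and backtrack.  With C empty this reduces to the density test
    on S itself.
    """
    g = _as_fraction(gamma)
    size = len(state.S)
    for v in state.S:
        ca = state.c_a.get(v, 0)
        if state.s_a.get(v, 0) + ca < required_degree(g, size + ca):
            return False
    return True


def prune_candidates_density(state: SearchState, gamma) -> SearchState:
    """Drop candidates that can never reach the density bar (Property 3).

    A candidate v survives only if ``s_a(v) + c_a(v) >=
    ceil(gamma * (|S| + c_a(v)))`` — the degree it would need were it to
    join S together with all of its candidate neighbours.  Removals lower
    other candidates' ``c_a``, so the rule is re-applied to a fixed point;
    counts in the returned state reflect the pruned candidate list.
    """
    if state.graph is None:
        raise ValueError("state must carry its graph (use SearchState.from_sets)")
    g = _as_fraction(gamma)
    adj = state.graph.adjacency_masks()
    S_mask = 0
    for v in state.S:
        S_mask |= 1 << v
    C_mask = 0
    for v in state.C:
        C_mask |= 1 << v
    C_mask, _ = _prune_candidates_masks(
        adj, S_mask, C_mask, g.numerator, g.denominator, len(state.S),
        True, 0, 0, 0, 1, False,
    )
    return SearchState.from_sets(
        state.graph, state.S, [v for v in state.C if (C_mask >> v) & 1], state.seed
    )


def _prune_candidates_masks(
    adj: Sequence[int],
    S_mask: int,
    C_mask: int,
    gn: int,
    gd: int,
    size: int,
    use_density: bool,
    q_mask: int,
    sq: int,
    mn: int,
    md: int,
    use_enrichment: bool,
) -> tuple[int, bool]:
    """Bitmask kernel for Properties 3 and 4: returns (pruned C, branch alive).

    Iterates both rules to a fixed point.  ``branch alive`` False means even
    absorbing every query candidate cannot make any extension of S enriched
    (which also implies S itself is not enriched).
    """
    while True:
        changed = False
        if use_enrichment:
            cq = (C_mask & q_mask).bit_count()
            # Property 4 branch bound: |S∩Q| + |C∩Q| >= mu (|S| + |C∩Q|)
            if md * (sq + cq) < mn * (size + cq):
                return 0, False
            # vertex-removal rule: a non-query candidate is admissible only
            # if the bound still holds after it joins S
            if md * (sq + cq) < mn * (size + 1 + cq):
                nonq = C_mask & ~q_mask
                if nonq:
                    C_mask &= q_mask
                    changed = True
        if use_density:
            m = C_mask
            while m:
                low = m & -m
                v = low.bit_length() - 1
                m ^= low
                av = adj[v]
                ca = (av & C_mask).bit_count()
                sa = (av & S_mask).bit_count()
                # Property 3: s_a + c_a >= ceil(gamma (|S| + c_a))
                if sa + ca < -((-gn * (size + ca)) // gd):
                    C_mask ^= low
                    changed = True
        if not changed:
            return C_mask, True


def prune_enrichment(state: SearchState, Q: QuerySet | Iterable[int], mu) -> bool:
    """Enrichment-feasibility bound (Property 4).

    True iff ``|S∩Q| + |C∩Q| >= mu * (|S| + |C∩Q|)`` — the enrichment the
    best extension (absorbing every query candidate) could reach.  When
    False the branch is abandoned: no supergraph of S drawn from C can be
    μ-enriched (nor, since the bound is monotone in the number of query
    vertices added, can S itself be).  When True, any non-query candidate
    whose admission would make the bound permanently unsatisfiable is
    removed from ``state.C`` in place (counts are refreshed).
    """
    members = Q.members if isinstance(Q, QuerySet) else frozenset(Q)
    m = _as_fraction(mu)
    sq = len(state.S & members)
    cq = len(set(state.C) & members)
    size = len(state.S)
    if m.denominator * (sq + cq) < m.numerator * (size + cq):
        return False
    if m.denominator * (sq + cq) < m.numerator * (size + 1 + cq):
        kept = [v for v in state.C if v in members]
        if len(kept) != len(state.C):
            state.C = kept
            if state.graph is not None:
                state.s_a, state.c_a = state.recompute_counts()
    return True


# ---------------------------------------------------------------------------
# The enumerator
# ---------------------------------------------------------------------------


def _bits(mask: int):
    """Yield set-bit positions of ``mask`` in ascending order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _n2_mask(adj: Sequence[int], v: int, cache: dict[int, int]) -> int:
    """Bitmask of vertices within distance ≤ 2 of v, excluding v itself."""
    m = cache.get(v)
    if m is None:
        m = adj[v]
        for u in _bits(adj[v]):
            m |= adj[u]
        m &= ~(1 << v)
        cache[v] = m
    return m


def enumerate_dense(
    graph: Graph,
    Q: QuerySet,
    params: Params,
    *,
    index: str = "hierarchical",
    use_expansion_bound: bool = True,
    use_candidate_prune: bool = True,
    use_enrichment_prune: bool = True,
    stats: dict | None = None,
) -> list[Module]:
    """Enumerate all maximal μ,γ-quasi-cliques of size ≥ ``params.min_size``.

    Seeds one search per query vertex in ascending index order; each search
    excludes earlier seeds from its candidate universe, so every module is
    discovered from its smallest-index query member exactly once (every
    feasible module contains a query vertex, because ``mu > 0`` forces
    ``|S ∩ Q| >= 1``).  The ``use_*`` switches disable individual pruning
    properties — output is identical either way, only time changes.

    Deterministic: fixed inputs and vertex order give identical output sets
    in identical order (size descending, then lexicographic label list).
    """
    if not isinstance(params, Params):
        raise TypeError("params must be a Params instance")
    if not Q.members:
        raise ValueError("query set must be non-empty")
    n = graph.n_vertices
    if any(not 0 <= v < n for v in Q.members):
        raise ValueError("query set contains out-of-range vertex indices")

    adj = graph.adjacency_masks()
    q_mask = Q.mask()
    gn, gd = params.gamma.numerator, params.gamma.denominator
    mn, md = params.mu.numerator, params.mu.denominator
    min_size = params.min_size
    registry = make_index(index)
    n2_cache: dict[int, int] = {}
    found: list[int] = []  # emitted candidate-module masks
    node_count = 0

    def req(size: int) -> int:
        return -((-gn * (size - 1)) // gd)

    def feasible_mask(S_mask: int, size: int, sq: int) -> bool:
        if md * sq < mn * size:
            return False
        need = req(size)
        for v in _bits(S_mask):
            if (adj[v] & S_mask).bit_count() < need:
                return False
        return True

    def has_feasible_extension(S_mask: int, size: int, sq: int) -> bool:
        """Any single vertex w anywhere in G with S ∪ {w} dense+enriched?"""
        ok_query = md * (sq + 1) >= mn * (size + 1)
        if not ok_query:
            return False
        ok_nonquery = md * sq >= mn * (size + 1)
        r = req(size + 1)
        deficient = 0
        union = 0
        for v in _bits(S_mask):
            av = adj[v]
            union |= av
            if (av & S_mask).bit_count() < r:
                deficient |= 1 << v
        if deficient:
            W = -1
            for v in _bits(deficient):
                W &= adj[v]
                if not W:
                    return False
        else:
            W = union
        W &= ~S_mask
        if not ok_nonquery:
            W &= q_mask
        for w in _bits(W):
            if (adj[w] & S_mask).bit_count() >= r:
                return True
        return False

    def recurse(S_mask: int, C_mask: int, size: int, sq: int) -> None:
        nonlocal node_count
        node_count += 1
        if use_candidate_prune or use_enrichment_prune:
            C_mask, alive = _prune_candidates_masks(
                adj, S_mask, C_mask, gn, gd, size, use_candidate_prune,
                q_mask, sq, mn, md, use_enrichment_prune,
            )
            if not alive:
                # even S itself cannot be enriched here (mu-bound monotone)
                return
        # bitmap early backtrack: an already-discovered module covers S ∪ C
        if registry.superset_registered(_bits(S_mask | C_mask)):
            return
        if size >= min_size and feasible_mask(S_mask, size, sq):
            if not has_feasible_extension(S_mask, size, sq):
                if not registry.superset_registered(_bits(S_mask)):
                    registry.register(_bits(S_mask))
                    found.append(S_mask)
        if not C_mask:
            return
        if use_expansion_bound:
            for v in _bits(S_mask):
                av = adj[v]
                ca = (av & C_mask).bit_count()
                if (av & S_mask).bit_count() + ca < req(size + ca):
                    return  # Property 2: no dense supergraph within S ∪ C
        m = C_mask
        while m:
            low = m & -m
            v = low.bit_length() - 1
            m ^= low
            child_C = C_mask & -(low << 1) & _n2_mask(adj, v, n2_cache)
            recurse(S_mask | low, child_C, size + 1, sq + ((q_mask >> v) & 1))

    banned = 0
    for v0 in sorted(Q.members):
        C0 = _n2_mask(adj, v0, n2_cache) & ~banned
        recurse(1 << v0, C0, 1, 1)
        banned |= 1 << v0

    modules = maximality_filter(
        [frozenset(_bits(m)) for m in found], graph, Q, params
    )
    if stats is not None:
        stats["nodes"] = node_count
        stats["emitted"] = len(found)
        stats["registered"] = registry.n_registered
    # soundness assertion on every run: outputs pass both predicates
    for mod in modules:
        assert is_gamma_dense(graph, mod.vertices, params.gamma)
        assert is_mu_enriched(mod.vertices, Q, params.mu)
    return modules


def maximality_filter(
    modules: Iterable[Iterable[int]],
    graph: Graph,
    Q: QuerySet,
    params: Params,
) -> list[Module]:
    """Keep only sets that are not strict subsets of another given set.

    The surviving collection is mutually incomparable under ⊂.  Implemented
    with a flat membership index: the AND of the members' module bitsets
    names every input set covering the probe, so a set is dropped exactly
    when that AND contains a bit other than its own.
    """
    unique = sorted(
        {frozenset(m) for m in modules},
        key=lambda s: (-len(s), sorted(s)),
    )
    index = FlatBitmapIndex()
    ids = [index.register(s) for s in unique]
    out: list[Module] = []
    qmembers = Q.members
    for mid, vs in zip(ids, unique):
        cover = index.covering_modules(vs)
        if cover & ~(1 << mid):
            continue  # a strict superset (same-size duplicates were merged)
        out.append(Module(vs, len(vs & qmembers)))
    out.sort(key=lambda m: (-len(m.vertices), sorted(graph.labels[v] for v in m.vertices)))
    return out
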
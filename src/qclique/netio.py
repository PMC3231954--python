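"""Network and query-set I/O.

Graphs are undirected, simple and unweighted: vertex identity is the exact
label string, edges are deduplicated at read time and any edge weight or
confidence score (e.g. the STRING ``combined_score``) is only used as a
read-time threshold.  Internally vertices carry contiguous integer indices
assigned in first-appearance order, which fixes the deterministic candidate
ordering used by the enumerator.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger("qclique")

__all__ = [
    "Graph",
    "QuerySet",
    "ParseError",
    "EmptyGraphError",
    "NoQueryVerticesError",
    "read_edge_list",
    "read_string_links",
    "read_query_set",
    "write_edge_list",
    "write_modules",
    "write_metadata",
]


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class EmptyGraphError(ValueError):
    """An input file produced a graph with no vertices."""


class NoQueryVerticesError(ValueError):
    """None of the query identifiers are present in the graph."""


@dataclass
class Graph:
    """Undirected simple graph with string vertex labels.

    Invariants: adjacency is symmetric, has no self-loops and no parallel
    edges (``adjacency[v]`` is a set of neighbour indices).
    """

    labels: list[str]
    adjacency: list[set[int]]
    _label_index: dict[str, int] = field(default=None, repr=False, compare=False)
    _masks: list[int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.adjacency):
            raise ValueError("labels and adjacency length mismatch")
        if self._label_index is None:
            self._label_index = {lab: i for i, lab in enumerate(self.labels)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_vertices: Iterable[str] = (),
    ) -> "Graph":
        """Build a graph from labelled edges.

        Self-loops are dropped (the endpoint label is still registered) and
        reciprocal duplicates collapse to a single undirected edge.  Indices
        follow first appearance in the edge stream.
        """
        labels: list[str] = []
        index: dict[str, int] = {}
        adjacency: list[set[int]] = []

        def vid(lab: str) -> int:
            i = index.get(lab)
            if i is None:
                i = len(labels)
                index[lab] = i
                labels.append(lab)
                adjacency.append(set())
            return i

        for a, b in edges:
            ia, ib = vid(a), vid(b)
            if ia == ib:
                continue
            adjacency[ia].add(ib)
            adjacency[ib].add(ia)
        for lab in extra_vertices:
            vid(lab)
        return cls(labels, adjacency, _label_index=index)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def index_of(self, label: str) -> int:
        return self._label_index[label]

    def has_label(self, label: str) -> bool:
        return label in self._label_index

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edges as label pairs, each reported once."""
        out = []
        for u, nbrs in enumerate(self.adjacency):
            for v in nbrs:
                if u < v:
                    out.append((self.labels[u], self.labels[v]))
        return out

    def adjacency_masks(self) -> list[int]:
        """Per-vertex neighbour bitmasks (bit ``u`` set iff ``u`` adjacent)."""
        if self._masks is None:
            masks = []
            for nbrs in self.adjacency:
                m = 0
                for u in nbrs:
                    m |= 1 << u
                masks.append(m)
            self._masks = masks
        return self._masks

    def check_invariants(self) -> None:
        """Raise AssertionError if the simple-graph invariants are violated."""
        for v, nbrs in enumerate(self.adjacency):
            assert v not in nbrs, f"self-loop at vertex {v}"
            for u in nbrs:
                assert v in self.adjacency[u], f"asymmetric edge ({v},{u})"


@dataclass(frozen=True)
class QuerySet:
    """The knowledge-prior subset Q of vertices, as graph indices.

    ``missing`` records query identifiers that were absent from the graph
    (reported, never silently dropped).
    """

    members: frozenset[int]
    missing: tuple[str, ...] = ()

    def mask(self) -> int:
        m = 0
        for v in self.members:
            m |= 1 << v
        return m


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_edge_list(
    path: str | os.PathLike,
    delimiter: str | None = None,
    comment_prefix: str = "#",
) -> Graph:
    """Read a 2+-column whitespace/``delimiter``-separated edge list.

    Lines starting with ``comment_prefix`` and blank lines are skipped.
    Columns beyond the first two are ignored.  A line with fewer than two
    tokens is a :class:`ParseError` naming the line number; a file yielding
    no vertices is an :class:`EmptyGraphError`.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (comment_prefix and line.startswith(comment_prefix)):
                continue
            tokens = line.split(delimiter)
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    graph = Graph.from_edges(edges)
    if graph.n_vertices == 0:
        raise EmptyGraphError(f"{path}: no vertices found")
    return graph


def read_string_links(path: str | os.PathLike, score_threshold: int) -> Graph:
    """Read a STRING ``protein.links`` file, keeping edges with
    ``combined_score >= score_threshold``.

    The expected layout is a header line ``protein1 protein2 combined_score``
    followed by data rows; a missing header is tolerated when the first row
    already parses as data.  Both endpoint proteins of every row are
    registered as vertices even when the row's edge is filtered out, so
    sub-threshold proteins remain as isolated vertices (use
    :func:`qclique.synth.remove_isolated` to drop them).
    """
    if not 0 <= int(score_threshold) <= 1000:
        raise ValueError("score_threshold must be in [0, 1000]")
    edges: list[tuple[str, str]] = []
    vertices: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns "
                    f"(protein1 protein2 combined_score), got {len(tokens)}"
                )
            try:
                score = int(tokens[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: non-integer combined_score "
                    f"{tokens[2]!r}"
                ) from None
            vertices.append(tokens[0])
            vertices.append(tokens[1])
            if score >= score_threshold:
                edges.append((tokens[0], tokens[1]))
    graph = Graph.from_edges(edges, extra_vertices=vertices)
    if graph.n_vertices == 0:
        raise EmptyGraphError(f"{path}: no vertices found")
    return graph


def read_query_set(path: str | os.PathLike, graph: Graph) -> QuerySet:
    """Read one vertex identifier per line and map to graph indices.

    Identifiers absent from the graph are collected into ``missing`` and
    reported through the package logger; if *no* identifier matches, the
    enumeration would be vacuous and :class:`NoQueryVerticesError` is raised.
    """
    members: set[int] = set()
    missing: list[str] = []
    with open(path) as fh:
        for raw in fh:
            lab = raw.strip()
            if not lab:
                continue
            if graph.has_label(lab):
                members.add(graph.index_of(lab))
            else:
                missing.append(lab)
    if not members:
        raise NoQueryVerticesError(
            f"{path}: none of the query identifiers are present in the graph"
        )
    if missing:
        logger.warning(
            "%d query identifier(s) not in graph: %s",
            len(missing),
            ", ".join(missing),
        )
    return QuerySet(frozenset(members), tuple(missing))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    """Write text to ``path`` via a temp file so no partial output is left."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".qclique-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_edge_list(graph: Graph, path: str | os.PathLike) -> None:
    """Write the graph as a tab-separated edge list (one edge per line)."""
    lines = [f"{a}\t{b}\n" for a, b in graph.edges()]
    _atomic_write(path, "".join(lines))


def module_rows(
    modules: Sequence[Iterable[int]],
    graph: Graph,
    query: QuerySet,
    gamma,
) -> list[tuple]:
    """Summary rows for a collection of modules, in output order.

    Each row is (size, n_query, density_ratio, enrichment_ratio, labels)
    where density_ratio is the minimum over members of
    ``|adj(v) ∩ S| / (|S|-1)`` (1.0 for singletons) and rows are ordered by
    size descending then lexicographically by the joined label list.
    """
    rows = []
    for mod in modules:
        vs = set(mod)
        if not vs:
            raise ValueError("empty module")
        size = len(vs)
        nq = len(vs & query.members)
        if size == 1:
            density = 1.0
        else:
            density = min(len(graph.adjacency[v] & vs) for v in vs) / (size - 1)
        labels = ",".join(sorted(graph.labels[v] for v in vs))
        rows.append((size, nq, density, nq / size, labels))
    rows.sort(key=lambda r: (-r[0], r[4]))
    return rows


def write_modules(
    modules: Sequence[Iterable[int]],
    graph: Graph,
    query: QuerySet,
    gamma,
    path: str | os.PathLike,
) -> None:
    """Write discovered modules as a TSV.

    Columns: module_id, size, n_query_members, density_ratio,
    enrichment_ratio, vertices (comma-joined sorted labels).  Rows are
    ordered by size descending then lexicographic label list; an empty
    module list yields the header only.
    """
    out = ["module_id\tsize\tn_query_members\tdensity_ratio\tenrichment_ratio\tvertices\n"]
    for mid, (size, nq, density, enrich, labels) in enumerate(
        module_rows(modules, graph, query, gamma), start=1
    ):
        out.append(f"{mid}\t{size}\t{nq}\t{density:.4f}\t{enrich:.4f}\t{labels}\n")
    _atomic_write(path, "".join(out))


def write_metadata(path: str | os.PathLike, metadata: dict) -> None:
    """Write the JSON run-metadata sidecar (parameters, seed, graph stats)."""
    _atomic_write(path, json.dumps(metadata, indent=2, default=str) + "\n")
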
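"""Registry of discovered modules with superset queries.

The enumerator numbers modules sequentially as it finds them and, for each
vertex, records which modules contain it as a bitset (bit *i* set iff module
*i* contains the vertex).  "Is some already-discovered module a superset of
this vertex set?" is then a bitwise AND across the members' bitsets: any
surviving bit names such a module, and the search may backtrack because no
extension of the current subgraph can be maximal.

Two interchangeable backends are provided.  The flat index ANDs the full
base-level bitsets.  The hierarchical index additionally keeps summary
layers — each byte of a layer is summarized by one bit in the layer above
(1 = byte nonzero) — and descends only into bytes whose summary AND is
nonzero, skipping zero regions of a large index.  Both answer every query
identically; only the work done differs.

Bitsets are Python arbitrary-precision ints, so the AND/shift kernels run
at C speed without an extra dependency.
"""

from __future__ import annotations

import os
from typing import Iterable

__all__ = ["FlatBitmapIndex", "HierarchicalBitmapIndex", "make_index"]

_BYTE = 8  # summary granule: one summary bit per byte of the layer below


class FlatBitmapIndex:
    """Module registry answering superset queries with a full bitwise AND."""

    def __init__(self) -> None:
        self._per_vertex: dict[int, int] = {}
        self._modules: list[frozenset[int]] = []

    @property
    def n_registered(self) -> int:
        return len(self._modules)

    @property
    def modules(self) -> list[frozenset[int]]:
        return self._modules

    def register(self, vertices: Iterable[int]) -> int:
        """Record a module; returns its sequential id (0-based)."""
        vs = frozenset(vertices)
        if not vs:
            raise ValueError("cannot register an empty module")
        mid = len(self._modules)
        bit = 1 << mid
        for v in vs:
            self._per_vertex[v] = self._per_vertex.get(v, 0) | bit
        self._modules.append(vs)
        return mid

    def superset_registered(self, vertices: Iterable[int]) -> bool:
        """True iff some registered module contains every given vertex."""
        acc = -1
        per_vertex = self._per_vertex
        for v in vertices:
            e = per_vertex.get(v)
            if not e:
                return False
            acc &= e
            if not acc:
                return False
        return acc != -1 and acc != 0

    def covering_modules(self, vertices: Iterable[int]) -> int:
        """Bitmask of ids of registered modules containing every vertex."""
        acc = -1
        for v in vertices:
            acc &= self._per_vertex.get(v, 0)
            if not acc:
                return 0
        return 0 if acc == -1 else acc


def _summarize(x: int) -> int:
    """One summary bit per byte of ``x`` (1 = byte nonzero)."""
    y = 0
    j = 0
    while x:
        if x & 0xFF:
            y |= 1 << j
        x >>= _BYTE
        j += 1
    return y


class HierarchicalBitmapIndex:
    """Module registry with byte-granular summary layers above the base.

    Each vertex's entry is a chain ``[base, level1, level2, ...]`` where bit
    *k* of level *l* is 1 iff byte *k* of level *l-1* is nonzero.  A new
    level is appended whenever the current top level outgrows one byte, so
    depth grows logarithmically (base 8) in the number of registered
    modules.  Entries are stored lazily: a vertex in no module carries no
    storage, and chains are deepened on demand.
    """

    def __init__(self) -> None:
        self._entries: dict[int, list[int]] = {}
        self._modules: list[frozenset[int]] = []
        self._depth = 0  # number of summary levels above the base

    @property
    def n_registered(self) -> int:
        return len(self._modules)

    @property
    def n_levels(self) -> int:
        """Total layers including the base level."""
        return self._depth + 1

    @property
    def modules(self) -> list[frozenset[int]]:
        return self._modules

    def register(self, vertices: Iterable[int]) -> int:
        vs = frozenset(vertices)
        if not vs:
            raise ValueError("cannot register an empty module")
        mid = len(self._modules)
        self._modules.append(vs)
        # Grow depth so that the top level fits in one byte.  Width of the
        # base is mid+1 bits; each level divides the width by 8.
        width = mid + 1
        depth = 0
        while width > _BYTE:
            width = (width + _BYTE - 1) // _BYTE
            depth += 1
        self._depth = max(self._depth, depth)
        for v in vs:
            chain = self._entries.get(v)
            if chain is None:
                chain = [0]
                self._entries[v] = chain
            while len(chain) <= self._depth:
                chain.append(_summarize(chain[-1]))
            idx = mid
            chain[0] |= 1 << idx
            for level in range(1, self._depth + 1):
                idx //= _BYTE
                chain[level] |= 1 << idx
        return mid

    def _chain(self, v: int) -> list[int] | None:
        chain = self._entries.get(v)
        if chain is None:
            return None
        while len(chain) <= self._depth:
            chain.append(_summarize(chain[-1]))
        return chain

    def superset_registered(self, vertices: Iterable[int]) -> bool:
        chains = []
        for v in set(vertices):
            chain = self._chain(v)
            if chain is None:
                return False
            chains.append(chain)
        if not chains:
            return False
        return self._descend(chains, self._depth, 0)

    def _descend(self, chains: list[list[int]], level: int, byte_idx: int) -> bool:
        """AND one byte of ``level`` across chains; recurse into set bits."""
        shift = byte_idx * _BYTE
        acc = 0xFF
        for chain in chains:
            acc &= chain[level] >> shift
            if not acc:
                return False
        acc &= 0xFF
        if not acc:
            return False
        if level == 0:
            return True  # a common module bit exists in this base byte
        while acc:
            low = acc & -acc
            bit = low.bit_length() - 1
            if self._descend(chains, level - 1, byte_idx * _BYTE + bit):
                return True
            acc ^= low
        return False

    def check_invariants(self) -> None:
        """Recompute every summary level from scratch and compare."""
        for v, chain in self._entries.items():
            for level in range(1, len(chain)):
                expected = _summarize(chain[level - 1])
                assert chain[level] & expected == expected, (
                    f"vertex {v} level {level}: summary missing bits"
                )
                assert chain[level] == expected, (
                    f"vertex {v} level {level}: stale summary bits"
                )

    def dump_counts(self, path: str | os.PathLike) -> None:
        """Debug TSV of per-vertex registered-module counts."""
        lines = ["vertex\tn_modules\n"]
        for v in sorted(self._entries):
            lines.append(f"{v}\t{self._entries[v][0].bit_count()}\n")
        with open(path, "w") as fh:
            fh.writelines(lines)


def make_index(kind: str):
    """Factory: ``"flat"`` or ``"hierarchical"`` (alias ``"hier"``)."""
    if kind == "flat":
        return FlatBitmapIndex()
    if kind in ("hierarchical", "hier"):
        return HierarchicalBitmapIndex()
    raise ValueError(f"unknown index kind: {kind!r}")
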
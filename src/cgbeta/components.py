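"""Gluing aligned triples into putative beta-sheet components.

Two aligned triples *overlap* when they share at least two of their three
grains (set-wise on grain ids; end/center roles are ignored).  The overlap
relation induces an undirected graph on the triples; its connected
components are the putative beta-sheets, each component's grain set being
the union of its member triples.

The default implementation glues triples through a union-find keyed on
2-subsets of grain ids — two triples overlap exactly when they share a
2-subset, so all members of a shared pair's bucket are united.  This is
linear in the number of triples and provably output-equivalent to the
quadratic pairwise-overlap scan, which is retained as
:func:`connected_components_bruteforce` (an explicit overlap graph handed to
networkx) and used as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .gro_io import Frame
from .triples import AlignedTriple

__all__ = [
    "SheetComponent",
    "are_overlapping",
    "connected_components",
    "connected_components_bruteforce",
    "grains_in_sheets",
]


@dataclass(frozen=True)
class SheetComponent:
    """A maximal set of overlap-connected triples."""

    component_id: int
    triples: frozenset[AlignedTriple]
    grain_ids: frozenset[int]
    peptide_ids: frozenset[int]

    @property
    def n_grains(self) -> int:
        return len(self.grain_ids)

    @property
    def n_triples(self) -> int:
        return len(self.triples)


def are_overlapping(a: AlignedTriple, b: AlignedTriple) -> bool:
    """True iff the two triples share at least two grain ids."""
    return len(a.grain_ids & b.grain_ids) >= 2


class _UnionFind:
    """Union-find with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


def _peptide_lookup(frame: Frame | None):
    if frame is None:
        return None
    return {g.grain_id: g.peptide_id for g in frame.grains}


def _build_components(groups: Iterable[Sequence[AlignedTriple]],
                      frame: Frame | None) -> list[SheetComponent]:
    pep = _peptide_lookup(frame)
    comps = []
    for group in groups:
        grains = frozenset(g for t in group for g in t)
        peptides = (frozenset(pep[g] for g in grains)
                    if pep is not None else frozenset())
        comps.append((grains, frozenset(group), peptides))
    # deterministic order: decreasing grain count, ties by smallest grain id
    comps.sort(key=lambda c: (-len(c[0]), min(c[0])))
    return [
        SheetComponent(component_id=i, triples=t, grain_ids=g, peptide_ids=p)
        for i, (g, t, p) in enumerate(comps)
    ]


def connected_components(triples: Iterable[AlignedTriple],
                         frame: Frame | None = None) -> list[SheetComponent]:
    """Partition triples into maximal overlap-connected groups.

    Pass the source ``frame`` to populate each component's peptide set.
    Output order is deterministic (largest grain set first, ties broken by
    smallest member grain id) and independent of input order.
    """
    tlist = sorted(set(triples))
    if not tlist:
        return []
    uf = _UnionFind(len(tlist))
    bucket: dict[tuple[int, int], int] = {}
    for i, t in enumerate(tlist):
        for pair in combinations(sorted(t.grain_ids), 2):
            j = bucket.setdefault(pair, i)
            if j != i:
                uf.union(i, j)
    groups: dict[int, list[AlignedTriple]] = {}
    for i, t in enumerate(tlist):
        groups.setdefault(uf.find(i), []).append(t)
    return _build_components(groups.values(), frame)


def connected_components_bruteforce(triples: Iterable[AlignedTriple],
                                    frame: Frame | None = None
                                    ) -> list[SheetComponent]:
    """Oracle: explicit O(T^2) pairwise-overlap graph, components via BFS."""
    tlist = sorted(set(triples))
    g = nx.Graph()
    g.add_nodes_from(tlist)
    for a, b in combinations(tlist, 2):
        if are_overlapping(a, b):
            g.add_edge(a, b)
    return _build_components(nx.connected_components(g), frame)


def grains_in_sheets(components: Iterable[SheetComponent]) -> frozenset[int]:
    """Union of all components' grain sets."""
    out: set[int] = set()
    for c in components:
        out |= c.grain_ids
    return frozenset(out)
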
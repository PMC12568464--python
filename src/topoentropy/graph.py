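"""Molecular graphs, degree pairs, and degree-pair edge partitions.

A molecular graph is the hydrogen-suppressed heavy-atom skeleton of a
molecule: vertices are atoms, edges are bonds.  Every quantity computed by
this package (the degree-based topological indices and their Shannon
entropies) depends on the graph only through its *degree-pair edge
partition*: the multiset of edges classified by the unordered pair of
endpoint degrees.  This module provides the graph container, degree
computation, partition extraction, and a feasibility check for whether a
given partition can be realized by a simple graph at all.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping, NamedTuple

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "GraphValidationError",
    "PartitionError",
    "DegreePair",
    "EdgePartition",
    "MolecularGraph",
    "FeasibilityReport",
    "vertex_degrees",
    "edge_partition",
    "validate_partition_realizability",
]


class GraphValidationError(ValueError):
    """Raised when an input graph violates the simple-graph contract."""


class PartitionError(ValueError):
    """Raised for malformed or infeasible degree-pair edge partitions."""


_DegreePairBase = NamedTuple("_DegreePairBase", [("d_lo", int), ("d_hi", int)])


class DegreePair(_DegreePairBase):
    """Unordered pair of endpoint degrees, stored canonically (d_lo <= d_hi).

    ``DegreePair(3, 2)`` and ``DegreePair(2, 3)`` compare equal; both
    normalize to ``(d_lo=2, d_hi=3)``.  Degrees must be positive integers —
    an edge endpoint always has degree at least 1.
    """

    __slots__ = ()

    def __new__(cls, d_lo: int, d_hi: int) -> "DegreePair":
        try:
            a, b = int(d_lo), int(d_hi)
        except (TypeError, ValueError) as exc:
            raise PartitionError(f"degrees must be integers, got ({d_lo!r}, {d_hi!r})") from exc
        if a != d_lo or b != d_hi:
            raise PartitionError(f"degrees must be integers, got ({d_lo!r}, {d_hi!r})")
        if a < 1 or b < 1:
            raise PartitionError(f"degrees must be >= 1, got ({d_lo}, {d_hi})")
        if a > b:
            a, b = b, a
        return super().__new__(cls, a, b)

    def __str__(self) -> str:
        return f"({self.d_lo},{self.d_hi})"


class EdgePartition(Mapping[DegreePair, int]):
    """Edge counts per degree pair — the joint degree matrix of a graph.

    Keys may be supplied as ``DegreePair`` or plain 2-tuples; they are
    canonicalized, and counts for the same unordered pair are merged.
    Zero counts are dropped.  Counts must be non-negative integers.
    """

    def __init__(self, counts: Mapping | Iterable[tuple]) -> None:
        items = counts.items() if isinstance(counts, Mapping) else counts
        merged: Counter[DegreePair] = Counter()
        for pair, count in items:
            dp = pair if isinstance(pair, DegreePair) else DegreePair(*pair)
            c = int(count)
            if c != count or c < 0:
                raise PartitionError(f"count for {dp} must be a non-negative integer, got {count!r}")
            merged[dp] += c
        self._counts: dict[DegreePair, int] = {
            p: c for p, c in sorted(merged.items()) if c > 0
        }

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, pair) -> int:
        dp = pair if isinstance(pair, DegreePair) else DegreePair(*pair)
        return self._counts[dp]

    def __iter__(self) -> Iterator[DegreePair]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, EdgePartition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            try:
                return self._counts == EdgePartition(other)._counts
            except PartitionError:
                return NotImplemented
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        body = ", ".join(f"{p}: {c}" for p, c in self._counts.items())
        return f"EdgePartition({{{body}}})"

    # -- derived quantities -------------------------------------------------
    @property
    def total_edges(self) -> int:
        return sum(self._counts.values())

    def degrees(self) -> list[int]:
        """Sorted distinct degrees appearing in any pair."""
        return sorted({d for p in self._counts for d in p})

    def stub_counts(self) -> dict[int, int]:
        """Total edge-endpoint ("stub") count per degree class.

        An edge of type (a, b) contributes one stub to class a and one to
        class b (two to class a when a == b).
        """
        stubs: Counter[int] = Counter()
        for (a, b), c in self._counts.items():
            stubs[a] += c
            stubs[b] += c
        return dict(stubs)


class MolecularGraph:
    """Simple undirected graph of heavy atoms (vertices) and bonds (edges).

    Vertex identifiers are opaque hashables (typically strings); no chemical
    element labels are kept, because every quantity in this package is
    degree-based.  Self-loops and duplicate edges (including reversed
    duplicates) are rejected at construction.  Isolated vertices are
    permitted but excluded from all edge-based computation; a warning is
    logged when any are present.
    """

    def __init__(
        self,
        edges: Iterable[tuple[Hashable, Hashable]],
        vertices: Iterable[Hashable] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(vertices)
        seen: set[frozenset] = set()
        for u, v in edges:
            if u == v:
                raise GraphValidationError(f"self-loop on vertex {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise GraphValidationError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            g.add_edge(u, v)
        isolated = [v for v, d in g.degree() if d == 0]
        if isolated:
            log.warning(
                "graph has %d isolated vertex(es); they are ignored in all "
                "edge-based computation", len(isolated),
            )
        self._g = g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MolecularGraph":
        return cls(g.edges(), vertices=g.nodes())

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._g.nodes())

    @property
    def edges(self) -> list[tuple[Hashable, Hashable]]:
        return list(self._g.edges())

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v: Hashable) -> int:
        return self._g.degree(v)

    def __repr__(self) -> str:
        return f"MolecularGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


def vertex_degrees(graph: MolecularGraph) -> dict[Hashable, int]:
    """Degree of every vertex: the number of bonds incident to the atom.

    The degree sum equals twice the number of edges (handshake identity).
    """
    return dict(graph.to_networkx().degree())


def edge_partition(graph: MolecularGraph) -> EdgePartition:
    """Classify every edge by the unordered pair of its endpoint degrees.

    Raises :class:`PartitionError` on an empty edge set — the partition of
    nothing is not defined and neither are the indices built on it.
    """
    if graph.n_edges == 0:
        raise PartitionError("graph has no edges; edge partition undefined")
    g = graph.to_networkx()
    deg = dict(g.degree())
    counts = Counter(DegreePair(deg[u], deg[v]) for u, v in g.edges())
    return EdgePartition(counts)


@dataclass
class FeasibilityReport:
    """Outcome of the partition realizability check.

    When feasible, ``vertex_counts`` holds the forced number of vertices of
    each degree (stub count divided by degree) and ``n_vertices`` /
    ``n_edges`` the implied totals.  When infeasible, ``problems`` lists
    human-readable reasons, each naming the violating degree or pair.
    """

    feasible: bool
    vertex_counts: dict[int, int] = field(default_factory=dict)
    n_vertices: int = 0
    n_edges: int = 0
    problems: list[str] = field(default_factory=list)


def validate_partition_realizability(partition: EdgePartition) -> FeasibilityReport:
    """Check whether a simple graph with this degree-pair partition can exist.

    Necessary conditions checked:

    * the stub count of every degree class d is divisible by d (each vertex
      of degree d absorbs exactly d stubs);
    * the edge count between classes a != b does not exceed |V_a|·|V_b|,
      and within a class does not exceed C(|V_a|, 2) (simple-graph capacity).

    These are also sufficient for realizability by a simple graph (the
    joint-degree-matrix realization theorem); :func:`topoentropy.fixtures.realize_jdm`
    constructs a witness.
    """
    if not isinstance(partition, EdgePartition):
        partition = EdgePartition(partition)
    if len(partition) == 0:
        raise PartitionError("empty partition: nothing to validate")

    problems: list[str] = []
    stubs = partition.stub_counts()
    vertex_counts: dict[int, int] = {}
    for d, s in sorted(stubs.items()):
        if s % d != 0:
            problems.append(
                f"stub count {s} for degree {d} is not divisible by {d}"
            )
        else:
            vertex_counts[d] = s // d

    if not problems:
        for (a, b), c in partition.items():
            va, vb = vertex_counts[a], vertex_counts[b]
            cap = va * (va - 1) // 2 if a == b else va * vb
            if c > cap:
                problems.append(
                    f"{c} edges of type ({a},{b}) exceed simple-graph "
                    f"capacity {cap} for {va} deg-{a} and {vb} deg-{b} vertices"
                )

    if problems:
        return FeasibilityReport(feasible=False, problems=problems)
    return FeasibilityReport(
        feasible=True,
        vertex_counts=vertex_counts,
        n_vertices=sum(vertex_counts.values()),
        n_edges=partition.total_edges,
    )
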
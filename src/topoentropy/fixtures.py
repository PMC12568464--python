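"""Concrete test graphs: the kekulene skeleton, JDM realizations, random partitions.

Everything the index/entropy machinery computes depends only on the
degree-pair edge partition, so a graph realizing a given partition (a
*joint degree matrix* realization) is the minimal object on which a
partition-level result can be verified by brute-force edge enumeration.
This module builds three kinds of such objects:

* the explicit hydrogen-suppressed kekulene skeleton (the one graph-level
  ground truth the family models anchor to),
* a simple graph realizing an arbitrary feasible partition, and
* random feasible partitions for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations_with_replacement

import networkx as nx
from networkx.generators.joint_degree_seq import is_valid_joint_degree, joint_degree_graph

from .graph import (
    DegreePair,
    EdgePartition,
    MolecularGraph,
    PartitionError,
    edge_partition,
    validate_partition_realizability,
)

__all__ = [
    "RealizationError",
    "RealizationResult",
    "build_kekulene",
    "realize_jdm",
    "random_partition",
]


class RealizationError(RuntimeError):
    """A feasible-looking partition could not be realized."""


@dataclass(frozen=True)
class RealizationResult:
    graph: MolecularGraph
    attempts: int
    achieved_partition: EdgePartition


def build_kekulene() -> MolecularGraph:
    """The hydrogen-suppressed kekulene (C48H24) skeleton.

    Twelve benzene rings fused in a macrocycle: an outer rim of 30 carbons,
    an inner rim of 18, and 12 spokes joining them, giving 48 vertices and
    60 edges with 24 carbons of degree 2 and 24 of degree 3.  Around the
    rims, consecutive spoke attachment points are separated alternately by
    two/one degree-2 carbons (outer) and zero/one (inner), so that each of
    the 12 fused rings is a hexagon.
    """
    outer_gaps = [2, 1] * 6
    inner_gaps = [0, 1] * 6

    outer: list[str] = []
    inner: list[str] = []
    for i in range(12):
        outer.append(f"O{i}.0")
        outer.extend(f"O{i}.{j}" for j in range(1, outer_gaps[i] + 1))
        inner.append(f"I{i}.0")
        inner.extend(f"I{i}.{j}" for j in range(1, inner_gaps[i] + 1))

    edges: list[tuple[str, str]] = []
    for rim in (outer, inner):
        edges.extend((rim[k], rim[(k + 1) % len(rim)]) for k in range(len(rim)))
    edges.extend((f"O{i}.0", f"I{i}.0") for i in range(12))
    return MolecularGraph(edges)


def _to_joint_degrees(partition: EdgePartition) -> dict[int, dict[int, int]]:
    # networkx convention: jd[k][l] is the number of (k,l) edges for k != l,
    # and jd[k][k] is TWICE the number of edges inside degree class k.
    jd: dict[int, dict[int, int]] = {}
    for (a, b), c in partition.items():
        jd.setdefault(a, {})
        jd.setdefault(b, {})
        if a == b:
            jd[a][a] = 2 * c
        else:
            jd[a][b] = c
            jd[b][a] = c
    return jd


def realize_jdm(partition: EdgePartition, seed: int = 0) -> RealizationResult:
    """Construct a simple graph whose degree-pair edge partition equals the request.

    The partition is first validated (stub divisibility and simple-graph
    capacity); a witness graph is then built by the joint-degree-matrix
    construction, deterministically under a fixed seed.  The achieved
    partition is re-extracted from the graph and checked to round-trip
    exactly.  Only the partition is targeted — no chemical plausibility
    (planarity, ring sizes, connectivity) is attempted, because every index
    and entropy in this package depends on the partition alone.
    """
    if not isinstance(partition, EdgePartition):
        partition = EdgePartition(partition)
    report = validate_partition_realizability(partition)
    if not report.feasible:
        raise PartitionError(
            "partition is not realizable: " + "; ".join(report.problems)
        )
    jd = _to_joint_degrees(partition)
    if not is_valid_joint_degree(jd):
        raise PartitionError("partition is not realizable as a simple graph")
    g = joint_degree_graph(jd, seed=seed)
    graph = MolecularGraph.from_networkx(nx.relabel_nodes(g, lambda v: f"v{v}"))
    achieved = edge_partition(graph)
    if achieved != partition:
        raise RealizationError(
            f"realization does not round-trip: requested {partition}, got {achieved}"
        )
    return RealizationResult(graph=graph, attempts=1, achieved_partition=achieved)


def random_partition(
    seed: int,
    max_degree: int = 6,
    max_classes: int = 4,
    max_count: int = 30,
    min_degree: int = 1,
    max_tries: int = 5000,
) -> EdgePartition:
    """A random feasible degree-pair partition (rejection-sampled).

    Candidate partitions draw 1..max_classes distinct degree pairs with
    degrees in [min_degree, max_degree] and counts in 1..max_count, and are
    accepted once they pass the realizability check.  Deterministic under a
    fixed seed.
    """
    if min(max_degree, max_classes, max_count, min_degree) < 1:
        raise ValueError("all bounds must be >= 1")
    if min_degree > max_degree:
        raise ValueError("min_degree exceeds max_degree")
    rng = random.Random(seed)
    all_pairs = [
        DegreePair(a, b)
        for a, b in combinations_with_replacement(range(min_degree, max_degree + 1), 2)
    ]
    for _ in range(max_tries):
        k = rng.randint(1, min(max_classes, len(all_pairs)))
        pairs = rng.sample(all_pairs, k)
        counts = {p: rng.randint(1, max_count) for p in pairs}
        candidate = EdgePartition(counts)
        if not validate_partition_realizability(candidate).feasible:
            continue
        if not is_valid_joint_degree(_to_joint_degrees(candidate)):
            continue
        return candidate
    raise RealizationError(f"no feasible partition found in {max_tries} tries")
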
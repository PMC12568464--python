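"""Shannon entropy of an index's edge-contribution distribution.

Given a degree-based index D(G) = sum_e j(e), each edge is treated as an
outcome with probability j(e)/D.  The index entropy is

    ENT_D(G) = log D - (1/D) * sum_e j(e) log j(e)        (natural log)

which is algebraically the Shannon entropy -sum p log p of the normalized
contribution vector.  It lies in [0, log |E|], attaining the maximum
exactly when all contributions are equal (e.g. on degree-regular graphs).

The natural logarithm is used throughout the index-entropy computation;
base 2 and base 10 are available only in the generic
:func:`shannon_entropy`.  Contributions must be strictly positive: a zero
contribution (ABC on a (1,1) edge) makes the normalization ill-posed and
raises :class:`EntropyError` rather than being silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .descriptors import DescriptorSpec, edge_contribution
from .graph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "EntropyError",
    "EntropyValue",
    "shannon_entropy",
    "entropy_from_partition",
    "entropy_from_graph",
]


class EntropyError(ValueError):
    """Ill-posed entropy request (bad probability vector or non-positive contributions)."""


@dataclass(frozen=True)
class EntropyValue:
    """An index entropy in nats, with the descriptor and normalizer that produced it."""

    value: float
    descriptor: DescriptorSpec
    index_total: float
    n_edges: int

    def __float__(self) -> float:
        return self.value


def shannon_entropy(probabilities: Sequence[float], log_base: float = math.e) -> float:
    """Shannon entropy -sum p_i log(p_i) in the requested base.

    Probabilities must be non-negative and sum to 1 within 1e-9.  The
    convention 0*log 0 = 0 applies, so zero probabilities are allowed here
    (unlike in the index entropies, where zero contributions are an error).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise EntropyError("probability vector must be a non-empty 1-D sequence")
    if np.any(p < 0):
        raise EntropyError("probabilities must be non-negative")
    total = float(p.sum())
    if abs(total - 1.0) > 1e-9:
        raise EntropyError(f"probabilities must sum to 1 (got {total!r})")
    if log_base <= 1.0:
        raise EntropyError("log base must exceed 1")
    nz = p[p > 0]
    h_nats = float(-(nz * np.log(nz)).sum())
    return h_nats / math.log(log_base)


def entropy_from_partition(
    partition: EdgePartition, spec: DescriptorSpec
) -> EntropyValue:
    """Index entropy ENT_D = log D - (1/D) sum count*j*log j, natural log.

    Raises :class:`EntropyError` if any per-edge contribution is <= 0 —
    notably ABC on a partition containing the (1,1) class.
    """
    if not isinstance(partition, EdgePartition):
        partition = EdgePartition(partition)
    if len(partition) == 0:
        raise EntropyError("empty partition: entropy undefined")

    contribs = []
    for pair, count in partition.items():
        j = edge_contribution(spec, pair)
        if j <= 0.0:
            raise EntropyError(
                f"entropy undefined for non-positive contributions: "
                f"{spec.label()} on {pair} gives {j}"
            )
        contribs.append((count, j))

    d_total = sum(c * j for c, j in contribs)
    if d_total <= 0.0:
        raise EntropyError("entropy undefined for non-positive contributions: index total is 0")
    weighted = sum(c * j * math.log(j) for c, j in contribs)
    value = math.log(d_total) - weighted / d_total
    return EntropyValue(
        value=value,
        descriptor=spec,
        index_total=d_total,
        n_edges=partition.total_edges,
    )


def entropy_from_graph(graph: MolecularGraph, spec: DescriptorSpec) -> EntropyValue:
    """Index entropy by direct edge enumeration; equals the partition form."""
    return entropy_from_partition(edge_partition(graph), spec)
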
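"""Degree-based topological indices as per-edge contribution functions.

Every index here is a sum over edges e = pq of a function of the two
endpoint degrees, expressed through the edge weights

    w*(e) = dp * dq      (product)
    w+(e) = dp + dq      (sum)

The ten indices:

===========  ==========================  ============================
name         index                       per-edge contribution j(e)
===========  ==========================  ============================
M1           first Zagreb                w+
M2           second Zagreb               w*
R_alpha      general Randic              (w*)^alpha
R            Randic                      (w*)^(-1/2)
HM           hyper-Zagreb                (w+)^2
SCI          sum-connectivity            (w+)^(-1/2)
CHI_alpha    general sum-connectivity    (w+)^alpha
GA           geometric-arithmetic        2*sqrt(w*)/w+
ABC          atom-bond connectivity      sqrt((w+ - 2)/w*)
H            harmonic                    2/w+
===========  ==========================  ============================

Because every contribution depends only on the unordered degree pair, an
index is fully determined by the degree-pair edge partition; computing it
on a graph and on the graph's partition are interchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import sympy as sp

from .graph import DegreePair, EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "DescriptorError",
    "DescriptorSpec",
    "DESCRIPTOR_NAMES",
    "PARAMETRIC",
    "NONPARAMETRIC",
    "edge_weights",
    "edge_contribution",
    "edge_contribution_exact",
    "index_from_partition",
    "index_from_graph",
]


class DescriptorError(ValueError):
    """Unknown descriptor name or invalid parameterization."""


#: Canonical descriptor names, in the order the index table lists them.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "M1", "M2", "R_alpha", "R", "HM", "SCI", "CHI_alpha", "GA", "ABC", "H",
)
PARAMETRIC: frozenset[str] = frozenset({"R_alpha", "CHI_alpha"})
NONPARAMETRIC: tuple[str, ...] = tuple(n for n in DESCRIPTOR_NAMES if n not in PARAMETRIC)

_ALIASES = {
    "m1": "M1", "m2": "M2", "r": "R", "hm": "HM", "sci": "SCI", "sci1": "SCI",
    "ga": "GA", "abc": "ABC", "h": "H",
    "r_alpha": "R_alpha", "ralpha": "R_alpha",
    "chi_alpha": "CHI_alpha", "chialpha": "CHI_alpha", "chi": "CHI_alpha",
}


@dataclass(frozen=True)
class DescriptorSpec:
    """One of the ten degree-based indices, with its exponent if parametric.

    ``alpha`` is mandatory for R_alpha and CHI_alpha and must be absent for
    the other eight — there is deliberately no default exponent.
    """

    name: str
    alpha: float | None = None

    def __post_init__(self) -> None:
        canonical = _ALIASES.get(self.name.lower())
        if canonical is None:
            raise DescriptorError(
                f"unknown descriptor {self.name!r}; valid names: {', '.join(DESCRIPTOR_NAMES)}"
            )
        object.__setattr__(self, "name", canonical)
        if canonical in PARAMETRIC:
            if self.alpha is None:
                raise DescriptorError(f"{canonical} requires an explicit alpha exponent")
            object.__setattr__(self, "alpha", float(self.alpha))
        elif self.alpha is not None:
            raise DescriptorError(f"{canonical} takes no alpha parameter")

    def label(self) -> str:
        if self.alpha is not None:
            return f"{self.name}({self.alpha:g})"
        return self.name


def edge_weights(d_p: int, d_q: int) -> tuple[int, int]:
    """Return (w*, w+) = (dp*dq, dp+dq) for an edge with endpoint degrees dp, dq."""
    if int(d_p) != d_p or int(d_q) != d_q or d_p < 1 or d_q < 1:
        raise DescriptorError(f"degrees must be positive integers, got ({d_p!r}, {d_q!r})")
    d_p, d_q = int(d_p), int(d_q)
    return d_p * d_q, d_p + d_q


_CONTRIB: dict[str, Callable[[int, int, float | None], float]] = {
    "M1": lambda ws, wp, a: float(wp),
    "M2": lambda ws, wp, a: float(ws),
    "R_alpha": lambda ws, wp, a: float(ws) ** a,
    "R": lambda ws, wp, a: float(ws) ** -0.5,
    "HM": lambda ws, wp, a: float(wp) ** 2,
    "SCI": lambda ws, wp, a: float(wp) ** -0.5,
    "CHI_alpha": lambda ws, wp, a: float(wp) ** a,
    "GA": lambda ws, wp, a: 2.0 * math.sqrt(ws) / wp,
    "ABC": lambda ws, wp, a: math.sqrt((wp - 2) / ws),
    "H": lambda ws, wp, a: 2.0 / wp,
}


def edge_contribution(spec: DescriptorSpec, pair: DegreePair | tuple[int, int]) -> float:
    """The single-edge summand j(e) of the named index on one degree pair.

    ABC on the pair (1,1) returns exactly 0 (w+ - 2 = 0); this is fine for
    index sums but makes the index entropy undefined — the entropy module
    rejects it.
    """
    if not isinstance(pair, DegreePair):
        pair = DegreePair(*pair)
    ws, wp = edge_weights(pair.d_lo, pair.d_hi)
    return _CONTRIB[spec.name](ws, wp, spec.alpha)


def edge_contribution_exact(spec: DescriptorSpec, pair: DegreePair | tuple[int, int]) -> sp.Expr:
    """Exact symbolic contribution (sympy), used by the closed-form machinery.

    A float alpha is converted to an exact rational via nsimplify, so e.g.
    alpha = -0.5 yields genuine radicals.
    """
    if not isinstance(pair, DegreePair):
        pair = DegreePair(*pair)
    ws, wp = edge_weights(pair.d_lo, pair.d_hi)
    ws, wp = sp.Integer(ws), sp.Integer(wp)
    a = None if spec.alpha is None else sp.nsimplify(spec.alpha, rational=True)
    exact: dict[str, sp.Expr] = {
        "M1": wp,
        "M2": ws,
        "R_alpha": ws ** a if a is not None else None,
        "R": 1 / sp.sqrt(ws),
        "HM": wp ** 2,
        "SCI": 1 / sp.sqrt(wp),
        "CHI_alpha": wp ** a if a is not None else None,
        "GA": 2 * sp.sqrt(ws) / wp,
        "ABC": sp.sqrt(sp.Rational(int(wp) - 2, int(ws))),
        "H": sp.Rational(2, int(wp)),
    }
    return exact[spec.name]


def index_from_partition(
    partition: EdgePartition, spec: DescriptorSpec
) -> float:
    """Index value from an edge partition: sum of count x contribution."""
    if not isinstance(partition, EdgePartition):
        partition = EdgePartition(partition)
    if len(partition) == 0:
        raise DescriptorError("empty partition: index undefined")
    return float(
        sum(count * edge_contribution(spec, pair) for pair, count in partition.items())
    )


def index_from_graph(graph: MolecularGraph, spec: DescriptorSpec) -> float:
    """Index value by direct edge enumeration on a graph.

    Identical (exactly, not just numerically) to summing over the graph's
    degree-pair partition.
    """
    return index_from_partition(edge_partition(graph), spec)
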
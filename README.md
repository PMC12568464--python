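# topoentropy

Degree-based topological indices and Shannon edge-entropy measures for
molecular graphs, with exact symbolic edge-partition models for two
fractal molecular families: the **kekulene fractal** (KEₙ, built on the
cycloarene C₄₈H₂₄) and the **terpyridine-metal Sierpinski triangle**
(SEₙ).

## The problem

In QSPR/QSAR work, a molecule is abstracted to its hydrogen-suppressed
graph G = (V, E): atoms are vertices, bonds are edges. A large class of
structure descriptors — the Zagreb, Randić, hyper-Zagreb,
sum-connectivity, geometric-arithmetic, atom-bond-connectivity and
harmonic indices — are sums over edges e = pq of a function of the two
endpoint degrees, conveniently expressed through the edge weights
w\*(e) = d_p·d_q and w⁺(e) = d_p + d_q:

| index | contribution j(e) | index | contribution j(e) |
|---|---|---|---|
| first Zagreb M₁ | w⁺ | sum-connectivity SCI | (w⁺)^(−1/2) |
| second Zagreb M₂ | w\* | general sum-connectivity χ_α | (w⁺)^α |
| general Randić R_α | (w\*)^α | geometric-arithmetic GA | 2√(w\*)/w⁺ |
| Randić R | (w\*)^(−1/2) | atom-bond connectivity ABC | √((w⁺−2)/w\*) |
| hyper-Zagreb HM | (w⁺)² | harmonic H | 2/w⁺ |

To quantify how *unevenly* an index distributes over the bonds — a proxy
for structural complexity — each index D(G) = Σ_e j(e) induces a Shannon
entropy over edges with probabilities j(e)/D:

```
ENT_D(G) = log D − (1/D) Σ_e j(e) log j(e)        (natural log, nats)
```

with 0 ≤ ENT_D ≤ log |E|, the maximum attained exactly when all edges
contribute equally (degree-regular graphs).

Because every such index and entropy depends on G only through the
multiset of edges classified by their unordered endpoint-degree pair (the
**degree-pair edge partition**, a.k.a. joint degree matrix), whole
self-similar families can be handled by a symbolic partition model: for
the kekulene fractal the counts are (2,2): 75n²−207n+138,
(2,3): (9/2)·8ⁿ, (3,3): (3/2)·12ⁿ; for the Sierpinski family five
quadratic polynomials in n. This package evaluates those models exactly
(arbitrary-precision integers, exact radical coefficients via sympy),
verifies the published closed-form index expressions against the
partition sums — flagging a known misprint in the Sierpinski harmonic
form — and cross-checks every partition-level value by brute-force edge
enumeration on explicitly constructed graphs.

## Worked example

```python
from topoentropy import (DescriptorSpec, build_kekulene, edge_partition,
                         entropy_from_graph, index_from_graph)

g = build_kekulene()                    # 48 carbons, 60 bonds
print(edge_partition(g))                # EdgePartition({(2,2): 6, (2,3): 36, (3,3): 18})
spec = DescriptorSpec("HM")
print(index_from_graph(g, spec))        # 1644.0
print(entropy_from_graph(g, spec).value)  # 4.068308...
```

The partition says kekulene's 60 bonds split into 6 bonds between two
degree-2 carbons, 36 between a degree-2 and a degree-3 carbon, and 18
between two degree-3 carbons. The hyper-Zagreb index sums (w⁺)² over the
bonds: 6·16 + 36·25 + 18·36 = 1644. Its entropy, 4.0683 nats, sits just
below the log 60 ≈ 4.0943 ceiling — the three edge classes make the
contribution distribution only mildly non-uniform.

Family tables and the consistency report come from one call each
(see `examples/` for runnable narrated versions):

```python
from topoentropy import reference_entropy_table, verify_closed_forms
reference_entropy_table("SE", n_max=10).round(4)   # 10 x 10 entropy table
print(verify_closed_forms("SE").to_text())         # flags the harmonic misprint
```

A thin CLI mirrors the library:

```sh
topoentropy entropy --family KE --n 1 --descriptor GA     # -> 4.0943 nats
topoentropy family-table --family SE --n-max 10 --out se.csv
topoentropy verify --family SE --json
topoentropy family-partition --family SE --n 2 --out p.json
topoentropy realize --partition p.json --seed 7 --out edges.tsv
```

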
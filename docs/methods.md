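# Methods

## Model

All quantities are functions of a hydrogen-suppressed molecular graph
G = (V, E) — simple, undirected, unlabeled beyond vertex identity. Ten
degree-based indices D(G) = Σ_{e=pq∈E} j(d_p, d_q) are supported, with
per-edge contributions expressed through w\* = d_p·d_q and w⁺ = d_p + d_q
(table in the README). The index entropy is

    ENT_D(G) = log D − (1/D) Σ_e j(e) log j(e),

the Shannon entropy of the probability vector {j(e)/D}. The identity with
the generic Shannon form is algebraic, and the implementation keeps it
exact to ~1e−15: the property suite asserts agreement to 1e−12.

**Logarithm base.** Natural log throughout the index-entropy path. The
choice is forced numerically: with D = HM(SE₁) = 6366 the entropy is
5.2198 nats only in base e; base-2 or base-10 values differ by factors
log₂e / log₁₀e and match nothing in the reference tables. The generic
`shannon_entropy` accepts an explicit base for other uses.

**Positivity.** Contributions must be strictly positive for an entropy to
be well-posed. The single degenerate case among the ten indices is ABC on
a (1,1) edge, where w⁺ − 2 = 0. Index *sums* accept the zero contribution
(the summand is simply 0); entropy computation raises `EntropyError`
instead of adopting a 0·log 0 convention, because the normalization by D
makes the distribution ill-defined, not merely a removable limit. The
generic `shannon_entropy` does use 0·log 0 = 0, which is the standard and
harmless convention for genuine probability vectors.

## Family partition models

The degree-pair edge partition fully determines every index and entropy
here, so each fractal family is *defined* by its symbolic partition:

* KEₙ (kekulene fractal): (2,2): 75n² − 207n + 138, (2,3): (9/2)·8ⁿ,
  (3,3): (3/2)·12ⁿ. The source typography for the two exponential classes
  is ambiguous ("928n", "3212n"); the exponential reading is the unique
  one that both matches the explicit C₄₈ kekulene skeleton at n = 1
  (36 and 18) and reproduces the reference entropy table at n = 2..10 —
  any polynomial reading is off by more than a nat already at n = 2.
* SEₙ (terpyridine Sierpinski triangle): (1,3): 4n+2,
  (2,2): 24n²+25n−1, (2,3): 36n²+38n+10, (3,3): 27n²+30n−3,
  (3,6): 9n²+9n. The (1,3) class implies retained degree-1 atoms; the
  engine computes on whatever partition is supplied and treats the model
  as the family's definition. No geometric reconstruction of the SEₙ
  molecules (or KEₙ beyond n = 1) is attempted.

Counts are evaluated with sympy into exact Python integers, so the
exponential KE classes never overflow; the CLI caps n at 30 as a
practical guard, the library does not.

**Alpha conventions.** The parametric indices R_α and χ_α take α as an
explicit, mandatory argument — no default — because the two reference
tables use different conventions: the kekulene table's parametric columns
duplicate R and SCI (α = −1/2 both), while the Sierpinski table's use
α = +1/2 (general Randić) and α = −1 (general sum-connectivity; its
entropy equals the harmonic entropy exactly, by scale invariance). The
per-table conventions are hard-coded only in the table-reproduction
layouts (`KE_TABLE_COLUMNS` / `SE_TABLE_COLUMNS`) and documented there.

## Closed forms and the consistency verifier

Closed-form index expressions for both families are re-derived
symbolically as Σ count(n)·j with exact rational/radical coefficients —
not transcribed from the published decimal-rounded intermediates. The
literal published forms (decoded to exact coefficients) are stored
separately and `verify_closed_forms` compares the two at n = 1..10,
flagging relative differences above 1e−6. Outcomes:

* All eight non-parametric kekulene forms and seven of eight Sierpinski
  forms agree exactly.
* The published Sierpinski harmonic form is a misprint: its constant term
  reads 72 where the partition sum gives 7/2 (151.1 vs 82.6 at n = 1).
  It is flagged and never used; partition sums are authoritative.
* The published worked example for the Sierpinski hyper-Zagreb entropy
  prints a rounded numerator (n² coefficient 10645.4); the exact value is
  384·ln16 + 900·ln25 + 972·ln36 + 729·ln81 ≈ 10648.4, recorded in the
  report notes. Exact symbolic evaluation reproduces the final entropy
  table to ≤2e−4; chaining the printed rounded intermediates does not.

## Realization and synthetic test objects

`realize_jdm` builds a simple graph realizing a requested partition via
the joint-degree-matrix construction (networkx's seeded
`joint_degree_graph`), after an independent feasibility report: stub
counts per degree class must be divisible by the degree (fixing the
vertex count per class) and class-pair edge counts must fit simple-graph
capacity. Realizations target the partition only — no planarity, ring
sizes, connectivity or chemical plausibility — because the partition is
sufficient for every quantity computed here. Consequently, passing
round-trip tests demonstrate correctness of the partition-to-index
pipeline, not that realized graphs resemble molecules. `random_partition`
rejection-samples feasible partitions (default degrees 1..6, ≤4 classes,
counts ≤30, deterministic per seed); entropy property tests sample with
`min_degree=2` so the ABC (1,1) error path — tested separately — does not
interrupt the identity checks.

The one explicit molecular anchor is the kekulene skeleton: 12 fused
hexagons as an outer 30-carbon rim, inner 18-carbon rim, and 12 spokes,
alternating rim gaps chosen so every fused ring is a hexagon. Its
enumerated partition equals the KE model at n = 1, and all ten entropies
computed on the graph match the reference table's first row.

## Numerical choices and tolerances

* Contributions in double precision; exact sympy arithmetic only in the
  closed-form/symbolic layer. Reference tables are printed to 4 decimals;
  doubles carry ~16.
* Table reproduction uses ±0.002 absolute, absorbing the publication's
  last-digit rounding (observed discrepancies ≤2e−4). Four Sierpinski
  cells are documented misprints that no computation reproduces (EM2 at
  n=3, EGA and EABC at n=7, ERα at n=6 — two are transparent digit
  transpositions; all four sit >0.002 from the model while every
  neighboring cell matches to ~1e−4). Reproduction tests check all other
  cells at ±0.002 and assert the misprinted cells are indeed
  irreproducible.
* Algebraic identities (Shannon equivalence, scale invariance, parametric
  specializations) at 1e−12 absolute/relative; closed-form vs partition
  agreement at 1e−6 relative in the verifier.
* Degenerate inputs: empty edge sets, empty partitions, non-positive
  degrees, and infeasible partitions all raise typed errors naming the
  offending element; isolated vertices are tolerated with a warning and
  excluded from edge-based computation.

## Problem sizes

Reference tables are reproduced over n = 1..10 for both families (the KE
partition at n = 10 has ~9.8e10 edges — partition-level arithmetic is
O(#classes), so this is instant). Property suites run 100 random
partitions × 10 descriptors for the entropy identities and 200 random
partition round-trips through graph realization; realized graphs stay in
the hundreds of vertices. The whole test suite runs in a few seconds on
one CPU.

## Known limitations

* Only degree-based (edge-contribution) indices; no distance-based
  indices (Wiener etc.) and no vertex-partition entropies.
* Families are partition models, not coordinates: nothing geometric or
  electronic can be derived from them.
* Realized graphs are arbitrary witnesses of a partition, not samples
  from any well-defined distribution over realizations, and are generally
  disconnected/non-planar.
* SDF/MOL ingestion reads heavy-atom connectivity only and ignores bond
  orders; it requires the optional rdkit dependency.
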
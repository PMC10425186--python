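# Methods

## Model

A dynamic graph is a set `G = {G1, …, GT}` of `T ≥ 2` simple undirected
snapshot graphs over one shared vertex namespace; snapshots may be
time-ordered (stages, weekly crawls) or unordered conditions. Given a
target snapshot `u`, the collapsed graph `Gc` contains exactly the edges
of `Gu`, each annotated with `NoCond(e)`, the number of snapshots whose
edge set contains that vertex pair (`1 ≤ NoCond ≤ T`), and the weight

    w(e) = 2·(1 + log(T/NoCond(e)))   NoCond(e) = 1
    w(e) = 1 + log(T/NoCond(e))       NoCond(e) > 1.

The weight is an inverse-document-frequency transform of snapshot
frequency: ubiquitous edges weigh exactly 1, and u-specific edges
(`NoCond = 1`) weigh `2(1 + log T)`, strictly above the largest shared
weight `1 + log(T/2)` for every `T ≥ 2` and every supported base. Edges of
`Gu` absent from a subgraph's other snapshots are *not* assigned weight 0
— they are simply not part of `Gc` — because zero-weight edges would
corrupt vertex degrees and the exclusive fraction.

The objective over a subgraph `S ⊆ Gc` is the weighted density
`density(S) = mass(S)/|V(S)|` with `mass(S) = Σ_{e∈S} w(e)`; at equal
vertex count, larger mass means denser. Feasibility is the exclusive
threshold `|Eu(S)|/|E(S)| ≥ γ ∈ (0,1]`, the fraction of the subgraph's
edges that are u-specific.

## Algorithm

Exhaustive search over subgraphs is combinatorial, so extraction is a
greedy peel. From the full `Gc`, one vertex is deleted per step:

* an isolated vertex, smallest label first, whenever one exists (removing
  it can only raise density);
* otherwise the vertex minimising `score(v) = dw(v)·(1 + du(v)/d(v))`,
  ties broken toward the lexicographically smallest label.

`dw` targets dense remainders; the `(1 + du/d)` factor protects vertices
carrying u-specific edges. Every configuration visited (from the full
graph down to the stop floor) is recorded with its mass, density, edge
counts and exclusive fraction; the returned subgraph is the feasible
configuration of maximum density, requiring at least one edge, at least
`min_vertices` vertices and exclusive fraction ≥ γ.

For the score-minimising choice the post-removal density is bracketed per
step by `(mass − 2·dw_min)/(|V|−1) ≤ density′ ≤ (mass − dw_min)/(|V|−1)`,
because `dw(v*) ≤ score(v*) ≤ score(argmin dw) ≤ 2·dw_min`. The bracket
is recorded in the trace and asserted by the test suite over thousands of
random steps; it never influences a removal, so timing runs may disable
its bookkeeping (`with_bounds=False`).

k disjoint usnaps are extracted by deleting each accepted usnap's vertices
and incident edges from the residual graph and re-peeling, stopping early
(with a logged notice) when nothing feasible remains. Output is relabelled
`d0, d1, …` in decreasing density. An edge-only deletion variant would
permit overlapping results; vertex deletion was chosen because disjoint
per-stage results are the natural reading of stage-specific module tables.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `u` | — | target snapshot, 1-based |
| `k` | 1 | number of usnaps |
| `gamma` | 1.0 | minimum u-specific edge fraction, in (0, 1] |
| `min_vertices` | 3 | smallest reportable usnap (more than two nodes) |
| `fraction_to_remain` | 0 | stop peeling once fewer than this fraction of starting vertices remains; 0 peels to exhaustion |
| `restart` | false | optional second peel pass seeded from the accepted configuration's neighbourhood; never worsens density, experimental |
| `log_base` | e | base of the weight logarithm (e, 2 or 10) |

The weight function's log base is configurable because the definition
leaves it open; natural log is the common IDF convention, and every
invariant (monotonicity, rarity dominance, bracket) holds in any base.
`restart` and `fraction_to_remain` are defined here as stated above; the
defaults (no restart, peel to exhaustion) are the reference setting used
throughout the tests.

## Numerical choices

* Selection ties break on vertex labels (via a sorted-label int renumbering,
  so heap order is label order); determinism is required for testability.
* Best-configuration density ties prefer fewer vertices, then the earlier
  visit. Densities are compared with relative tolerance 1e-9: the running
  mass accumulates subtraction round-off along the peel, and mathematically
  tied states — e.g. one planted clique versus the disjoint union of two
  equal copies — must still resolve toward the smaller configuration.
  1e-9 is orders of magnitude above accumulated round-off and below any
  genuine density gap on weights of order 1–10.
* `exclusive_fraction ≥ γ` is tested with a 1e-12 slack for representation
  error; at γ = 1 the fraction is an exact integer ratio, so no usnap with
  a shared edge can slip through.
* An edgeless configuration has no exclusive fraction and is never
  feasible; a single isolated vertex has density 0.
* Degenerate inputs: an empty target snapshot yields an empty `Gc` and no
  usnaps (warning logged); graphs smaller than `min_vertices` return
  nothing.

## Implementation notes

The peel is inherently sequential (each removal depends on all previous
ones), so the inner loop is JIT-compiled with numba over a flat CSR
layout; lazy-deletion binary heaps keyed by `(score, vertex index)` give
the `mc·log nc` term, with an entry valid only while it matches the
vertex's current score. A pure-Python twin of the identical loop is kept
next to it and the tests assert bit-identical traces on random instances.
Bulk collapsing maps labels to integers with a C hash table, counts
`NoCond` by sorted-key membership, and materialises the dict-of-dict API
views lazily. Incremental float updates can resolve exact-symmetry score
ties differently from a fresh summation; the re-simulation tests therefore
compare scores, not labels, at near-ties.

## Synthetic data

The generator plants what the method is built to find: a background of
edges shared by every snapshot (collapsing to weight 1, `NoCond = T`) plus
planted dense regions (cliques by default) on fresh vertex labels whose
edges exist only in snapshot u. Defaults — `T = 4` snapshots, matching a
four-stage disease-progression design; one 6-vertex planted clique;
40 background vertices at edge probability 0.1 — make ground truth
unambiguous. `cross_leak` lets each planted edge also appear in one random
other snapshot to exercise `γ < 1`; `background_mode="resampled"` draws
the background independently per snapshot, scattering incidental
u-specific edges. Scaling instances use ~`mc/10` vertices (average degree
20), 10% u-only edges and five planted 8-cliques so that five extractions
all succeed.

What the generator does not emulate: scale-free degree distributions,
correlated noise between snapshots, partially overlapping planted regions,
or measurement noise in edge presence. Passing tests therefore certify the
algorithmic guarantees (bracket, exclusivity, disjointness, recovery of
planted optima, quasilinear growth) — not robustness to the full
messiness of real co-expression networks, where threshold choices upstream
(see below) dominate.

## Expression-derived snapshots

`expression_graphs` reproduces a generic construction of stage snapshots:
keep a physical-interaction edge in stage `s` when `|corr|` of the two
genes' expression over stage-`s` samples (absolute Pearson by default,
Spearman optional) reaches a threshold (default 0.7). Each stage needs at
least 3 samples; constant profiles never pass (their correlation is
undefined). The exact statistic and threshold used by any particular
published dataset are a property of that dataset's pipeline — both are
plain parameters here, and nothing in the core algorithm depends on this
module.

## Problem sizes used in the checks

The automated checks run at desk scale by design: bracket checks on ≥ 50
random collapsed graphs (mixed `T ∈ {2..8}`, ≥ 1000 steps), exclusivity
over 100 seeded runs, brute-force comparison on 200 instances of ≤ 12
vertices plus 50 oracle-certified planted instances, and runtime growth
across collapsed graphs of 10⁴, 10⁵ and 10⁶ edges (timed best-of-three
after a warm-up, ratios — not absolute seconds — being the quantity of
interest).

## Limitations

* The peel is a heuristic: outside the per-step bracket there is no global
  optimality guarantee, and on adversarial instances it can miss the
  densest feasible subgraph (the oracle suite bounds how often this
  happens on random instances).
* Results are vertex-disjoint by construction; overlapping unique regions
  are not representable.
* `Gc` must fit in memory; there is no streaming or incremental update
  when snapshots change.
* Directed graphs and multigraphs are out of scope.
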
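# usnap

Unique dense region detection across the snapshots of a dynamic graph.

Many systems — disease stages profiled as co-expression networks, weekly
social or communication graphs, financial interaction networks — are
naturally modelled as a set of **snapshot graphs** `G = {G1, …, GT}` over a
shared vertex namespace. A recurring question is *which tightly connected
region exists in one snapshot and (mostly) nowhere else*: for tumour-stage
networks these are candidate stage-specific mechanisms. This package finds
such regions, called **usnaps**, given the target snapshot `u`, the number
of subgraphs `k`, and an exclusive threshold `γ`.

## Method

1. **Collapse.** Build a single weighted graph `Gc` whose edges are exactly
   the edges of snapshot `u`. For each edge let `NoCond(e)` be the number of
   snapshots containing that vertex pair; the weight is an inverse document
   frequency style score that rewards rarity,

   ```
   w(e) = 2·(1 + log(T / NoCond(e)))   if NoCond(e) = 1   (u-specific)
   w(e) = 1 + log(T / NoCond(e))       if NoCond(e) > 1
   ```

   so an edge shared by all snapshots weighs 1 and a u-specific edge weighs
   `2(1 + log T)`, strictly more than any shared edge.

2. **Peel.** Starting from the full `Gc`, greedily delete one vertex at a
   time — the vertex minimising `dw(v)·(1 + du(v)/d(v))`, where `dw`, `d`
   and `du` are the weighted degree, degree, and number of incident
   u-specific edges. Every visited configuration is recorded; the result is
   the configuration maximising the weighted density
   `density(S) = Σ_{e∈S} w(e) / |V(S)|` among those whose fraction of
   u-specific edges is at least `γ`. For each step the post-removal density
   is provably bracketed:

   ```
   (mass − 2·dw_min)/(|V|−1)  ≤  density(after)  ≤  (mass − dw_min)/(|V|−1)
   ```

   with `mass` and `dw_min = min_v dw(v)` taken before the removal.

3. **Iterate.** Remove the accepted usnap's vertices from `Gc` and peel the
   remainder, up to `k` times. Results are vertex-disjoint and labelled
   `d0, d1, …` densest-first.

A peel costs `O(m + mc·log nc + nc·log nc)` (`m` edges in the snapshot set,
`mc`/`nc` edges/vertices of `Gc`): lazy min-heaps over a compiled CSR core.
A million-edge collapsed graph peels in seconds on one core.

## Worked example

Generate a synthetic four-snapshot set with two 6-vertex cliques planted
only in snapshot 1 over a background shared by all snapshots, then extract
two usnaps unique to snapshot 1:

```
$ usnap synth --seed 1 --n-planted-regions 2 --out data
$ usnap run --snapshots data --u 1 --k 2 --gamma 1.0 --out results
$ cat results/summary.tsv
#rank  n_vertices  n_edges  density  exclusive_fraction
d0     6           15       11.9315  1
d1     6           15       11.9315  1
```

Both planted cliques are recovered exactly. The density 11.9315 is the
clique's 15 edges, each u-specific with weight `2(1 + ln 4) ≈ 4.7726`,
divided by its 6 vertices: `15 · 4.7726 / 6 = 11.93`. The exclusive
fraction 1 certifies that no edge of either result appears in any other
snapshot. Per-usnap edge lists (`usnap_d0.tsv`, …) carry the weight,
`NoCond` and u-specificity of every edge, and `manifest.json` records the
resolved parameters and input checksums.

The same pipeline from Python:

```python
from usnap import SyntheticSpec, UsnapConfig, generate, find_usnaps

snapshots, truth = generate(SyntheticSpec(seed=1, n_planted_regions=2))
for us in find_usnaps(snapshots, UsnapConfig(u=1, k=2, gamma=1.0)):
    print(us.rank, us.n_vertices, round(us.density, 4))
```

Real inputs are plain edge-list TSVs (one file per snapshot, or one long
file with a snapshot column) or GraphML; see `usnap run --help`. The
`usnap.expression_graphs` module can build stage-wise snapshots from an
expression matrix plus a protein-interaction network by per-stage
correlation filtering.

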
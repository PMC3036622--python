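# Methods

This note documents the models, statistics and algorithms implemented in
orbitkit, the defaults chosen where the design was open, and what the
synthetic test fixtures do and do not demonstrate.

## Graphlet catalog and orbit numbering

Graphlets are the connected induced non-isomorphic subgraphs on 2–5
nodes.  The catalog is built by exhaustive generation: for each node count
k ∈ {2..5}, all 2^C(k,2) labelled graphs are enumerated, disconnected ones
discarded, and isomorphism classes collapsed via a canonical adjacency
code (the minimum over all k! relabellings of the upper-triangle bitmask).
This yields 30 graphlets.  Automorphism orbits are the node classes of
each canonical representative under its automorphism group, computed by
brute force over permutations; there are 73 orbits in total, and the
3-node path splits into its end-node and middle-node orbits.

Graphlets are ordered by (node count, edge count, canonical code), so G0
is the single edge and orbit 0 is the edge orbit; orbits within a graphlet
are ordered by smallest member index.  This ordering is deterministic and
reproducible but is *not* the historical published numbering — no code or
test in this package depends on any particular numbering beyond orbit 0.
`GraphletCatalog.describe()` dumps the full catalog for inspection.

## Counting

The fast counter enumerates every connected induced subgraph on 2–5 nodes
exactly once (ESU-style recursive extension with exclusive
neighbourhoods), classifies each subgraph in O(1) via a precomputed
table mapping adjacency codes to (graphlet, per-position orbit), and
accumulates graphlet counts and per-node orbit touches in one pass.  Its
correctness oracle, `count_graphlets_oracle`, enumerates all C(n,k)
subsets with direct isomorphism tests; the suite checks equivalence on
225 random graphs spanning n ∈ [4, 12] and densities 0.1–0.9, plus
closed forms on cliques and the orbit-sum identity
Σᵤ GDV[u][j] = c_j · N_i (c_j = orbit multiplicity).  Worst-case cost is
O(n⁵) but scales with the number of connected 5-node subgraphs, so sparse
networks are far cheaper than dense ones.

## Signature similarity and orbit weights

The distance between signatures u, v is

    D(u,v) = Σᵢ wᵢ · |log(uᵢ+1) − log(vᵢ+1)| / log(max(uᵢ, vᵢ) + 2) / Σᵢ wᵢ

and S = 1 − D.  The log scaling makes large orbit counts comparable to
small ones; the +1/+2 offsets keep zero counts finite and bound each
orbit's contribution by wᵢ.

Orbits are not independent — a node at the centre of a 4-star necessarily
also sits mid-path and on edges — so orbit i is weighted by
wᵢ = 1 − log(oᵢ)/log(73), where oᵢ counts the orbits that orbit i depends
on: the non-zero coordinates of the signature of orbit i's representative
node computed inside its own graphlet.  This is self-contained and
deterministic; o₀ = 1 (the edge depends only on itself, w₀ = 1) and all
weights are strictly positive, which makes S(u,v) = 1 equivalent to
u = v.  Any fixed positive weight vector preserves every property the
package asserts; the enumeration convention is documented so the vector
is reproducible.

## RGF-distance and GDD-agreement

RGF-distance uses Fᵢ = −ln(Nᵢ/T) with T = ΣNᵢ.  Zero counts are handled
so the sum stays finite and symmetric: graphlets absent from *both*
networks are skipped; a count of zero in exactly one network is replaced
by a pseudo-count of 1 before forming Fᵢ.  On strictly positive counts
this reduces to the pure definition.  The natural logarithm is used; the
result object records which graphlets were skipped or smoothed.

GDD-agreement per orbit j: from the touch counts, dʲ(k) = #nodes touching
orbit j exactly k ≥ 1 times; Sʲ(k) = dʲ(k)/k (the 1/k scaling removes the
k = 0 bin and tempers heavy tails); Nʲ(k) = Sʲ(k)/Σ Sʲ; and
Aⱼ = 1 − (1/√2)·‖Nʲ_G − Nʲ_H‖₂ ∈ [0, 1].  An orbit absent from both
networks contributes Aⱼ = 1 (identical empty distributions); an orbit
absent from exactly one network is compared against the empty
distribution.  The agreement is the arithmetic mean of the 73 Aⱼ by
default; a geometric mean is available by flag.

## Random models

All generators take a single integer seed feeding one `numpy` Generator,
so outputs are bit-reproducible.  Model instances are sized to the data:
n nodes and, where the model's natural output size is random, a post-hoc
uniform edge add/delete adjustment to exactly m edges (SF, SF-GD).
Defaults, chosen as typical usage for PPI-scale sparse networks:

| model  | key parameters | default |
|--------|----------------|---------|
| ER     | n, m           | — |
| ER-DD  | degree sequence; bounded stub-matching retries | 100 restarts |
| SF     | attachment degree d = round(m/n) | — |
| GEO    | dimension of the unit cube | dim = 3 |
| STICKY | degree sequence (θᵢ = dᵢ/√Σd) | natural random m |
| SF-GD  | divergence probability q; duplicate-link probability | q = 0.5, p_link = 0.1 |
| GEO-GD | locality probability p; ball radius | p = 0.5, ε = 2·r̂, dim = 3 |

Design notes:

* **GEO radius.**  Rather than fixing a radius and accepting a random
  edge count, the connection radius is the m-th smallest pairwise
  distance (ties broken by pair index), which hits m exactly and
  deterministically.
* **STICKY** is deliberately *not* adjusted to m: its defining property
  is the per-pair edge probability θᵢθⱼ, so the edge count stays random
  with expectation ≈ Σd/2 (verified within 5 % over 200 seeds).
* **SF-GD** starts growth from a single edge; the duplicate-link
  probability p_link is exposed because the growth literature varies on
  it.
* **GEO-GD** implements a probability-cutoff placement: with probability
  p the child point lands uniformly in a ball of radius ε around its
  parent (ε = twice the a-priori estimate of the final connection radius,
  from the expected number of pairs within r for uniform points), else
  uniformly in the cube.  p = 0 recovers GEO in law; larger p produces a
  more spatially clustered point set (smaller mean nearest-neighbour
  distance, checked statistically).

## GRAAL alignment

Costs combine degrees and signatures,
C(u,v) = 2 − [(1−α)(deg u + deg v)/(maxdeg G + maxdeg H) + α·S(u,v)],
with α = 0.8 by default (signatures dominate; α is configurable).  The
aligner seeds with the cheapest unaligned pair and extends breadth-first:
for radii 1..3 around the seed, the unaligned neighbours of each aligned
pair (a, b) are matched greedily in ascending cost.  Constraining the
greedy matching to the neighbourhoods of aligned pairs — rather than the
full cross-product of the two spheres — is what makes the extension walk
both networks in lock-step and map edges onto edges; with unconstrained
sphere pairing, cost ties (e.g. on a cycle, where all nodes share one
signature) can cross BFS branches and break adjacency.  When unaligned
nodes remain after a pass, seeding/extension is repeated on the power
graphs G^p, H^p (nodes within distance ≤ p adjacent) for p = 1, 2, 3
cyclically; signatures and degrees always come from the original graphs,
power graphs only guide traversal.  Every round aligns at least its seed
pair, so termination and totality are guaranteed; injectivity is
maintained by construction.  All ties are broken by a seeded random
priority matrix, making alignments deterministic per seed.

Greedy seed-and-extend is not guaranteed optimal; the suite asserts
statistical quality instead: self-alignment edge correctness ≥ 90 % on
average over 20 seeds (measured: 100 % on 50-node small-world graphs) and
monotone degradation under 5 % vs 25 % edge rewiring.  Like any purely
topological aligner, GRAAL degrades quickly on noisy networks — the noise
experiment quantifies exactly that.

## k-medoids clustering

The distance matrix is D = 1 − S (square within one network, rectangular
across two).  k medoids are initialised uniformly at random; iteration
alternates nearest-medoid assignment (ties to the lowest cluster index)
with medoid update (member minimising summed within-cluster distance,
ties to the lowest node index) until the medoid set is stable or 300
iterations.  The objective is checked to be non-increasing at every step.
A cluster emptied during assignment is repaired by reseeding its medoid
at the node farthest from its current medoid.  k is user-supplied;
`random_partition` provides the uniform null model with non-empty
clusters for enrichment-style comparisons.

An important caveat on what signature clustering can recover: signatures
encode local topological *role*, not component or community identity.
Two structurally identical communities (e.g. two disjoint equal cliques)
produce identical signature rows and cannot be separated by any
signature-based method.  The planted-structure tests therefore use blocks
of distinct internal density (0.8 vs 0.25 within, 0.03 between, 15 nodes
each), which signatures separate reliably (mean adjusted Rand ≈ 0.9–1.0
over seeds).

## Task planner

Analyses decompose into 8 basic task types (model generation, graphlet
counting, RGF-distance, GDD-agreement, GRAAL execution, signature
similarities, k-medoids clustering, basic-properties comparison) with
explicit dependencies: distance/agreement tasks require the counts of
both of their networks; alignment and clustering require signatures;
instance counting requires generation.  A model-fit plan for n_d data
networks, n_m models and n_i instances contains
n_d·n_m·n_i + (n_d + n_d·n_m·n_i) + 3·n_d·n_m·n_i tasks (3 × 7 × 10 →
1,053).  `ready_tasks` yields the tasks whose prerequisites are complete;
`run_plan` executes a plan on a thread pool (result independence from
worker count is tested at 1 vs 4 workers) with a file-backed cache keyed
by a SHA-256 digest of (task type, inputs, parameters), so resumed or
follow-up analyses skip everything already computed.

## Input handling

Both readers enforce the undirected-simple-unweighted contract:
self-loops, duplicate edges (either orientation) and directions are
stripped on read.  Edge lists are whitespace-delimited pairs (blank lines
and `#` comments skipped); the LEDA `.gw` dialect accepts the
parameterised header, uses node payloads between `|{` `}|` as labels
(falling back to 1-based position), and preserves isolated declared
nodes — the edge-list format cannot express those, which is the one
asymmetry between the formats.

## Problem sizes in the test suite

Fixtures are generated, not stored: oracle equivalence uses 225 graphs
with n ≤ 12 (where subset enumeration is exact and fast); metric
identities use 50 graphs with n ≤ 14; alignment quality uses 50-node
connected small-world graphs over 20 seeds; clustering uses 30-node
planted graphs over 5 seeds.  These sizes make every statistical
assertion cheap to re-run while remaining large enough for the asserted
margins to be stable across seeds.  Synthetic model graphs share the
broad features of sparse PPI data (size, density, heavy tails for the
growth models, local clustering for the geometric ones) but none of its
measurement noise or sampling bias, so green tests certify algorithmic
correctness and statistical behaviour on clean topology — not performance
on any particular experimental interactome.

## Known limitations

* Graphlets stop at 5 nodes and graphs are undirected and unweighted by
  design; there is no sampling-based approximate counting, so very dense
  or very large networks (≫10⁴ nodes) are slow in pure Python.
* The orbit-weight enumeration convention and orbit numbering are
  self-consistent but not interchangeable with other implementations'
  numbering.
* GRAAL's greedy extension has no optimality guarantee and should not be
  used on noisy networks.
* The k-medoids result depends on initialisation; run several seeds (or
  several k, as the clustering literature recommends) and compare
  objectives.
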
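# Methods

## Profiles and similarity

A protein's phylogenetic profile is a binary vector **L** indexed by a
fixed, ordered universe of species-rank taxa. A bit is set when the protein
has at least one homology hit — E-value ≤ 10⁻³, subject sequence length
within 80–120% of the query (inclusive at both boundaries) — in any taxon
that collapses to that species. Lengths are full sequence lengths
(`qlen`/`slen`), not alignment lengths: the filter's intent is to compare
whole proteins of commensurate size, not to score local coverage. Strain-
and subspecies-level taxids are collapsed to their species-rank ancestor,
so database redundancy (many genomes of one species) cannot inflate a
profile. Hits to the query organism itself are excluded; a profile records
non-self homology only. Taxids missing from the taxonomy dump are counted
and skipped rather than treated as fatal, because version skew between a
sequence database and a taxonomy dump is the rule, not the exception.

Profiles are stored packed (eight species per byte) and all pairwise
scalar products are computed as popcounts of bitwise AND on the packed
matrix: D(i,j) = |Lᵢ ∩ Lⱼ|, the number of species common to the two
profiles. With N = popcount(L), the similarity is

    S(i,j) = D(i,j) / min(Nᵢ, Nⱼ)            (default)

with two alternatives exposed (and covered by the same tests):
D/√(NᵢNⱼ) ("geometric") and D/|Lᵢ ∪ Lⱼ| ("jaccard"). For any pair,
jaccard ≤ geometric ≤ min. The min-normalization is deliberately
asymmetric-friendly — a narrow profile nested inside a broad one scores
1.0 — and is therefore only meaningful together with the **length gate**:
a pair contributes to the analysis only when min(N)/max(N) ≥ 0.6. Without
the gate, the near-universal presence of most proteins across a clade
creates dense spurious similarity and destroys cluster resolution; with
it, the residual asymmetry of min-normalization is bounded by the factor
0.6. Pairs with either N = 0 score 0 and never pass the gate. Both the
gate ratio and the 80/120% filter are evaluated on ratios (60/100 ≥ 0.6 is
exactly true in binary floating point because correctly rounded division
maps an exact decimal ratio onto the same double as the literal), so the
documented inclusive boundaries hold exactly.

## Graph, layout and convex clustering

The similarity graph has one node per protein (isolated nodes included)
and an edge for every gated pair, weighted by S. Clustering uses **all**
gated pairs (threshold 0); the 0.6 similarity threshold is a display
convention only, used when writing the CLANS interchange file.

The layout is a Fruchterman–Reingold scheme: all node pairs repel with
force k²/d, edges attract with force S·d²/k, where k scales as
(1/|V|)^(1/dims) and S acts directly as the attraction strength (the graph
carries similarities, not E-values, so no score conversion is applied).
Per-step displacement is capped by a temperature that decays by a factor
0.99 per iteration from 0.1; defaults are 3 dimensions and 1000
iterations, which converge robustly on graphs up to a few thousand nodes.
Coincident nodes are jittered by a seeded epsilon, so forces are always
finite; the whole layout is deterministic given its seed. The layout is
for visualization and sanity checks — cluster calls never depend on it.

Cluster calling is a deterministic reconstruction of attraction-threshold
("convex") clustering. Let μ and σ be the mean and population standard
deviation of all gated pairwise similarities, and θ = μ + 0.5σ. The
attraction of protein i to cluster C is the mean of S(i,j) over members
j ≠ i, with non-edges (gated-out or sub-similar pairs) contributing 0.
Seed clusters are the connected components of the graph restricted to
edges with S ≥ θ; membership is then re-evaluated synchronously — each
protein moves to the cluster maximizing its attraction if that attraction
reaches θ, otherwise to the cloud — until a fixpoint (at most 100 rounds;
in practice 2–5). Numerical choices:

* **Inclusive admission** (attraction ≥ θ, not >): in the degenerate
  uniform-similarity case σ = 0 makes θ equal the maximum attainable
  attraction, and a strict comparison would dissolve perfect clusters.
* **Tie-breaks**: equal attraction goes to the larger cluster, then to the
  one containing the lexicographically smallest protein id; together with
  sorted node processing this makes the result invariant to input order.
* Clusters smaller than 2 dissolve into the cloud; labels A, B, C, … are
  assigned by descending size.

This rule is a global-threshold method: whether a cluster survives depends
on the dataset-wide similarity mix, not only on its own cohesion. Two
consequences are worth knowing. First, a single above-threshold edge
between two seed components merges them, and a merged heterogeneous seed
usually dissolves entirely (every member's attraction to the mixture falls
below θ) — the synthetic generator's default geometry is designed to keep
cross-cluster similarities well below θ for this reason. Second, the
response to rising profile noise is *not* monotone: past the point where
clusters dissolve, further noise homogenizes profile breadths, shrinks σ
and lowers θ faster than cohesion decays, so the broadest cluster can
partially re-emerge at extreme noise. The tests assert strong recovery at
the design noise level and degradation away from it, not pairwise
monotonicity.

## Statistics

* **ANOVA**: one-way fixed-effects F test (`scipy.stats.f_oneway`) of a
  per-protein quantity (length in residues, taxonomy-hit count N) across
  clusters including the cloud; groups need ≥ 2 values.
* **Binomial category test**: exact tail probability
  (`scipy.stats.binomtest`) that k of n category proteins (e.g. n = 54
  disease-mutation proteins) fall in a cluster when each does so with
  probability p₀ = the cluster's share of the proteome. One-sided in the
  direction of the observed deviation by default; two-sided by small-p
  aggregation is exposed.
* **Venn overlaps**: exclusive region counts of up to four clusters'
  species unions; regions partition the union by construction.
* **Term enrichment**: per term with ≥ 1 cluster occurrence, the
  hypergeometric upper tail of drawing k annotated proteins in a cluster
  of m from a background of N containing K annotated; fold enrichment
  (k/m)/(K/N); Benjamini–Hochberg step-up adjustment across the cluster's
  tested terms. This is a plain hypergeometric test, not a modified
  one-sided EASE-style score, so absolute agreement with tools using the
  latter is not expected; ranks agree in practice. BH is *not* idempotent
  (re-adjusting multiplies sorted values by n/rank again); the guaranteed
  properties — adjusted ≥ raw, monotone in rank, capped at 1 — are what
  the tests assert.

## Synthetic data: what it emulates and what it does not

The generator plants a known cluster structure to make every stage
testable end to end. The default instance:

* **Taxonomy**: 3 superkingdoms × 4 phyla × 10 species = 120 species, two
  strains each, plus a designated query-organism species excluded from the
  profile universe (so self-hits exist in the hit table and must be
  removed).
* **Clusters**: 50/30/20/10 proteins ("ubiquitous"/"broad"/"narrow"/
  "very narrow") with species pools covering 55/35/25/18% of the universe.
  Pools are windows over one seeded permutation of the species axis,
  placed so that adjacent breadth tiers share roughly a third of the
  smaller pool (partially nested species sets) while tiers three apart are
  disjoint. Members set each pool bit with probability 0.95, then every
  bit flips with probability 0.05.
* **Cloud**: 30 proteins with individual uniformly-random pools whose
  breadth is uniform between 5% and 45% of the universe.
* **Hit table**: one row per set bit against a random strain below the
  species, in-window length, E-value ≤ 10⁻⁴; per protein four decoys —
  E-value 0.01, subject just below 80% and just above 120% of the query,
  and an otherwise-valid self-hit — which the filters must remove exactly.
  Parsing → filtering → species-collapsing → profile-building reproduces
  the source profiles bit for bit.

The pool geometry is chosen so the pipeline's two separation mechanisms
are both exercised: breadth tiers more than the gate ratio apart
(ubiquitous vs the narrow tiers) are separated by the length gate alone —
their cross edges do not exist — while adjacent tiers (which do pass the
gate) are separated by similarity, their limited pool overlap keeping
cross-cluster S far below the clustering threshold θ ≈ 0.67. Cloud
breadths stay below the broadest tier's realized popcount; above it,
min-normalization would give a broad random profile S ≈ its own breadth
against *every* cluster, letting single noisy cloud proteins bridge seed
components. Protein lengths are lognormal around per-cluster means
(350/450/650/300 residues; cloud 520) so the length ANOVA has signal, and
a Bernoulli(0.04) disease-mutation flag mimics the sparsity of curated
mutation annotations.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: presence/absence is independent per bit, whereas
real homologue distributions are tree-correlated (gain/loss along
lineages); the 5% uniform flip noise is far noisier, relative to narrow
profiles, than real false-hit rates, while the universe (120 species) is
~30× smaller than a RefSeq-scale species set; real cluster breadths are
more extreme (the broadest real clusters reach thousands of species while
narrow ones have a few dozen); and annotation terms are synthetic tokens,
not GO/pathway vocabularies. Recovery of planted labels here demonstrates
the correctness and determinism of the machinery, not field performance
on a particular proteome.

## Problem sizes and determinism

Default test and acceptance runs use the 140-protein × 120-species
instance (∼9,700 profile pairs), 20 replicate seeds for recovery
statistics, and 10⁴ random pairs for the bitset/similarity oracles; a full
pipeline run takes well under a second, the whole suite a few seconds.
Every random draw flows from an explicit integer seed through
`numpy.random.default_rng`; identical inputs and seeds give byte-identical
cluster assignments, layouts and serialized fixtures.
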
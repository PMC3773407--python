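# Methods

This note documents the models, parameter defaults and numerical choices
behind `cgcphy`, and what the synthetic validation does and does not show.

## 1. Ortholog assignment

**Objective.**  Between genomes G (genes i = 1..n, operons k₂ = 1..p) and H
(genes j = 1..m, operons k₁ = 1..o), the assignment x ∈ {0,1}ⁿˣᵐ is a
one-to-one matching over candidate pairs that maximizes

    Σ x_ij · a · A_ij  −  b · |{operons of H touched}|  −  c · |{operons of G touched}|

The operon terms implement structural parsimony: a biologically coherent
ortholog set concentrates in few operons, so touching an additional operon
costs b (resp. c).  Genes outside any annotated operon are modelled as
singleton operon units, so every gene has exactly one unit.  The published
description of this optimization is contradictory as printed ("minimizes
the objective" with all-positive terms would make the empty matching
optimal); we implement the stated intent — similarity rewarded, operon
fragmentation penalized.

**Candidate filter.**  E-value ≤ 10⁻³, identity > 30 % (strict; the cut is
toggleable since it originates in an earlier reciprocal-best-hit protocol),
and COG compatibility: a hit is dropped only when *both* genes carry COG
categories and they differ.  One best-scoring hit is kept per gene pair.

**Score scale A_ij.**  Default `raw`: A_ij is the hit score as given
(bit-score-like, typically 50–2000), against which b = c = 0.5 act as weak
tie-breakers — this matches the weighting the method was published with
(A = 1.0 on raw scores, B = C = 0.5).  A `normalized` mode
(A_ij = score / best score of the pair) exists but is not the pipeline
default: with unit-scale similarities the 0.5 penalties rival the rewards,
singleton-operon genes can never pay for themselves, and distant genome
pairs lose so many orthologs that the count-based distance develops
plateaus across distinct divergence depths.

**Solver.**  The candidate graph (similarity edges plus operon
co-membership) is split into connected components.  A component touching at
most 12 operons is solved *exactly*: enumerate activation subsets (S_A,
S_B) of its operons, solve a maximum-weight bipartite matching
(`scipy.optimize.linear_sum_assignment`) restricted to activated genes, and
score it as matching weight − b|S_B| − c|S_C|; the maximum over subsets is
the global optimum because the optimal matching's own touched-operon sets
occur in the enumeration.  Larger components use first-improvement local
search (drop, whole-operon group drop, add, replace, 2-swap; ≤ 20 passes)
seeded from the unconstrained matching; zero-gain adds are accepted so that
fully tied instances keep the complete matching.  The local search is a
heuristic: on adversarial small instances with penalties comparable to the
rewards it can miss the optimum (observed gaps up to ~0.6 on a unit scale);
under the default raw-score regime the penalties are second-order and the
seed matching is already near-optimal.  Exhaustive enumeration over all
matchings (`brute_force_orthologs`) serves as the independent oracle in the
tests, and the default solver matches it exactly on 200 random ≤ 6×6
instances.

## 2. HGT-gene elimination

**Ratio of orthologous genes.**  R_og(G,H) = 2·N_O/(N_G+N_H) ∈ [0,1]; a
species set S is summarised by the mean over its C(|S|,2) pairs.

**Three-sigma calibration.**  m random subsets of a reference panel
(default m = 10 000; subsets the size of the analysis set) give μ and σ
(sample sd) of the set statistic.  The analysis set is *ordinary* (oss)
when its statistic lies within the closed interval [μ−3σ, μ+3σ] for mean
R_og, and for std R_ge when it lies in (−∞, μ+3σ]; it is *special* (sss)
outside.  The upper-tail-only rule for std R_ge means unusually homogeneous
sets are not special for the barcode screen.

**Conserved-gene screen.**  For ordinary sets, genes orthologous in at
least (1−0.15) = 85 % of the panel's species are eliminated; special sets
(e.g. a single phylum, where universal conservation reflects vertical
descent) skip it.  The published elimination count "0.15·N_as" is read as
this occupancy threshold, consistent with the accompanying discussion that
the conserved tail starts near 85 % of the panel size; the literal reading
(eliminate exactly 92.55 genes) is not implementable as printed.

**Genome barcodes.**  A genome of length M is cut into N = ⌊M/1000⌋
non-overlapping 1 kb fragments; each fragment's barcode is the combined
frequency of each 4-mer and its reverse complement over the L−k+1 sliding
windows (windows containing non-ACGT symbols are excluded from numerator
and denominator).  Pairing 4-mers with reverse complements yields 120
two-member classes + 16 palindromic classes = 136 dimensions; palindromes
are counted once so one normalization serves all classes and rows of clean
fragments sum to 1.  The class construction makes the barcode invariant
under reverse-complementing the genome.  Fragment anomaly is the Euclidean
distance to the genome's average barcode; the genomic-evolution value is
r_ge = mean(dis) + 3·sd(dis) (sample sd throughout, consistent with the
1/(m−1) convention used by the calibrations).  Published r_ge values on
real panels (≈0.6–0.9) depend on the genome panel and an unstated frequency
scale and are not asserted here.

**Barcode screen.**  In special sets, fragments are walked in decreasing
anomaly order (ties: ascending index), collecting genes by any-bp overlap,
until ⌊0.2·N_g⌋ genes are collected; the collection is truncated to exactly
that count (so the overflow from the last fragment drops its highest-index
genes — fully deterministic).  The 20 % budget reflects the expectation
that roughly a fifth of a prokaryotic genome's genes are HGT-involved; it
is applied to every genome of a special set, including ones with little
foreign content, whose "most anomalous" fragments are then just noise —
the main cost of the screen.

**Calibration scope.**  The reference panel defaults to the analysis set
itself; an external panel can be supplied, and calibration subsets may be
drawn either from the whole panel (`calibration_scope="panel"`, the
original design: analysis sets are a negligible fraction of a 617-genome
universe) or from the external reference only (`"reference"`).  At desk
scale the second is the meaningful null: a self-calibrated statistic sits
at its own calibration mean by construction, so a 10-genome clade that is
homogeneous, or HGT-riddled, can never be three sigma from subsets that
resample its own members.  The synthetic experiments therefore calibrate on
the clean background panel.

## 3. Conserved gene clusters and the distance

A cluster is a chain of ortholog pairs: consecutive pairs advance by +1 in
the A gene index and ±1 in B (orientation uniform per cluster: forward or
inverted), except that up to `max_gap_events` = 1 time per cluster one side
may jump over up to `max_gap_len` = 2 genes while the other advances by
one.  Chains shorter than `min_cluster_size` = 2 are discarded.  These
defaults are the smallest values that reproduce the published 16-gene
worked example (4 clusters, N_cgc = 14); allowing two gap events per
cluster merges its two indel-bearing clusters.

**Segmentation.**  Chains must be contiguous in the walking order, so the
pair list is segmented by dynamic programming maximizing (genes covered,
−gap events, −clusters) lexicographically.  Greedy left-to-right chaining
was rejected: on the worked example it absorbs the head of the second indel
chain into the first and strands the tail below minimum size,
under-counting the clustered genes (13 instead of 14).  The segmentation is
run along both genomes and the better cover kept, with order-independent
tie-breaks (lexicographically smaller canonical cover, then the walk along
the genome whose id sorts first), making detection symmetric in the two
genomes.

**Distance.**  D_cgc = −log₁₀(N_cgc); base 10 is forced by the worked value
−log₁₀(14) = −1.1461.  N_cgc = 0 is mapped to a configurable sentinel
(+1.0, one decade beyond a single shared gene) since the log is undefined;
the diagonal is 0 by definition.  Distances are typically negative; NJ
operates on arbitrary real dissimilarities, so no shift is applied.

## 4. Tree building and evaluation

Neighbor joining follows Saitou–Nei with the Q-criterion; ties are broken
by the lexicographically smallest contained leaf labels, so output is
deterministic.  Negative branch lengths are kept (logged) unless
`clamp_negative` is set.  On additive matrices the implementation recovers
topology and branch lengths to < 10⁻⁹ (property-tested, 4–20 leaves) and
agrees with an independent NJ implementation.

Quartet agreement: the reference is the multifurcating rank trie of
Bergey-style codes (one internal node per code prefix).  A quartet is
*effective* when the reference resolves it; accuracy is agreement over
effective quartets only, and a fully star reference yields an explicit
undefined (never 0/0).  Topologies are read from pairwise topological LCA
depths (the pairing with the strictly largest depth sum; a three-way tie is
a star), precomputed in O(n²) so exact enumeration of all C(n,4) quartets
is practical to n = 60; beyond that a seeded uniform sampler is used, whose
estimate is unbiased (checked against exact enumeration).

## 5. Synthetic data: what it models

The generator evolves an annotated ancestral genome (operon sizes
geometric with mean 3, clipped at 8; uniform single-letter COGs; 900 bp
genes, 100 bp intergenic spacers) along a given tree with per-branch gene
loss (probability 1−e^(−rate·bl)), segmental inversions (strand-flipping),
short indels, and insertion of foreign cassettes (4–6 genes) drawn from a
small donor pool, optionally confined to a sub-clade.  Sequence is emitted
as GC-parameterised i.i.d. draws (host GC 0.5; foreign GC shifted by
`foreign_gc_shift`): only composition matters downstream, so no
substitution process is simulated.

Similarity is modelled directly: a vertically inherited gene's identity
decays as 100·e^(−r_g·d) with tree distance d.  Rates are parameterised by
a per-gene *detectability horizon* t_g (the d at which identity crosses
30 %), drawn Exponential with mean 1/(β·ln 10), β = `divergence_decay` =
0.3 decades per unit branch length.  Then the expected number of detectable
orthologs is n_genes·10^(−βd), so −log₁₀(count) is affine in d — and on a
clock-like tree every monotone transform of an ultrametric is additive with
the same topology, making exact NJ recovery the *correct* outcome of an
event-free run rather than a coincidence.  This is a deliberate design
device; real divergence-vs-synteny relationships need not be log-linear.
Cassette copies descending from different insertion events of one donor hit
each other at ≈99 % identity regardless of host distance — the xenolog
signal that distorts unfiltered distances.  A configurable fraction of
spurious low-identity hits models paralog noise.

Random clock-like trees place merge times with uniform(0.7, 1.3)-spaced
gaps, so no two internal depths coincide and adjacent depths stay
distinguishable in finite gene counts.

## 6. Canned experiments (study conditions)

Both experiments embed a 10-leaf analysis clade (depth 1.0) inside a
14-genome background clade (depth 2.5, joined at total depth 3.0) that
provides the calibration panel and occurrence counts; quartet accuracy is
scored against the generating subtree on the analysis leaves.

* **Event-free recovery** — all event rates 0, spurious-free noiseless
  hits, n_genes = 400 (large enough that every pair of distinct tree depths
  differs by several detectable orthologs).  Expectation: quartet accuracy
  exactly 1.0 through the *full* pipeline — the conserved-gene screen
  classifies the homogeneous clade as special (mean R_og far above the
  background calibration) and correctly stands down.
* **HGT benefit** — n_genes = 250, insertions confined to the analysis
  clade at rate 3.0 per unit branch length (≈20 % foreign genes per exposed
  genome, the regime the 20 % elimination budget presumes), GC shift
  +0.25, donor pool of 3 cassettes.  Ten replicates compare the full
  pipeline against the no-filter arm; the expectation is directional
  (filtered ≥ unfiltered in ≥ 7/10), not a fixed accuracy gain: replicates
  where the cassettes happen not to distort the topology leave nothing for
  the filter to win.

Passing these shows the pipeline's stages compose correctly and the
barcode screen removes planted foreign genes with high precision under its
own model.  It does *not* show that real prokaryotic HGT is confined to
GC-shifted recent cassettes, that real divergence is clock-like, or that
similarity decays exponentially — the synthetic generator realises the
method's assumptions, it does not test them.

## 7. Numerical and degenerate-input conventions

* Coordinates 1-based inclusive; fragment and gene indices 0-based.
* Sample (n−1) standard deviations everywhere.
* Non-contiguous operon declarations are split into contiguous runs (with
  a warning) rather than rejected.
* Multi-record FASTA is rejected: multi-chromosome genomes are out of
  scope (gene clusters do not span chromosomes).
* Chromosomes are treated as linear; genes spanning the origin of a
  circular chromosome are not modelled.
* Solver/DP tie-breaks are lexicographic on gene ids / leaf labels
  throughout, so all outputs are reproducible bit-for-bit under a fixed
  seed.
* Calibrations consume a seeded `numpy` Generator; the pipeline derives
  the two calibration seeds from its single `seed` option.

## 8. Known limitations

* The local-search path of the assignment solver is heuristic (see §1).
* Cluster detection assumes a one-to-one map; many-to-many ortholog groups
  and tree reconciliation are out of scope.
* The quartet enumerator is O(n⁴) with O(1) per quartet — fine at desk
  scale, far from the asymptotically optimal quartet-distance algorithms.
* The three-sigma screens inherit the calibration-scope caveat of §2: with
  a small self-panel they are conservative to the point of inertness.
* N_cgc is not normalised by genome size; very unequal genome sizes bias
  the distance, as in the original formulation.
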
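# Methods

This note documents the models, parameter choices and numerical
conventions behind `panstrep`, and what the synthetic-data tests do and
do not establish about real data.

## Orthologue detection

Pairwise similarity is computed by optimal Smith–Waterman local
alignment (Biopython's `PairwiseAligner`; BLOSUM62, first gap column
−11, each further −1). Three statistics are derived from the optimal
alignment:

- **percent identity** — identical columns divided by the full
  alignment length *including gap columns* (the BLAST `pident`
  convention, since the thresholds were designed for BLAST output);
- **coverage** — aligned span (end − start) on each sequence divided by
  its full length, computed separately for query and subject
  ("qcovs-like"); both sides must reach the threshold;
- **E-value** — a Karlin–Altschul approximation with the fixed gapped
  BLOSUM62 parameters λ = 0.267, K = 0.041 and search space m·n per
  pair. This is an intentional simplification: the E-value acts only as
  a filter, and at identity ≥ 80% / coverage ≥ 0.70 the identity and
  coverage criteria dominate by orders of magnitude. When hits are
  ingested from BLAST tabular files the file's E-value is authoritative,
  and `qlen`/`slen` columns are mandatory because dual-sided coverage
  cannot be computed without them.

Boundary semantics follow the inequality directions as printed:
identity and coverage thresholds are inclusive (≥), the E-value
threshold is strict (<). The same conventions recur in every other
filter: Pfam/SMART at E < 10⁻¹, EggNOG at E < 10⁻¹⁰, PPTase at
E < 10⁻³, relaxed KO rescue at E < 10⁻⁸⁰ — all strict.

The all-vs-all search prefilters candidate pairs with an inverted
k-mer index (k = 5, ≥ 2 shared distinct k-mers). Two unrelated uniform
sequences of length ~150 share two 5-mers with negligible probability,
while any pair at ≥ 80% identity shares many; correctness is guarded by
an oracle-equivalence test (prefiltered search vs exhaustive
full-matrix DP on a 50-protein set), and the prefilter can be disabled.
A score-only pass precedes the traceback so that pairs whose E-value
already fails are discarded cheaply.

Amino-acid validation accepts the residues scored by BLOSUM62
(20 standard + B, Z, X); the rare letters U, O, J are mapped to X
before alignment, anything else is an error naming the position.

## Graph clustering

Nodes are the full protein universe (proteins without hits become
isolated singletons); an undirected edge joins a pair when *either*
direction qualifies — the criterion is pairwise, not
reciprocal-best-hit. Groups are connected components, i.e. single
linkage: one qualifying pair merges two groups, and chains can in
principle connect proteins that are not directly similar. This is a
known property of the method, preserved deliberately; no community
detection is applied on top.

Conservation labels apply the real-valued prevalence fraction with no
rounding: at N = 205 "core" (≥ 95%) means prevalence ≥ 195 and "rare"
(< 5%) means ≤ 10 — reproducing the "10 genomes or fewer" arithmetic.
Group ids are assigned by sorting components on their smallest member
id, so outputs are byte-stable across runs.

## Pangenome statistics

Accumulation curves use 100 random genome orderings by default (the
number of orderings is an open choice; it is exposed, seeded, and the
exhaustive-enumeration oracle test covers a 3-genome toy where all 6
orderings are checked). At k genomes the strict core counts groups
present in all k, the soft core groups present in ≥ 95% of k.
Conservation bins are the twenty half-open intervals
(0, 0.05], (0.05, 0.10], …, (0.95, 1.0] — open on the left, closed on
the right, which places a group at exactly 5% prevalence in the lowest
bin and makes (0.95, 1.0] the core bin.

The unique-vs-proteome-size association uses Spearman rank correlation
(the analysis does not hinge on linearity); Pearson is switchable.
Printed percentages use decimal half-up rounding at 0.1% resolution
(integer option for coarse figures). The Heaps-law exponent fit on the
mean accumulation curve is a convenience openness diagnostic beyond
the core method.

## Feature classifiers

Sigma-factor and TF calls are pure functions of the per-protein domain
multiset; order never matters, and the sigma rules are tested over all
2⁵ presence combinations of the five σ⁷⁰ domains. A protein matching
both σ⁷⁰ and σ⁵⁴ rules is called σ⁷⁰ with a conflict warning (no σ⁵⁴
factor is expected in streptomycetes). The TF architecture catalogue is
external configuration with a documented TSV schema (required set,
forbidden set, priority; smallest priority wins, ties logged); the
built-in five-family table (SARP, TetR, MarR, LacI, LuxR) is a test
fixture, not a complete catalogue. "Second transferase domain" for
Sfp-typing is operationalised as ≥ 2 envelope-non-overlapping PF01648
hits, overlap meaning any shared residue; the count is the maximum
non-overlapping subset (greedy interval scheduling, optimal for this
objective).

## Pathway completeness

Steps use OR semantics over their KO sets (isoenzymes and multi-subunit
alternatives). Completeness is genome-level presence only — copy number
and synteny are out of scope. The shipped β-ketoadipate definition
carries real KEGG KO identifiers as *editable defaults* (e.g. K00448/
K00449 for protocatechuate 3,4-dioxygenase, K03381 for catechol
1,2-dioxygenase, shared K01055/K14727, K01031/K01032, K00632/K07823);
users should review them against the current KEGG release. Because the
two branches share their last three steps by construction, the
shared-step presence flags for a genome always agree between branches —
asserted as an invariant.

## CAZyme landscape

Family selection keeps a family iff ≥ 70% of its member proteins sit in
groups whose prevalence fraction lies in [0.05, 0.55]; both band edges
and the 70% cut are inclusive ("at least", "between"). Matrix columns
are the selected families' groups at prevalence ≥ 0.05.

Embedding distance is Jaccard on binary rows (the natural choice for
presence–absence data; configurable). Defaults: UMAP n_neighbors = 15
(clamped below the strain count), min_dist = 0.1, fixed seed mandatory
in pipeline mode. A deterministic classical-MDS (Torgerson) fallback on
the same Jaccard distances, with an eigenvector sign convention fixed
for reproducibility, allows cluster-recovery checks independent of the
stochastic embedder. Clustering is HDBSCAN on the 2D coordinates with
min_cluster_size = 5 by default; for planted-block recovery the tests
set min_cluster_size to half the block size (10 for 20-strain blocks),
the standard way of telling HDBSCAN the smallest cluster worth
reporting — at 5, 20-point blocks can fragment into density
sub-clusters. A fully degenerate matrix (all strains identical) is
returned as a single cluster directly, since density clustering cannot
operate on zero spread.

## Synthetic data: what it does and does not emulate

Each planted group is one ancestor sequence (i.i.d. uniform over the 20
standard residues) plus one substitution-only mutated copy per member
genome. Copies are mutated at identity 1 − (1 − g)/2 to the ancestor so
that two members, with mostly disjoint substitutions, sit near the
target pairwise identity g; at g = 0.9 the expected pairwise identity
is ≈ 0.90, verified against the DP oracle. Substitution-only mutation
makes identity exact by construction and the threshold boundary
deterministic to test. Prevalence bands draw accessory group prevalence
uniformly; unique proteins are independent random sequences (at length
≥ 100 a spurious ≥ 80%-identity/70%-coverage hit between unrelated
sequences is vanishingly unlikely); paralogs are extra within-genome
copies at a per-member rate.

Default study conditions: 20 genomes, 150 core groups, 30 accessory
groups over two prevalence bands, 10 unique proteins per genome,
within-group identity 0.9, paralog rate 0.02, lengths 100–300. The
identity level and cohort size are free parameters of the generator,
not estimates of real within-genus divergence; they are chosen so that
planted groups are unambiguous at the 80%/70% thresholds while the
mutation machinery still exercises the aligner.

Consequently, a perfect adjusted Rand index on this generator shows the
search, filtering and clustering machinery is correct — it does **not**
show that the thresholds resolve real paralogous families (the sigma
factor SigB/SigI/SigN/SigL problem), domain-shuffled architectures, or
indel-rich alignments. There is no phylogeny-aware gain/loss process,
no nucleotide level, no chromosome structure.

## Problem sizes and determinism

The test suite and the acceptance script run the planted-recovery
study at 20 genomes × ~180 proteins (~3,600 proteins, ~60k qualifying
directed hits), oracle equivalence at 50 proteins, component checks on
100 random graphs up to 200 nodes, and block recovery at 40 strains —
sizes chosen so the whole chain, including the O(nm) pure-Python DP
oracle, completes in minutes on one CPU. All randomness flows through
explicit seeds (`numpy.random.default_rng`); identical configuration
and seed give byte-identical pipeline artefacts, and the UMAP embedding
is seeded (`random_state`) at the cost of single-threaded layout.

## Known limitations

- Single-linkage chaining (above) is inherited from the method.
- The built-in E-value is approximate; for publication-grade hit
  tables, ingest real BLAST output instead of the internal aligner.
- COG multi-letter assignments are split one-contribution-per-letter by
  default (a single-category first-letter mode exists); KEGG category
  rollup requires a user-supplied KO → pathway → category mapping, and
  the eukaryote-only / secondary-metabolite exclusions are a config
  list, not bundled knowledge.
- The TF catalogue and pathway KO sets shipped here are small editable
  defaults, not the full external databases they stand in for.
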
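# Methods

`mcta` annotates metagenomic short reads by binning them first and
annotating whole bins, instead of aligning each read (or each assembled
contig) to a reference database on its own.  The unit of work is the
*virtual contig*: a group of reads and contigs treated as one object,
whose members need not be contiguous on the genome.  This note records
the model, the parameter choices, and the places where the design was
genuinely open.

## The three phases

**Phase 1 — virtual contigs.**  Reads are attached to assembled contigs
(≥ 500 bp) when an ungapped end-to-end placement on either strand
matches at ≥ 95% of positions.  Placements are found by exact 16-mer
seeding at a handful of read offsets followed by full-read Hamming
verification; with at most ⌊0.05·75⌋ = 3 tolerated mismatches, at least
one of the five seed windows of a 75 bp read is guaranteed error-free,
so seeding loses nothing.  Each used contig with its reads forms an
initial cluster; every unattached read is a singleton cluster.  Clusters
are then merged transitively whenever they share at least `min_shared`
(default 1) canonical w-mers with w = 36: substrings of that length are
effectively unique to a species, so a single shared one is strong
evidence of common origin.  Two guards apply: any w-mer containing N is
skipped, and a w-mer occurring in more than `repeat_cap` (default 50)
distinct initial clusters is discarded as repeat-like evidence, since
repeats and horizontally transferred segments are exactly the w-mers
that would chain unrelated clusters together.  The length of a virtual
contig is estimated as |distinct canonical w-mers| + (w − 1), which is
exact on repeat-free sequence and invariant to read coverage depth.

**Phase 2 — composition clustering.**  The q-mer spectrum of a genome is
a compositional signature; fragments of one genome have similar 4/5-mer
distributions.  Because coverage is uneven, profiles are computed over
the *distinct* w-mer set of a virtual contig (all w − q + 1 windows per
w-mer), not over raw reads — duplicate coverage collapses in the set, so
the estimate is exactly coverage-invariant.  Reverse-complement q-mer
pairs are collapsed (dimensions 136 for q = 4, 512 for q = 5), making
profiles strand-invariant, which clustering requires.  Long virtual
contigs (estimated length ≥ 10 kb) are clustered by K-means under the
Spearman distance 1 − ρ (ρ = Pearson correlation of average ranks;
constant profiles get distance 1, logged) of their 5-mer profiles.
Short virtual contigs are attached afterwards to the nearest centroid by
their 4-mer profiles: short fragments carry too little 5-mer signal to
steer the clustering.  The 4-mer centroid of a cluster is the
estimated-length-weighted mean of member profiles, renormalized — the
pooling rule was an open choice; length-weighting approximates the
profile the cluster's pooled sequence would have.

K-means details.  Initialization is deterministic farthest-point
seeding.  The centroid update is the renormalized arithmetic mean of
member frequency vectors — a standard relaxation, since the Spearman
distance has no closed-form centroid; the within-cluster objective is
asserted non-increasing per iteration and, if a mean update ever raises
it, the run stops at the previous assignment and logs the event.
Farthest-point seeding has a known failure mode: when one genome's
profiles are internally more spread than the gap between two other
genomes, two seeds land in the spread genome and Lloyd iterations cannot
escape.  After convergence a deterministic merge–split refinement
therefore evaluates, for every cluster pair and every third cluster,
merging the pair while bisecting the third, re-polishes the best
candidate with Lloyd iterations, and accepts it only when the objective
strictly decreases.  The procedure needs no randomness, so identical
inputs give identical partitions.  K is a user parameter; an `auto` mode
scans K ∈ [2, k_max] and keeps the best mean silhouette under the
Spearman distance.

**Phase 3 — annotation and merging.**  Only contigs are compared against
the reference database (reads inherit their cluster's annotation).  The
built-in scorer counts a contig's distinct canonical 12-mers present in
each reference genome — a cheap surrogate for an ungapped alignment
score: at 2% divergence a seed survives with probability ≈ 0.98¹² ≈
0.78, at 20% divergence ≈ 0.8¹² ≈ 0.069, while unrelated 100 kb genomes
share only ≈ 2–3% of seed k-mers by chance.  The hit threshold
`min_hit_fraction` = 0.05 sits between those regimes, so order-level
relatives remain detectable and random genomes are rejected.
Precomputed tabular hits (BLAST outfmt-6) can be imported instead and
follow the same best-hit-by-score rule.  A cluster is annotated to the
LCA of its contigs' best-hit genomes; clusters with no contig hits are
UNASSIGNED.  Clusters annotated to the same species-or-lower taxon are
merged (they are evidence of one organism, and the LCA of the pooled
hits equals the shared taxon, so the merge is idempotent); clusters
meeting only at genus or above are never merged, as they may hold
different species of one genus.

## Synthetic communities

The simulator emulates the benchmark protocol for unknown-species
annotation: each *target* genome is excluded from the reference
database, which keeps only relatives at a prescribed *reference level*
(same species, or same order with nothing below).  Defaults are the
protocol values: 75 bp paired-end reads, 1% substitution error, insert
length Normal(250, 50) truncated to [150 bp, genome end] (the ± in
"250 ± 50" is read as an SD, the common simulator convention), pair
count = round(coverage·|G|/150), forward–reverse orientation, 15×
coverage.  Errors are substitutions only, matching the ungapped ≥ 95%
read-placement rule.  Surrogate contigs are error-free non-overlapping
substrings ≥ 500 bp placed uniformly, covering a configured fraction of
each genome — they stand in for an assembler's output.

Genome sequences are drawn from a per-genome first-order Markov chain
whose transition rows are Dirichlet(6) draws.  This gives every genome
its own dinucleotide bias, hence a distinctive q-mer spectrum — the
property real genomes have through GC content and codon usage and the
one composition clustering depends on; i.i.d. uniform sequences would
make Phase 2 vacuous.  A reference relative at level L is the target
mutated at the level-L divergence (defaults: species 2%, genus 6%,
family 12%, order 20% — our convention, monotone so that order-level
relatives are much harder to hit with long exact matches).  Two
relatives are emitted per target (configurable): with a single relative,
every hit set collapses to that one genome and a cluster can only ever
be annotated to its species, never to the shared order, which would make
order-level annotation structurally impossible.

What the simulator does **not** model: indels, chimeric reads, quality
profiles, GC coverage bias, strain mixtures, plasmids, and real
inter-genome homology (repeats shared across species).  Passing tests
therefore show the method's logic is correct under its stated error
model, not that it reaches any particular accuracy on real data, where
assembly errors and shared repeats make Phase 1 evidence noisier.

## Numerical and procedural choices

- Ties break lexicographically everywhere (contig/genome/cluster ids),
  making every stage deterministic; a single global seed is fanned out
  per stage by CRC-32 hashing of `(seed, stage)`.
- w = 36 (smallest length satisfying the uniqueness argument), exposed
  as a flag; q = 5 for clustering, q = 4 for short-fragment attachment;
  10 kb long/short boundary ("at least 10 kb" is long).
- The w-mer sharing rule is a deterministic count threshold rather than
  a probabilistic model: one shared 36-mer is near-conclusive, and the
  repeat cap covers the failure mode a probability model would guard.
- Degenerate inputs: no long virtual contigs → everything pools into a
  single cluster (logged); empty w-mer summaries are rejected for
  profiles and give length 0; an empty cluster during K-means is
  reseeded with the globally worst-fit profile.
- Outcome categories for a read from genome G at reference level L with
  annotation T: Accurate if T lies on G's lineage at or below the
  rank-L ancestor (an on-lineage annotation *below* L is strictly more
  informative than L, so it is not "Higher" and not "Incorrect");
  Higher if T is a strict ancestor of the rank-L ancestor; Incorrect
  otherwise; Unassigned without annotation.  Binning precision is
  cluster-majority purity over assigned reads; sensitivity is
  genome-majority recovery over all reads, unassigned included in the
  denominator.

## Benchmark sizes

The packaged end-to-end benchmark (`mcta.benchmark.run_benchmark`, also
driven by `scripts/acceptance.py`) uses six 100 kb targets — three with
species-level references, three with order-level — at 10× coverage with
contigs covering 60% of each genome (~40,000 read pairs); one run takes
well under a minute on one CPU.  These sizes keep the full suite quick
while leaving every stage non-trivially exercised; coverage, genome
count and genome length scale up linearly via the same configuration.

## Known limitations

- Read-contig alignment is ungapped; indel-bearing data would need a
  gapped aligner in front.
- The seed-count hit scorer is a surrogate for alignment bitscore; on
  real data, importing BLASTN outfmt-6 hits is the higher-fidelity path.
- Composition clustering can still merge genomes whose signatures
  collide; the merge–split refinement removes the observed initialization
  artifacts but cannot separate genuinely overlapping spectra.
- Reads in clusters without contigs can only be annotated if their
  cluster acquires contigs through binning; a community with very low
  contig coverage degrades toward the unassigned baseline.
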
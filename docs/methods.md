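# Methods

This note documents the models, parameter choices and numerical decisions
behind `tandemscout`, and what the synthetic validation does and does not
demonstrate about real data.

## Scope and assumptions

The pipeline estimates the genomic share of high-copy tandem-repeat
(satellite) families from a low-coverage, single-end short-read survey of an
otherwise unknown genome. Its central assumptions:

- at survey coverage, only high-copy sequence accumulates enough k-mer
  support to assemble, so the assembled contig set is strongly enriched for
  repeats;
- the fraction of reads recruited by a repeat family is an unbiased
  estimator of the fraction of the genome the family occupies (uniform
  read sampling);
- a tandem family is adequately represented by one consensus monomer plus
  the set of contigs homologous to it.

All genomic coordinates anywhere in the package are 0-based, half-open.
Every stage is deterministic given its inputs; all randomness flows from
one integer seed. Every stage is single-threaded, so results are trivially
independent of the `--threads` flag (accepted for interface compatibility).

## Synthetic genomes and reads

`simulate.build_genome` splices blocks into a uniform-random background of
configurable GC: per family, `n_arrays` arrays of `copies_per_array`
head-to-tail monomer copies, each copy independently substituted at
`per_copy_mutation_rate` (emulating intra-family divergence of a satellite);
optionally a dispersed TE-like repeat (one ancestral sequence, diverged
copies scattered individually). Arrays sit on random strands at
non-overlapping loci separated by random background gaps. The truth table
records each family's canonical monomer and planted fraction =
planted reference bases / genome length — deliberately *not* read-sampled
bases, so sampling error is the pipeline's to measure.

`simulate.shotgun_reads` draws `ceil(coverage × G / L)` single-end reads of
length L (default 150) with uniform starts and strands and i.i.d.
substitution errors. Read ids carry (index, start, strand) so sampling
properties are directly testable.

The reference design (`demo_genome_spec`): 1 Mb, GC 0.47, families of 180,
350 and 184 bp monomers at ~10%, 5% and 1% (4, 2 and 1 arrays), 1% per-copy
divergence, plus a 3 kb TE at 10 copies with 5% divergence. The monomer
lengths are those typical of grass knob/centromere satellites; the
fractions span the range observed across grass genomes (over 13% down to
under 1%). Pipeline validation samples this genome with 50,000 error-free
reads (an intentionally generous depth — 7.5X — so that assembly,
detection, recruitment and extraction are all exercised in one run;
coverage is a free parameter of the simulator).

What the simulator does **not** model: indel errors, GC-biased coverage,
quality-score error profiles, higher-order repeat structure, library
artifacts, polyploidy. Passing tests therefore demonstrate correctness of
the algorithmic chain under idealized sampling, not robustness to
platform-specific noise.

## Assembly

A de Bruijn graph over canonical k-mers (k = 31, odd so no k-mer is its own
reverse complement). K-mers below the noise floor (`kmer_noise_threshold`,
default 2 — singletons are treated as errors; the floor scales slowly and
monotonically with total read volume) are removed. Contigs are maximal
non-branching paths subject to a *mutual dominant-edge* rule: from an
oriented k-mer the walk continues through a branch only when the best
extension's count is at least `dominance_ratio` (default 8) times the
combined count of the alternatives, and the reverse walk from the target
agrees. Rationale: each diverged monomer copy hangs a low-count variant
branch on the high-count trunk of a satellite ring; with hundreds of
copies, nearly every trunk node branches, so a strictly conservative
"never extend through a branch" rule shatters exactly the contigs the
pipeline exists to recover. Dominance keeps the conservative behaviour in
balanced (genuinely ambiguous) branches — background forks truncate as
before — while letting a 50-fold-deeper trunk shrug off variants.

Tandem arrays collapse to cycles; every cycle is unrolled to at least three
monomer copies (and to at least the minimum contig length for very short
monomers) so the downstream detector sees multiple copies. Contigs under
`min_contig_length` (default 200 bp) are discarded — this is also what
removes unassembled singleton reads. Contigs are emitted strand-canonically
(lexicographic min of sequence and reverse complement) and sorted, so
assembling the reverse-complemented read set yields byte-identical output.
`n_reads` per contig is estimated as (total k-mer count along the path) /
(k-mers per read).

Known limitation: with few copies (tens) and nonzero divergence, two
variant copies can collide at the same monomer position; the combined
branch count can then defeat dominance and break the ring, leaving a linear
contig of ~1 lap that the detector (needing ≥ 2 copies) rejects. At the
reference design this loses the 1% family in roughly 1 run in 20; at
smaller scales it is the dominant failure mode, which is why low-copy test
fixtures use homogeneous arrays.

## Tandem detection

*Candidate periods.* For probe k-mers (k = 4) the detector histograms the
distances between consecutive recurrences of identical k-mers; a lag d
(≤ max period 2000) is kept when its exact support — positions i whose
k-mer recurs at i + d — reaches `ceil(pm · (n − d − k))` with pm = 0.80.
This deterministic filter replaces a probabilistic k-tuple model: pm is the
target per-base match probability, and at k = 4 a 96%-identity array (2%
per-copy divergence) still clears the filter while uniform-random sequence
essentially never does. The target indel probability pi = 0.10 is carried
in `ScoringParams` but unused (substitution-only scoring). Small multiples
of observed lags (≤ 8×) are also evaluated so composite periods of
low-complexity sequence are not missed; work is capped at 64 base lags.

*Wraparound alignment.* `wraparound_align` computes the best global-in-
sequence alignment against an unbounded cyclic concatenation of the
monomer, free starting phase: row 0 is all zeros, each row update takes the
max of diagonal (cyclic column −1), vertical gap, and horizontal gap terms;
with linear gap cost the within-row closure is a running-max prefix scan,
and a single extra pass propagates wraparound through the last column
(a full circle of gaps can only lose score, so one pass suffices — verified
against an exhaustive DP oracle on thousands of random instances).
Traceback prefers diagonal, then vertical, then horizontal moves
(deterministic). The matrix is int32; scores are exact integers.

*Consensus.* Per-phase majority vote over the period-phased array, ties to
the alphabetically first base, then one refinement: realign the span
against the voted consensus with the wraparound DP and re-vote each monomer
column from the aligned bases (columns with no aligned base keep the voted
base).

*Annotation.* For each candidate period the matching span is located from
the lag-d per-base match profile; spans shorter than two periods are
dropped; score < 50 or period > 2000 is discarded. Overlapping annotations
resolve to the highest score, ties to the smaller period — which also
suppresses perfect multiples of a primitive period — and a contig's
representative repeat is its highest-scoring annotation. Scoring boundary:
since a perfect array scores 2 × length, no array under 25 bases can ever
be annotated.

## Read recruitment

A read hits a contig iff they share a canonical 15-mer seed and an
alignment covering ≥ 80% of the read reaches identity ≥ `min_identity`
(default 0.85). Candidate (read, contig) pairs come from a sorted canonical
k-mer index of the read set (built once and shared across recruitment
passes); verification uses edlib infix alignment of the full read and, for
edge overhangs, of its 80% prefix/suffix, on both strands, with the edit
budget `floor((1 − min_identity) · part_length)` as an early cutoff.
Defaults (15, 0.85) are chosen so a 150 bp read with ~1% divergence from
the family consensus reliably seeds and passes. Multi-mapping policy:
all-hits per contig, single-counting toward the total — the total tandem
fraction is the *union* fraction of reads hitting any tandem contig, which
is the quantity a "proportion of all reads mapping to any tandem contig"
summary reports, while per-contig counts drive the ranking.

## Family extraction

Greedy seed-and-remove over the tandem contig pool, 4 iterations by
default (family abundance is typically negligible beyond the 4th):

1. rank remaining contigs by recruited reads (ties: longer contig, then
   id); contigs whose representative monomer is < 30 bp cannot seed a
   family (they may still join one as members);
2. the top contig's consensus monomer, doubled to expose rotations, is
   searched against every pooled contig with seeded (word 16) ungapped
   X-drop local alignment at +1/−2; a contig joins the family when its best
   segment score S satisfies E = K·m·n·exp(−λS) ≤ 0.1, with λ solved from
   the score moments at equal base frequencies (λ ≈ 1.33), K = 0.621 (the
   standard ungapped constant for +1/−2), m the doubled-seed length and n
   the total pooled contig length;
3. the family (seed + members) is removed from the pool; early exhaustion
   of the pool is logged, not an error.

Word size 16 (rather than a classic 11) is deliberate: against the small
contig pools of a desk-scale run, an 11-base seed admits on the order of
0.1 expected chance merges per search at E ≤ 0.1, enough to occasionally
fuse unrelated families; 16 removes chance seeding while losing nothing on
genuine members, which are near-identical to the consensus.

Composition: each family's genomic fraction is re-estimated by recruiting
the full read set against a reference of the seed monomer (doubled — the
monomer is a cyclic unit, so 150 bp reads sample every rotation) plus all
member contigs. Mapping against monomer+polymers versus the monomer alone
agrees within binomial noise on simulated data, so reference fragment
length does not bias the estimate. Families are disjoint over contigs but
not over reads; a boundary read recruited by two families counts in both,
bounded in tests by 3 binomial SD on the family-fraction sum.

`classify_top_repeat` reuses the homology machinery to report, for a family
seed, the best-matching entry of a user-supplied known-repeat library
(lowest E ≤ 0.1, with the monomer length difference), or none.

## Reporting

Composition tables carry full-precision fractions plus percentages
(2 decimal places in text output). The genome-size correlation is a
standard Pearson product-moment r with a two-sided t-based p, pairs matched
by taxon name and unmatched taxa dropped with a warning (≥ 3 pairs
required); a 16-taxon grass genome-size table (pg/1C) ships with the
package. Self dot-plots mark (i, j) when the length-`window` windows at i
and j match at ≥ `min_identity` on either strand (symmetric, main diagonal
always present); tandem periodicity appears as off-diagonal bands at the
period spacing. Plot images are optional artifacts behind `--plots`; the
tables are the contract.

## Validation design and problem sizes

The test suite validates each stage against independent oracles: exhaustive
DP for the wraparound aligner; string reconstruction for the assembler;
brute-force support counts for the period filter; the closed-form
product-moment formula for the correlation; and, end to end, the
simulator's truth tables. The end-to-end design uses twenty seeded runs of
the reference genome (1 Mb, 50,000 reads) for recovery/unbiasedness checks
and twenty repeat-free runs as negative controls; `scripts/acceptance.py`
reports the same quantities over ten seeds derived from its `--seed`.
These sizes were chosen to make binomial error bars a few times smaller
than the smallest planted effect while keeping a full validation run in
minutes on one CPU.

## Known limitations

- Ring breaks at low copy number × nonzero divergence (see Assembly): the
  smallest-fraction family is occasionally lost whole; estimates for
  recovered families are unaffected.
- No indel error model and no gapped homology search; strongly
  length-polymorphic satellites would be under-grouped.
- Nested or overlapping tandem annotations are resolved to a single
  representative per region; higher-order repeat structure is out of scope.
- The abundance estimator inherits the uniform-sampling assumption; real
  library GC bias would propagate directly into family fractions.
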
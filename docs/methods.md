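# Methods

## The problem

Double-digest RAD sequencing reduces a genome to the set of restriction
fragments cut by two enzymes and falling inside a size-selection
window. Because both fragment ends are enzyme-defined, every individual
sequences the *same* fixed-length loci, and paired 100 bp reads cover
the two fragment ends at uniform depth. The computational task is to
build a reference contig per locus de novo — without a genome — and to
reduce raw variant calls to the subset informative at population scale.
radloci implements those stages natively, plus a simulator that
generates libraries with known truth so the stages can be verified.

## Trimming

Adapter read-through is clipped by scanning every 3′-anchored alignment
of a read suffix against an adapter prefix (minimum overlap 3) and
removing the best one whose mismatch fraction is ≤ the error rate
(default 0.1); "best" means most matching bases, longest on ties. The
default adapter is the Illumina TruSeq common stem `AGATCGGAAGAGC`,
configurable because adapter kits vary. Quality trimming uses the BWA
partial-sum rule at PHRED 10: cut at the position maximizing
Σ(threshold − q) over the trimmed suffix, never touching the 5′ end.
One pass of the two trims composed is not idempotent — a quality cut
can expose a chance 3-mer that looks like the adapter start — so
`trim_read` iterates both to a fixpoint; each pass strictly shortens
the read, so this terminates, and trimming an already-trimmed read is
then exactly a no-op. Pairs are dropped jointly when either mate falls
below 20 bp so files never contain orphans.

Reduction and assembly intentionally consume *untrimmed* reads: exact
composite matching needs equal-length sequences, and the consensus step
absorbs low-quality tails. Trimmed reads are written for the (external)
mapping stage.

## Reduction and the coverage cutoff

Each pair becomes the composite `forward ++ revcomp(reverse)`; the
split point is stored per entry so mixed-length input fails loudly
rather than mis-splitting. Exact counts of unique composites over all
individuals pooled are summarized as a cumulative curve: value *k* is
the number of unique composites occurring ≥ k times (k = 1..50,
occurrences above 50 displayed in the last bin). The user-chosen cutoff
*K* keeps composites seen ≥ K times. There is no universally right K —
it should sit past the steep error/singleton drop of the curve but
below the per-allele expected coverage. The acceptance runs use K = 50
for the clean library (10 individuals × 20 pairs, every locus
monomorphic, so a locus's composite count is ~200) and K = 4 for the
polymorphic/erroneous library (an error-free composite of even a
rare allele at frequency ≥ 0.05 is still expected ≥ ~3–4 times, while
recurring identical errors are vanishingly rare).

## Assembly

**Forward clustering.** Unique pairs are processed in descending
abundance (ties lexicographic); a pair joins the first cluster whose
*seed* (founding forward read) is within 6 Hamming mismatches of its
forward read, else founds a new cluster. Six mismatches (rather than a
more usual four) tolerates the divergence of species with large
effective population sizes. This greedy seeded scheme is deliberately
simple and totally ordered — bit-identical output for any input order.

**Allele division.** Within a cluster, the reverse-read column whose
second-most-common base (abundance-weighted) is largest drives a split
when that minor count is ≥ 2 *and* ≥ 20% of the cluster; parts recurse.
The two thresholds suppress singleton sequencing errors while
separating genuine alleles; both are exposed in `AssemblyConfig`. Ties
between columns go to the leftmost.

**Consensus and contig choice.** Each allele subcluster yields
column-wise abundance-weighted majority consensuses (ties to the
alphabetically first base). Each candidate contig is built and the
longest represents the cluster (ties: more abundant subcluster, then
division order) — one contig per locus, so heterozygosity does not
inflate the reference.

**Contig construction.** The reverse consensus is reverse-complemented
so contigs read along the sequenced top strand, then merged with the
forward consensus: an exact suffix/prefix overlap ≥ 10 bp joins them
directly; otherwise ten `N` characters are inserted to mark the
unsequenced fragment middle. With 350–400 bp fragments and 100 bp
reads the ends essentially never overlap, so padded contigs are the
norm (2 × 100 + 10 = 210 bp). Exact-match overlap detection replaces
an aligner here because the branch is rare by design.

**Final identity clustering.** Contigs are sorted longest-first (ties
lexicographic) and greedily absorbed by the first representative with
identity ≥ 0.90, where identity = (maximum number of matching aligned
positions under a global alignment scoring match 1 and everything else
0) ÷ (shorter sequence length). That maximum equals the longest common
subsequence, computed by a vectorized dynamic program; the test suite
cross-checks it against an independent pairwise-alignment
implementation. Random 210 bp sequences score ≈ 0.65 under this
measure, comfortably below the 0.90 threshold, while alleles of one
locus score ≈ 0.99.

## Variant filtering and metrics

"Called in X% of individuals" means a non-missing genotype; the site
QUAL field (not per-genotype quality) carries the quality threshold —
the semantics of VCFtools' `--max-missing`/`--minQ`. All thresholds
are inclusive: call rate exactly 0.90, QUAL exactly 30 and MAC exactly
5 survive. MAC is the copy count of the second-most-frequent allele
over called allele copies (two per diploid genotype), which handles
multi-allelic sites without special-casing. The metric table counts a
SNP toward cell (d, p) when ≥ p of individuals hold a non-missing
genotype with DP ≥ d; indels and complex records never enter the
table (the published comparisons decomposed complex calls with an
external tool first). A called genotype lacking DP counts below every
depth threshold, with a warning. When the bottom 10% of individuals by
mean depth are dropped before metrics, ranking ties break by sample
name; the count removed is ⌈0.10 · n⌉.

## The simulator

What it emulates: EcoRI (G^AATTC) + MspI (C^CGG) double digest on an
i.i.d. random genome (GC 0.5), retention of only fragments flanked by
one cut of each enzyme (ddRAD adapter chemistry: barcoded adapter on
EcoRI, generic on MspI — A–A and B–B fragments do not amplify),
inclusive 350–400 bp size selection, per-locus segregating SNPs and
1–5 bp indels at per-base rates with allele frequencies uniform on
(0.05, 0.95), diploid individuals via independent Bernoulli haplotype
draws, Poisson pair counts per individual per locus, and i.i.d.
substitution errors with a two-level quality model (37 correct /
8 erroneous) that gives the trimmer a clean signal. One seeded NumPy
generator drives everything; a fixed seed reproduces the library
exactly.

Defaults are the targeted study conditions: 2 populations × 20
individuals, 100 bp reads, mean 20 pairs per locus per individual,
error 0.005, SNP rate 0.005/bp, indel rate 0.0005/bp. The default
2 Mb genome yields ~35–60 loci — large enough for stable percentages,
small enough that the full pipeline runs in seconds. "Rate per locus"
parameters are interpreted per base (the usual θ-like convention);
a per-locus fraction in [0, 1) could not express high polymorphism.

Not modeled, hence what passing tests do *not* show: restriction-site
polymorphism (allele dropout), PCR duplicates, paralogous loci that
co-cluster, indexed-adapter hopping, and realistic quality-score
profiles. Real libraries will have ragged coverage across individuals
and loci that these simulations do not produce; the recovery
percentages measured here are upper bounds on real-data behavior.

## Numerical and design choices

- PHRED+33 is assumed for FASTQ input; other encodings are not
  auto-detected. Quality values outside [0, 93] are rejected.
- Gzip is detected from magic bytes, never the file extension.
- Internal coordinates are 0-based half-open; VCF positions convert at
  the I/O boundary only. VCF I/O goes through htslib (pysam), FASTQ
  and FASTA through Biopython.
- Exactly one underscore is allowed in sample stems (`POP_IND`); more
  is an error, not a guess.
- Every tie-break in reduction and assembly (abundance, lexicographic,
  leftmost column, first matching representative) is a total order, so
  all outputs are reproducible bit for bit.
- The reverse consensus is reverse-complemented before contig
  construction so that references read along the sequenced strand;
  this also makes comparison against simulated truth well-defined.
- The pipeline accepts an externally produced VCF for the filter and
  evaluation stages; it never invokes mappers or callers.

## Problem sizes used in the checks

The end-to-end checks simulate 2 Mb genomes with 10 individuals
(~35–60 loci, ~8–9 k read pairs), which exercises every stage in a few
seconds; operation-level checks compare against brute-force
recomputations on ≥ 1000 random small instances each. These sizes were
chosen to make the whole suite quick to run anywhere while keeping
locus counts high enough that recovery percentages are meaningful.
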
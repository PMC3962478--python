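# Methods

## The problem

Whole-genome bisulfite sequencing (WGBS) reads the methylation state of
individual cytosines: bisulfite deaminates unmethylated C to U (sequenced
as T), while 5-methyl-C resists conversion and is sequenced as C. Because
conversion is imperfect, an unmethylated cytosine still shows C in a read
with small probability, so calling a site "methylated" is a statistical
decision, not a lookup. `methylcall` implements that decision pipeline for
sparse, gene-body-dominated invertebrate methylomes (the hymenopteran
regime, where well under 1% of CpGs are methylated and methylation
concentrates in exons), together with a read simulator that provides ground
truth for every stage.

## Model

For a cytosine with `n` informative reads of which `k` remained C, the
null hypothesis is that the site is unmethylated and every C is a
conversion failure:

    k | n  ~  Binomial(n, p_e),     p_e = 1 - c

where `c` is the bisulfite conversion rate. The one-sided exact tail
`P(X >= k)` is the per-site p-value (computed by `scipy.stats.binom.sf`;
no normal approximation). Sites are tested only inside the coverage window
[2, 30]: singleton coverage carries almost no evidence, and very high
coverage flags collapsed repeats or mapping artifacts. The family for
multiple-testing correction is the set of coverage-eligible sites, and the
default correction is Benjamini–Hochberg step-up at FDR 0.05 (Holm and
Bonferroni are selectable). A site is called methylated when its adjusted
value is at or below the FDR level. The per-site methylation *level*
`k / n` is reported separately from the binary call.

`c` is estimated two ways, and both are always logged:

* **Spike-in**: pooled `sum(T) / sum(coverage)` over every covered cytosine
  of an unmethylated spike-in contig (the lambda-phage control added before
  conversion). No coverage window is applied — the control pools raw
  tallies.
* **Non-CpG**: the same pooled ratio over CHG + CHH sites of the target
  genome, exploiting that non-CpG methylation is negligible in this clade.
  UNCLASSIFIED sites are excluded.

The spike-in estimate parameterises the null when available, the non-CpG
estimate otherwise; which one fed the test is configuration, not hard-coded.
The degenerate case `p_e = 0` is defined as p-value 0 for `k >= 1` and 1
for `k = 0`.

## Base counting

A read informs only cytosines on its strand of bisulfite origin. A read
base enters the tally iff its Phred quality is >= 20 and every existing
read base within three positions on each side matches the reference in
bisulfite space (T over a reference C of the read's strand is a match)
with quality >= 15. The window size and both thresholds are configurable;
"three neighbors per side, all must pass" is our reading of the
neighborhood rule — "three total adjacent" is expressible by setting the
window accordingly. Bases other than C/T at a cytosine are discarded
entirely rather than counted as coverage, since the statistic only
contrasts converted with unconverted reads.

Context is classified from the two bases 3' of the cytosine on its own
strand: CG, CHG, CHH (H = A, T or C), and UNCLASSIFIED when the window
crosses the contig end or an ambiguous base. The UNCLASSIFIED-on-edge/N
mechanism is a design choice: it is the only rule consistent with a small
residual unclassified class in a finished genome, and it guarantees the
four contexts exactly partition the cytosine census.

## Annotation

Positions are classified exon > intron > intergenic: exonic in *any*
transcript wins over intronic in an overlapping isoform, so the three
classes exactly partition the genome with no ambiguous class. The ranking
unit for gene-body methylation is the transcript; its "length" is the
genomic span including introns, which is what lets the intronic share of a
transcript's methylated sites be reported for the same ranked entity
(single-exon transcripts report NA). Methylated sites on either strand and
in any context count toward a transcript regardless of the transcript's own
strand — CpG methylation is overwhelmingly double-stranded in this regime,
and strand-restricting would halve counts arbitrarily. Symmetric CpG pairs
are (plus-strand C at i, minus-strand C at i+1); a "both-strand methylated"
CpG contributes two sites. Region summaries are computed in two scopes —
CG-context calls only, and all significant calls — because published
context and region tallies need not agree on scope; both files are written.

## Simulator

The generator emulates a WGBS experiment on a small genome:

* **Genome**: first-order Markov sequence with stationary GC fraction
  (default 0.42, a typical insect value) and a CpG dinucleotide frequency
  targeting `(gc/2)^2 * cpg_enrichment` (default enrichment 1.0). A
  spike-in contig (default 20 kb, GC 0.5) is appended under a reserved name;
  it is distinguished by name, not sequence.
* **Gene models**: `n_genes` non-overlapping single-isoform genes per
  contig, exon counts and exon/intron lengths drawn from configured ranges,
  random strand, never on the spike-in.
* **True methylome**: every CpG cytosine is methylated as a Bernoulli draw
  with its region-class probability (defaults: exon 0.04, intron 0.004,
  intergenic 0.002 — the exon-biased, sparse regime); the two strands of a
  CpG share their state with probability `cpg_symmetry` (default 1.0, since
  both-strand methylation is the dominant observed pattern and asymmetry
  remains configurable). Non-CpG cytosines use `non_cpg_meth` (default 0).
  Spike-in cytosines are always 0.
* **Reads**: read starts are Poisson per position per strand at rate
  `mean_depth / read_length`, so per-site strand coverage is
  Poisson(`mean_depth`) (default 8, matching the study regime) — the
  simplest model with realistically dispersed coverage. Within a read, a
  cytosine of the origin strand reads C with probability
  `state * meth_level + (1 - state) * (1 - conversion_rate)`
  (defaults: `meth_level` 1.0, `conversion_rate` 0.9928), else T; other
  bases are copied, with an optional independent error rate (default 0).
  Phred qualities come from a two-component profile: ~Q35 body with a ~Q10
  tail at 2% (a post-cleaning HiSeq-like profile; the tail exists to
  exercise the quality filter without dominating the tally — at a 2% tail
  the post-filter median coverage at depth 8 is about 7).
* **Reads carry their true origin** (contig, start, strand) in the FASTQ
  header; no aligner is implemented or needed, so mapping error is out of
  scope by construction.

Determinism: all stages draw from `numpy` generators seeded as
`[config.seed, stage]`, so one (config, seed) pair reproduces the genome,
methylome and read stream byte-for-byte.

What the simulator does **not** model — and hence what passing tests do not
show about real data: methylated-fragment enrichment (the study's capture
step selects for methylated DNA, biasing global methylated fractions
upward; comparisons of *global* rates against enriched libraries are not
meaningful), paired-end structure, mapping ambiguity or error, PCR
duplicates, sonication/size selection, and sequence-composition-dependent
coverage bias.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulator at desk scale:
40–60 kb genomes with 12–20 genes for end-to-end checks, a 30 kb spike-in
(>= 1e5 cytosine observations) for conversion-rate recovery, and 20 000
synthetic count rows per replicate (20 replicates) for FDR and power
checks. These sizes give 3-sigma binomial margins on every stochastic
assertion while the whole suite completes in about two minutes.

Rounding in reports is half-away-from-zero at the printed precision
(context shares and per-region percentages to 3 significant figures, region
shares of all mCG to 2 decimals, transcript proportions to 5 decimals).
Ranking ties break by the secondary key descending, then transcript id
ascending, so rankings are invariant to input order. Exact binomial tails
are validated against exact rational-arithmetic enumeration to 1e-12 for
all n <= 30 (the only n the coverage window admits); the BH adjustment is
statsmodels' implementation, validated against the textbook step-up
definition on random vectors.

## Known limitations

* Counts ingestion accepts the TSV dialect only; SAM/BAM alignment parsing
  is a documented adapter point, not implemented.
* "Uniquely mapped" filtering is delegated to the simulator's truth; an
  external counts file is assumed already filtered.
* No differential methylation, no beta-binomial overdispersion, no
  per-read epiallele analysis; one sample at a time.
* Transcript proportion counts strand-distinct sites by default; a
  `collapse_cpg` flag folds the two strands of a CpG into one unit when a
  dinucleotide-level count is wanted.
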
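# Methods

This note documents the models behind `nemasrna`, the defaults and why
they were chosen, and what the synthetic data do and do not establish
about real libraries.

## Read cleaning

Reads follow the dual-4N small-RNA layout: 4 random bases + insert +
4 random bases + 3′ adapter. Trimming truncates at the *leftmost*
adapter match; a match is the full adapter anywhere, or a 3′-terminal
adapter prefix of ≥3 bases, in both cases allowing mismatches up to 10%
of the matched region (`adapter_max_error_rate`, a cutadapt-like
default — the match stringency is our choice, not a protocol constant).
Reads without any adapter match are rejected: for inserts shorter than
the read the adapter must be present, and without it the insert
boundary cannot be confirmed. The post-trim window is 26–38 nt
(18–30 nt insert + 8 random bases), after which 4 bases
(`flank_trim`) are stripped from each end. Both 4N-style kits used in
practice share the 8-random-base arithmetic, so a single layout is
implemented.

## Alignment

The policy is classic small-RNA alignment: ungapped, at most one
substitution (`max_mismatches = 1`), best stratum only (0-mismatch
placements suppress 1-mismatch ones), and exactly one reported
placement drawn uniformly from the best stratum, with a multimapper
flag when the stratum has >1 member. The random report-one choice is
keyed on (pipeline seed, insert sequence), so it is reproducible and
independent of read order. Multimappers are retained and counted once
at the reported position by default (`keep_multimappers`), with a
switch to drop them; no indels, no quality-aware scoring.

Candidates are found with an exact k-mer index and a pigeonhole split:
a placement with ≤1 mismatch has at least one mismatch-free half, and
each half (≥9 nt for 18-nt inserts) is discovered through its leading
k-mer. The index seed length defaults to **k = 9** because the search
is exhaustive only when k is at most half the shortest insert; longer
seeds (e.g. 18 nt) would overlap for 18–30 nt inserts and a mismatch in
the overlap could escape both, silently losing alignments. The tests
confirm exhaustiveness against a full sliding-window scan. The toy
aligner is meant for desk-scale genomes (tens to hundreds of kb);
real libraries enter via SAM, which is mapped onto the same
`AlignedRead` contract (FLAG 0x10 → strand, NM → mismatch count,
recomputed from the genome when absent).

## Classification

Reads are assigned to classes by length, 5′ nucleotide (in sequencing
orientation), strand relative to the feature, and feature biotype
(criteria listed in the README). Decisions the rule text leaves open:

* **Hierarchy** structural > miRNA > 21U > 22G/26G. Removing
  structural contaminants first is standard small-RNA practice; the
  remaining rules are mutually exclusive by biotype in a
  non-overlapping annotation, so the order only matters at planted
  overlaps.
* **Overlap** requires ≥1 shared exonic base (featureCounts-like);
  intronic overlap does not count.
* **Ties** within a rule go to the largest overlap, then lexicographic
  feature id — deterministic and order-independent.
* **26G over transposons** is admitted by default (the 22/26 rules are
  stated jointly); `allow_26g_transposons=False` restricts 26G calls to
  genic exons.

Count tables hold one increment per classified read in exactly one
(feature, class, sample) cell; unclassified reads are tallied
separately so column sums + unclassified always reconstruct the input.
Transposon copies can be aggregated by family label.

## Normalization and differential calls

Size factors are plain median-of-ratios: features with a zero in any
sample are excluded from the median (their geometric mean is zero).
The differential test is a deliberately simple two-condition
negative-binomial Wald test on normalized counts:

* per-feature dispersion by method of moments,
  α̂ = (pooled within-condition variance − pooled mean) / pooled mean²;
* the raw α̂ from a handful of replicates is far too noisy on its own,
  so, as in the standard small-sample DE tools, each estimate is
  squeezed toward the across-gene median with `dispersion_prior_df`
  (default 20) pseudo-degrees of freedom, and the Wald statistic is
  referred to a Student t with residual + prior df. With the default
  settings this puts the empirical null type-I error at ~0.05 for a
  nominal p < 0.05 (measured over 10 × 500-gene null simulations);
* log2FC = log2((μ̂_mut + ½)/(μ̂_wt + ½)); the ½ pseudocount stabilizes
  zeros, and the threshold is applied to this unshrunk estimate;
* delta-method standard error with Var(mean) = (μ + αμ²)/n per
  condition; identical counts give log2FC = 0 and p = 1;
* Benjamini–Hochberg step-up for FDR; calls are `up`/`down` at
  q ≤ `fdr_level` (0.10) **and** |log2FC| ≥ log2(`fc_cutoff`) (2-fold),
  both inclusive at the boundary.

No GLM covariates, no outlier filtering, no fold-change shrinkage: the
scheme that matters downstream is the normalization and the
2-fold/10%-FDR thresholding, and calibration is established by
simulation rather than by equivalence to any particular GLM
implementation. Coverage tracks divide per-base read coverage by the
sample's size factor and are emitted as run-length-merged bedGraph
(zero runs omitted).

## Metagene profiles and the 5′ shift

The gene model for binning is the concatenated-exon transcript,
oriented 5′→3′ by strand. Bin b of B covers the half-open slice
[⌊(b−1)L/B⌋, ⌊bL/B⌋) and takes the *mean* per-base coverage of its
slice (the scale-regions convention), which matters when L is not a
multiple of B; genes shorter than B bases get zero-valued empty bins.
The relative profile keeps rows with sum strictly greater than 10,
row-normalizes, and column-sums, so each kept gene contributes weight
exactly 1; the total profile column-sums without filtering and divides
by the size factor, so it is dominated by strongly covered genes. The
centroid Σ b·v_b / Σ v_b is this package's scalar summary of a profile
— the underlying analysis presents the curves themselves — and the
shift statistic centroid(mutant) − centroid(wild type) is negative
when coverage moves 5′. For a Beta(a, b) 5′-end law the expected
centroid is ≈ 100·a/(a+b) + 0.5 bins, displaced slightly toward 5′ by
half a read length because coverage extends from the 5′ end of each
antisense read toward the TSS; with ≥1 kb genes this is within a bin
or two. Transposon spans are treated as single exons.

## Simulator

The generator is the package's ground truth. A toy genome is i.i.d.
nucleotides at a set GC fraction (0.36, the worm-like default). Toy
features are non-overlapping by default (gap ≥ `min_gap`), single-exon
by default (so gene-body and exon-concatenated coordinates coincide;
multi-exon placement is available), with per-biotype length ranges
loosely modeled on the real size classes (21-nt piRNA loci, 22-nt
mature miRNAs, ~0.8–2.4 kb coding genes). An overlap fixture plants a
transposon inside a gene to exercise tie-breaking.

Reads encode their class: 21U → 21 nt forced 5′ T, sense over a piRNA
locus; 22G/26G → 22/26 nt forced 5′ G, antisense, with the 5′ end at a
transcript fraction drawn Beta(a, b) per gene and condition (resampled
when the read would overrun the transcript, capped); miRNA → 21–24 nt
sense from the locus start; structural → 18–30 nt sense. The forced 5′
base replaces the genomic base and is recorded as the read's single
allowed mismatch, so the reads remain alignable under the ≤1-mismatch
policy. Per-replicate counts are negative-binomial with dispersion
0.05 by default (0 gives Poisson); the count substream is keyed on
(seed, replicate, feature) but not condition, so a null fold change
yields literally identical counts in both conditions and any
difference between conditions is the one the truth encodes. Expected
counts across loci follow log-normal weights (the abundance law across
real loci is not asserted; it is configuration). Raw-layout reads are
4 random bases + insert + 4 random bases + adapter, quality "I".

What the simulator does *not* model: sequencing errors beyond the
forced substitution, quality values, PCR duplicates/UMI collisions,
isomiRs, genome repeats at realistic density, and multi-locus 22G
biogenesis coupling. Passing tests therefore demonstrate the
correctness and calibration of the *computations* under clean,
overdispersed count noise — not robustness to artifacts of real
libraries.

## Problem sizes

The test and acceptance workloads are sized for a desk run: 50 kb
genomes for oracle comparisons (10,000 classified reads, 2,000 aligned
inserts), 500-gene × 8-sample matrices over 10 seeds for calibration,
200 genes × ~100 reads for 5′-shift recovery, and a 300 kb,
~140-feature, 2×3-sample study of ~60,000 raw reads end to end. These
sizes give the Monte-Carlo checks comfortable statistical margins
while keeping the full suite at about half a minute.

## Conservation scoring

RBH scores consume 12-column tabular BLASTP files; BLAST itself is not
run. Duplicate (query, subject) lines keep the maximal bit score, best
hits break ties lexicographically (deterministic; the underlying
procedure does not specify), and scores are not clipped at 1 — a
reverse bit score exceeding the self score is reported as is and
flagged in the long-format output. The self bit score may be supplied
directly or extracted from a self-proteome search file.
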
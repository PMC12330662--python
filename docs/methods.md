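# Methods

`nanosplice` implements an analysis of alternative splicing from barcoded
long-read (nanopore-style) cDNA sequencing: sample demultiplexing, gene
assignment, per-base percent-spliced-in (%SI) quantification, segmentation
of genes into regions of homogeneous splicing, and a negative-binomial
likelihood-ratio test for differential splice-isoform abundance between
conditions. A synthetic-data generator reproduces the statistical structure
the analysis assumes, so every stage is verifiable end to end without
external sequencing data.

## Coordinates and containers

All genomic coordinates are 0-based, half-open internally; SAM and GTF
emission converts to 1-based at the file boundary only. Alignments use SAM
CIGAR semantics throughout (M/=/X aligned, I insertion, D deletion, N intron
skip, S soft clip). Negative-strand genes are simulated, but alignments are
always recorded in reference (forward-strand) orientation, matching SAM.

## Synthetic data generator

The generator emulates a barcoded oligo-dT experiment with two conditions in
biological triplicate. Each gene receives 4–6 exons (120–350 bp) separated
by introns of 60–200 bp — all introns at least 20 bp, so segmentation
boundaries are detectable under the 10-bp CIGAR merge rule — and exactly two
isoforms: fully spliced, and one retaining a single *middle* intron. The
middle-intron choice is deliberate: the %SI pileup discards each read's
first and last CIGAR runs, so retention is only measurable for introns
flanked by constitutive splice junctions; an isoform retaining a terminal
intron would be invisible to the method by construction.

Per (gene, condition, replicate), read counts are Poisson with mean 300 by
default; each read draws its isoform from the condition's mixing
proportions (the per-gene retention probability), a 5'-truncation point
(fraction of transcript retained from the 3' end ~ Uniform(0.5, 1),
reflecting oligo-dT priming anchoring the 3' end), an orientation
(P(forward) = 0.5), and a poly-T tract length (Uniform{12..25}).

Raw reads follow the layout
`[barcode][poly-T][revcomp(cDNA)][revcomp(common primer)]`, or its reverse
complement. Sequencing errors are substitutions at 2% per base by default
(indel rate configurable, default 0, so demultiplexing mismatch counts are
predictable; the matcher itself still uses edit distance). The 24 default
barcodes are 16 nt with pairwise *infix* edit distance ≥ 7 in both
directions, so no two barcodes can simultaneously fall within the 3-edit
matching tolerance — cross-sample misassignment is impossible by
construction unless four or more errors land inside one barcode.

Alignments are constructed directly from the truth table (clean cDNA), a
stand-in for a spliced aligner: substitution errors would appear inside M
runs anyway (the pileup counts mismatched bases as present), and small
indels would be absorbed by the 10-bp merge rule. A configurable fraction
of reads (default 2%) is emitted with a short, heavily soft-clipped
alignment to emulate the short, spurious alignments the aligned-fraction
filter exists to remove.

What the generator does *not* model: homopolymer-specific basecalling error
profiles, chimeric reads, PCR duplicates, expression-dependent coverage
biases, or genes with more than one alternative isoform. Passing tests
therefore demonstrate correctness of the pipeline's rules and statistics,
not robustness to every artefact of real nanopore data.

## Demultiplexing

Anchored search: the poly-T tract is the longest window (≤ 60 bp) of at
least 10 bases with ≥ 90% T, shrunk to T boundaries, scanned on both the
read and its reverse complement; the common primer (CP) is located by
semi-global (infix) edit-distance alignment on both strands, accepted at
distance ≤ 3. Anchor geometry decides orientation; conflicting anchors
exclude the read.

The barcode is searched in a window of barcode length + 8 bases immediately
5' of the poly-T start, extended 4 bases past the poly-T start so a
barcode whose T-rich suffix was swallowed by the poly-T window still
matches; failing that, a window at the CP-distal end of the read is used. A
barcode matches at infix edit distance ≤ 3 (Levenshtein rather than
Hamming, since nanopore errors include indels). Exactly one match ⇒
assigned; zero ⇒ none_found; two or more, including distance ties ⇒
multiple_found (conservative exclusion). Trimming removes barcode, poly-T
and CP loci and returns the insert reverse-complemented into transcript
sense.

The poly-T run-length threshold (10), window T-fraction (90%), and search
window geometry are package choices, fixed before any tuning; the 3-edit
tolerance is the analysis's reported value.

## Gene assignment and counts

An alignment's reference footprint (N runs included, since the comparison
is against annotation span, not exonic content) is scored against every
overlapping annotation as `overlap / max(annotation length, footprint
length)`; the maximiser wins. Ties break by larger overlap, then
lexicographic gene id, and are logged. Strand is ignored (cDNA reads align
to either strand). Only primary alignments are read from SAM/BAM. Gene
counts feed an external differential-expression engine; this package owns
only the count table and the reported significance filter (BH-adjusted
value ≤ 0.05 and |log2 fold-change| ≥ 0.5).

## %SI pileup

CIGAR cleaning: insertions and clips are dropped (no reference footprint);
M/=/X map to *present*, N/D to *absent*; runs shorter than 10 bases are
combined with the preceding run, adopting its class — so small deletions do
not masquerade as splicing — and same-class neighbours coalesce. A leading
short run has no predecessor and folds into the following run (the merge
rule is otherwise defined backwards only; this is the one place the package
had to choose).

Reads are kept only when *more than* 80% of their bases are aligned
(strict at the boundary; denominator is read length including soft clips).
Each read's first and last cleaned runs contribute to neither counter,
suppressing 5'/3' end-alignment noise; interior present runs increment
spliced-in and spanning, interior absent runs increment spanning only. A
read with fewer than three cleaned runs contributes nothing.

A consequence worth knowing: a 5'-truncated read that starts downstream of
a retained intron's upstream junction carries that intron inside its first
(terminal, discarded) run, so heavy truncation deflates intronic %SI. The
region-level *difference* between conditions is affected symmetrically, so
the differential test is insensitive to this, but absolute %SI under heavy
truncation underestimates retention.

## Segmentation

Replicate pileups of all samples under analysis are combined by summing
counts (summing, not averaging fractions, weights positions by evidence).
Positions are masked when any sample's spanning coverage is below 5 or any
condition's replicate-mean coverage is below 20 (the mean rule is applied
within each condition, the stricter of the available readings). The scan
maintains the cumulative mean %SI since the current region's start and
closes the region whenever a position deviates from that mean by more than
0.1; the cumulative mean restarts at each region start (the only reading
under which a long gene yields multiple clean regions). Masked positions
are skipped without closing the region and are excluded from summaries.

Regions with all-condition pooled %SI below 0.05 are dropped. Each
surviving region is summarised per sample by the mean spliced-in and
spanning counts over its unmasked positions, rounded half-to-even
(bit-reproducible; numpy's default).

## Differential splicing

Per (region, condition), replicate counts k_i with totals n_i follow
NB(mean = p·n_i, dispersion φ), variance μ + φμ²; (p, φ) minimise the
summed negative log likelihood by bounded Nelder–Mead from p₀ = Σk/Σn,
φ₀ = 1, with p ∈ [10⁻⁶, 1] and φ ∈ [10⁻³, 10³]. With three replicates φ is
weakly identified; hitting a φ bound is flagged but does not invalidate the
fit. The choice of a shared φ estimated jointly with p, and of refitting a
single (p, φ) in the joint model, are package defaults — the analysis is
defined only up to "a negative binomial distribution".

The test statistic is λ = L_joint / (L_A·L_B). The joint model is nested,
so λ ≤ 1; numerical overshoot is clipped. When both conditions carry
identical replicate data the joint objective is exactly twice the
per-condition objective at every parameter value, so λ = 1 is returned by
identity (the per-term likelihoods are summed with exact `fsum` so this
holds to the last bit). λ is treated as the significance value itself and
BH-adjusted across all tested regions transcriptome-wide; an optional
calibrated mode maps −2·log λ through a χ²(1 df) survival function and is
off by default. Note that the joint fit can absorb part of a
between-condition difference into its dispersion, which makes λ
conservative for very large effects — ordering by λ is unaffected.

## Targeted fractions

The intron-spanning splicing fraction counts a read as *spanning* when its
footprint covers the intron plus a 10-bp flank on each side, and as
*lacking* the intron when an absent run of its cleaned CIGAR covers at
least 90% of the interval (exact splice-site matching is brittle to
nanopore splice-site wobble; both tolerances are declared package
defaults). The standard error is the binomial delta-method formula on the
logit scale, √(1/k + 1/(n−k)), with a +0.5 continuity correction (flagged)
when k ∈ {0, n}; the reported interval is ±2 SE back-transformed, hence
always inside [0, 1].

The gel-band fraction is (s + h/2)/(u + s + h) for unspliced, spliced and
hybrid-dimer band intensities; intensities are numeric inputs
(densitometry is out of scope).

## Problem sizes and determinism

The verification suite uses desk-scale simulations chosen to make the
binomial/NB error bars decisive: ~10,000 reads for demultiplexing accuracy,
4 genes × 6 samples of full-length error-free reads for boundary recovery,
200 Monte-Carlo repeats per retention level for estimator bias, and a
20-gene × 6-sample experiment (~18,000 reads) for end-to-end detection.
All randomness flows from explicit seeds; rerunning any stage with the same
seed and configuration reproduces byte-identical outputs, which the run
manifest verifies by SHA-256.

## Known limitations

- Retention of first/last introns is structurally unobservable (terminal-run
  trimming); the generator only places retained introns mid-gene.
- Absolute %SI is biased downward under heavy 5'-truncation (see above).
- λ is conservative for large effects because the joint NB can inflate its
  dispersion; the optional χ² calibration does not remove this.
- The segmentation scan is order-dependent (left to right) by definition;
  it is not a changepoint-detection method and is deliberately kept as
  specified rather than upgraded.
- No UMI handling, quality-aware matching, transcript-level quantification,
  or multi-condition (>2) omnibus test.
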
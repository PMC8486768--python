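# Methods

## Coordinates and binning

All internal coordinates are 0-based, half-open — the native convention of
refGene, BED and BedGraph; conversion happens only at 1-based display
boundaries (SAM `POS` and WIG `start` on input). Each chromosome is divided
into ⌈length / bin_size⌉ consecutive bins; the bin size (the *window
resolution*) is the single memory/quality trade-off of the toolkit, and
every signal container is laid out on this grid. The TSS of a −-strand
transcript is `tx_end − 1` (the last covered base): half-open ends are
exclusive, so the first *transcribed* base of a minus-strand gene is the
base before `tx_end`.

## Pile-up and normalization

A retained alignment contributes its full aligned reference span — the
extent consumed by M/D/N/=/X CIGAR operations. This treats a spliced
RNA-seq read's N gap as covered, which matches the track-building intent
(the span is what the browser should shade) and keeps the arithmetic
integer-exact. No 5′-end reduction and no fragment-size extension is
applied; paired-end mates count independently, and `total_reads` counts
retained alignments. The per-bin unit is *reads overlapping the bin* (each
read increments every bin it touches once), not mean per-base coverage;
this makes the conservation identity Σ_bins counts = Σ_reads
(bins overlapped) exact, which the test suite asserts literally. A
per-base-mean dialect is available as a flag for users who want coverage
semantics.

Normalization multiplies the raw track by 10⁶ / total retained reads
(depth), 10⁶ / spike-in reads (spike-in), or 1 (none). The 10⁶ constant is
the reads-per-million convention; it only rescales axes. Under depth
normalization the track is exactly invariant to duplicating every read:
the factor halves as the counts double, and because the factor changes by
a power of two the invariance is bit-exact in IEEE arithmetic (also
asserted in tests).

Filters applied while streaming: unmapped, secondary and supplementary
alignments are dropped by default, an optional MAPQ floor and duplicate
drop are available, and reads on chromosomes absent from the genome index
are skipped and counted, never fatal. The accounting identity
retained + skipped = seen holds per file.

## Strand-specific tracks

For stranded libraries each read is assigned to the strand of the
transcript it reports on: `fr_firststrand` (dUTP-style) flips read1 and
keeps read2, `fr_secondstrand` mirrors. The signed track is the
forward-assigned pile-up minus the reverse-assigned pile-up, both scaled by
the same whole-library factor so the sign encodes strand, not depth.

## BedGraph output

Tracks are written as UCSC BedGraph with a `track type=bedGraph` header.
Adjacent equal-valued bins are merged into one record, zero runs are
suppressed by default, and the final record is clipped to the chromosome
length. Written tracks round-trip: re-expanding a file onto the same bin
grid reproduces the profile exactly. bigWig output is out of scope.

## Viewpoints, meta-profiles and heatmaps

An anchor set fixes the viewpoint: TSS, TES, peak center
(⌊(start+end)/2⌋), or gene body. Point-anchor windows sample the track on
the bin grid at offsets −flank … +flank (flank default 2500 bp);
minus-strand windows are read right-to-left so "upstream" always means 5′.
Windows that would leave the chromosome are dropped whole and counted —
zero-padding would dilute edge means. Genes with several transcripts
contribute one anchor per transcript; no canonical-transcript selection is
attempted.

Gene bodies are rescaled onto `body_bins` (default 100) equal slices; each
slice takes the unweighted mean of the bins it overlaps, flanks are
appended unscaled, and minus-strand bodies are reversed. When a gene's
length is an exact bin-aligned multiple of the slice count this reduces to
plain block means.

The heatmap matrix holds the same windows as rows (no averaging), so its
column means equal the meta-profile *by construction* — both code paths
share one window-extraction routine, and the equality is exact, not
approximate. Rows are ranked descending by a key (total, max, or the
offset-0 value; default total) with lexicographic tie-breaks, which makes
the permutation deterministic and idempotent. The color scale saturates at
an upper quantile (default 0.95) so a few extreme loci do not flatten the
map; saturation is rendering-only and never touches the TSV.

## Region quantification and conservation

Signal summaries work at bin resolution — the toolkit's measurement unit —
with partial boundary bins included whole; `total` is a bin-sum, so
comparisons across bin sizes should rescale by bin_size, and `bin_size=1`
recovers per-bp semantics. Totals are additive under splitting at bin
boundaries, and a whole-chromosome region reproduces the global track sum.

Conservation works at 1-bp resolution because PhastCons tracks are per-bp.
The fixedStep reader honors `step` and `span`, converts the 1-based WIG
`start`, rejects variableStep input explicitly, and warns on scores
outside [0, 1] (PhastCons is a probability) without failing. Positions the
track does not score are treated as 0 by default — an unscored gap is
legitimately unconserved — with `skip_missing` excluding them from the
mean instead (a region with no scored bp is then flagged `no_data`).

## Peak classification and spie charts

Transcripts are decomposed per-row (overlapping transcripts are not
merged) into: proximal promoter (default 2500 bp upstream of the TSS),
distal promoter (the band out to 10000 bp), 5′ UTR / CDS / 3′ UTR
(exonic bp split at the CDS boundaries, strand-aware), introns, and a
downstream band (default 1000 bp past the TES). Non-coding transcripts
(cdsStart == cdsEnd) have their exons carried in the 5′-UTR slot and are
reported as "noncoding exon". The promoter distances are explicit knobs
with documented defaults, not claims about any particular published
convention.

Classification is multi-counting: a peak is counted once in every
*distinct* category any of its bp overlaps (not once per segment), so
category counts may exceed the peak count; the per-peak annotation file
preserves all categories so users can impose a precedence downstream.
Peaks touching no promoter band and no transcript-derived segment are
intergenic. The basic detail level collapses to {promoter, intragenic,
intergenic}, with the downstream band folded into intergenic.

Spie charts compare a sample distribution to a reference (for peaks, the
genome's bp composition of the same categories, intergenic being the
uncovered remainder): sector angle ∝ reference proportion, sector radius
√(p_obs/p_ref), so sector area ∝ observed proportion and radius 1
everywhere iff the distributions agree. Categories absent from the
reference are excluded with a warning.

## Peak sets and gene association

`match_peaks` reports the pairwise intersection intervals of every
overlapping (A, B) pair with width ≥ min_overlap (default 1), plus the
whole original peaks unique to each set; the sorted sweep is verified
against brute-force all-pairs enumeration on hundreds of random instances.
`match_peaks_genes` links a peak to a transcript when it overlaps the
closed window TSS ± w (default w = 2500 bp, the standard promoter
association distance) — the window is symmetric and strand-agnostic in
extent; strand fixes only the TSS base and the distance sign (negative =
upstream in gene orientation, 0 = covering the TSS). An optional rule also
accepts overlap with the gene body. Link sets are monotone in w, and w = 0
links exactly the TSS-covering peaks.

## Synthetic data generator

The fixtures module emits matched ChromInfo, refGene, SAM (optionally
BAM), BED, gene-list and fixedStep WIG files from one seeded spec;
identical specs regenerate byte-identical files. Alongside the SAM it
returns the exact per-bin truth table computed by an independent naive
counter (a per-base CIGAR walk, structurally unlike the production
pile-up), which anchors the exactness tests. Fixture scale is capped at
100 kb of genome and 10⁴ reads so every brute-force oracle runs in
milliseconds; the acceptance script uses 4000 reads over 80 kb with half
the reads clustered in ±400 bp promoter windows, a center-to-flank
contrast typical of a sharp TSS mark.

What the generator does *not* emulate: fragment-length and GC biases,
sequencing errors, duplicate structure, mappability gaps, realistic gene
density or overlapping gene models. Passing tests therefore demonstrate
the *arithmetic* of the toolkit — exact pile-up, conservation identities,
format round-trips, interval algebra — on files in the real dialects, not
robustness to the noise structure of real libraries.

## Numerical choices and degenerate inputs

Exact integer identities are asserted bit-exactly (raw counts, BedGraph
round-trips, matrix/plot consistency); floating-point comparisons appear
only where genuinely stochastic quantities are involved. Empty anchor sets,
all-dropped windows and empty peak lists raise errors rather than emitting
NaNs; a constant heatmap degrades to a unit color range; zero-denominator
normalization instructs the user to switch to `none`. Ties in ranking
break lexicographically by row id. No operation mutates its inputs, and
reruns with the same inputs and seed are bit-identical at the TSV level.

## Known limitations

Single-end 5′-extension and fragment reconstruction for paired-end data
are not implemented (each mate counts independently); CRAM and bigWig are
unsupported; classification offers no precedence mode; the promoter
band distances have no authoritative external default and must be chosen
by the user for cross-study comparisons.
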
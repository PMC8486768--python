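"""Classify peaks into genomic features and associate them with genes.

Runs the feature classification (with the multi-counting rule), compares
the observed category distribution to the genome's bp composition as a
spie chart, intersects two peak sets, and links peaks to genes within
2500 bp of a TSS.
"""

from pathlib import Path

from seqsketch import (
    IntervalRecord,
    classify_peaks,
    decompose_gene_features,
    genome_reference_distribution,
    load_bed,
    load_chrom_info,
    load_refgene,
    match_peaks,
    match_peaks_genes,
    spie_chart_data,
)
from seqsketch.fixtures import random_spec, write_all

paths = write_all(random_spec(seed=3, n_genes=6, n_peaks=12), Path("example_out/peaks"))

index = load_chrom_info(paths["chrominfo"])
transcripts = load_refgene(paths["refgene"], index)
segments = decompose_gene_features(transcripts, index,
                                   proximal_bp=500, distal_bp=1500, downstream_bp=500)
peaks = load_bed(paths["peaks"])

dist, annotations = classify_peaks(peaks, segments, detail="basic")
print("peak classification (multi-counted):", dict(dist.counts))

reference = genome_reference_distribution(segments, index, detail="basic")
spie = spie_chart_data(dist, reference)
for cat, radius in zip(spie.categories, spie.radii):
    print(f"  spie radius {cat}: {radius:.2f}"
          f" ({'enriched' if radius > 1 else 'depleted'} vs genome)")

shifted = [IntervalRecord(p.chrom, p.start + 100, p.end + 100) for p in peaks]
common, a_only, b_only = match_peaks(peaks, shifted)
print(f"overlap with 100-bp-shifted self: {len(common)} common,"
      f" {len(a_only)} unique")

links, targets = match_peaks_genes(peaks, transcripts, tss_window_bp=2500)
print(f"{len(links)} peak-gene links within 2500 bp of a TSS;"
      f" target genes: {', '.join(targets)}")
# Radius > 1 means the category holds proportionally more peaks than its
# share of genomic bp; the 2500-bp rule is the default promoter association.
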
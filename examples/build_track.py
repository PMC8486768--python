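"""Build a genome-browser track from a SAM file.

Generates a small synthetic experiment, piles the reads onto 100-bp bins,
normalizes to reads-per-million, and writes a BedGraph custom track.
"""

from pathlib import Path

from seqsketch import (
    compute_normalization,
    load_chrom_info,
    load_reads,
    pileup,
    write_bedgraph,
)
from seqsketch.fixtures import random_spec, write_all

out = Path("example_out/track")
paths = write_all(random_spec(seed=1, n_reads=800), out)

index = load_chrom_info(paths["chrominfo"]).with_bin_size(100)
reads, counters = load_reads(paths["sam"], index)
norm = compute_normalization(counters, mode="depth")
profile = pileup(reads, index, norm, label="example")
write_bedgraph(profile, out / "example.bedgraph")

print(f"retained {counters.retained} of {counters.total_seen} alignments")
print(f"depth factor {norm.factor:g} (reads-per-million per read)")
print("first BedGraph records:")
for line in (out / "example.bedgraph").read_text().splitlines()[:5]:
    print(" ", line)
# Each record is chrom<TAB>start<TAB>end<TAB>value: the RPM-normalized count
# of reads overlapping those bins, 0-based half-open, ready for a browser.
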
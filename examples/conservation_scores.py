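"""Score regions against a PhastCons-style fixedStep conservation track.

Writes a piecewise-constant track with deliberate gaps, then summarizes a
set of regions under both missing-data conventions.
"""

from pathlib import Path

from seqsketch import IntervalRecord, load_fixedstep_wig, score_conservation
from seqsketch.fixtures import ConservationBlock, FixtureSpec, make_conservation

spec = FixtureSpec(
    chrom_plan=[("chrT", 5000)],
    conservation_plan=[
        ConservationBlock("chrT", 100, 200, 0.9),   # strongly conserved block
        ConservationBlock("chrT", 400, 200, 0.1),   # weakly conserved block
        # positions 300-399 and beyond 600 are unscored (alignment gaps)
    ],
)
wig = make_conservation(spec, Path("example_out/conservation"))
track = load_fixedstep_wig(wig)

regions = [
    IntervalRecord("chrT", 100, 300, "conserved"),
    IntervalRecord("chrT", 250, 450, "gap_spanning"),
    IntervalRecord("chrT", 700, 900, "unscored"),
]
for skip in (False, True):
    label = "missing excluded" if skip else "missing = 0"
    print(f"[{label}]")
    for s in score_conservation(track, regions, skip_missing=skip):
        print(f"  {s.region.name:>13}: mean {s.mean:.3f} max {s.max:.2f}"
              f" total {s.total:.1f} over {s.n_bins} bp"
              + ("  (no data)" if s.no_data else ""))
# The two conventions differ only where the track has gaps: treating gaps
# as 0 penalizes unaligned sequence, excluding them scores only what was
# actually aligned.
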
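"""Alignment ingest: stream mapped reads from SAM/BAM as genomic intervals.

Each retained alignment contributes its full aligned reference span (the
extent consumed on the reference by M/D/N/=/X CIGAR operations) — no 5'-end
reduction and no fragment extension.  Paired-end mates count independently.

Normalization is by sequencing depth (reads-per-million over the retained
alignments), by spike-in read count, or disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .genome import GenomeIndex

logger = logging.getLogger(__name__)

RPM_SCALE = 1_000_000  # reads-per-million constant


@dataclass(frozen=True)
class ReadInterval:
    """Aligned reference span of one retained alignment, half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    is_read2: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty read interval [{self.start},{self.end})")


@dataclass(frozen=True)
class ReadFilters:
    """Which alignments to drop while streaming."""

    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicates: bool = False
    min_mapq: int = 0


@dataclass
class IngestCounters:
    """Accounting for one streamed file: total = retained + sum(skipped)."""

    total_seen: int = 0
    retained: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1

    @property
    def total_skipped(self) -> int:
        return sum(self.skipped.values())

    def summary_lines(self) -> list[str]:
        lines = [f"alignments seen\t{self.total_seen}", f"retained\t{self.retained}"]
        for reason in sorted(self.skipped):
            lines.append(f"skipped ({reason})\t{self.skipped[reason]}")
        return lines


@dataclass(frozen=True)
class NormalizationSpec:
    """Scaling applied to raw per-bin counts.

    ``depth``: factor = 10^6 / total retained reads.
    ``spike_in``: factor = 10^6 / reads mapped to the exogenous genome.
    ``none``: factor = 1 (raw integer counts).
    """

    mode: str
    total_reads: int = 0
    spike_in_reads: int = 0
    scale_constant: float = RPM_SCALE

    def __post_init__(self) -> None:
        if self.mode not in ("depth", "spike_in", "none", "derived"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")

    @property
    def factor(self) -> float:
        if self.mode == "depth":
            return self.scale_constant / self.total_reads
        if self.mode == "spike_in":
            return self.scale_constant / self.spike_in_reads
        return 1.0


def stream_reads(
    path: str | Path,
    index: GenomeIndex,
    filters: ReadFilters | None = None,
    counters: IngestCounters | None = None,
) -> Iterator[ReadInterval]:
    """Yield one :class:`ReadInterval` per retained alignment in a SAM/BAM file.

    Reads on chromosomes absent from ``index`` are skipped and counted, never
    fatal.  ``counters`` (if supplied) is filled in place while iterating.
    """
    filters = filters or ReadFilters()
    counters = counters if counters is not None else IngestCounters()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            counters.total_seen += 1
            if aln.is_unmapped:
                if filters.drop_unmapped:
                    counters.skip("unmapped")
                    continue
            if filters.drop_secondary and aln.is_secondary:
                counters.skip("secondary")
                continue
            if filters.drop_supplementary and aln.is_supplementary:
                counters.skip("supplementary")
                continue
            if filters.drop_duplicates and aln.is_duplicate:
                counters.skip("duplicate")
                continue
            if aln.mapping_quality < filters.min_mapq:
                counters.skip("mapq")
                continue
            chrom = aln.reference_name
            if chrom not in index:
                counters.skip("unknown_chromosome")
                continue
            start = aln.reference_start          # already 0-based in pysam
            end = aln.reference_end              # start + reference-consuming span
            if end is None or end <= start:
                counters.skip("no_reference_span")
                continue
            counters.retained += 1
            yield ReadInterval(
                chrom=chrom,
                start=start,
                end=end,
                strand="-" if aln.is_reverse else "+",
                is_read2=aln.is_paired and aln.is_read2,
            )


def load_reads(
    path: str | Path,
    index: GenomeIndex,
    filters: ReadFilters | None = None,
) -> tuple[list[ReadInterval], IngestCounters]:
    """Materialize :func:`stream_reads`, returning (reads, counters)."""
    counters = IngestCounters()
    reads = list(stream_reads(path, index, filters, counters))
    return reads, counters


def compute_normalization(
    counters: IngestCounters | int,
    mode: str = "depth",
    spike_in_reads: int | None = None,
) -> NormalizationSpec:
    """Build the :class:`NormalizationSpec` for a streamed experiment.

    ``counters`` may be the :class:`IngestCounters` from streaming or the
    retained-read count directly.
    """
    total = counters.retained if isinstance(counters, IngestCounters) else int(counters)
    if mode == "depth" and total <= 0:
        raise ValueError("no retained reads: cannot depth-normalize (use mode='none')")
    if mode == "spike_in":
        if not spike_in_reads or spike_in_reads <= 0:
            raise ValueError("spike_in normalization needs spike_in_reads > 0 (use mode='none')")
        return NormalizationSpec("spike_in", total_reads=total, spike_in_reads=int(spike_in_reads))
    if mode == "none":
        return NormalizationSpec("none", total_reads=total)
    if mode != "depth":
        raise ValueError(f"unknown normalization mode {mode!r}")
    return NormalizationSpec("depth", total_reads=total)


LIBRARY_LAYOUTS = ("unstranded", "fr_firststrand", "fr_secondstrand")


def transcribed_strand(read: ReadInterval, library_layout: str) -> str:
    """Strand of the transcript a read reports on, under the declared layout.

    ``fr_firststrand`` (dUTP-style): read1 aligns antisense to the transcript,
    so its strand is flipped and read2's kept; ``fr_secondstrand`` mirrors.
    Single-end reads are treated as read1.
    """
    if library_layout == "unstranded":
        return "+"
    flip = {"+": "-", "-": "+"}
    if library_layout == "fr_firststrand":
        return read.strand if read.is_read2 else flip[read.strand]
    if library_layout == "fr_secondstrand":
        return flip[read.strand] if read.is_read2 else read.strand
    raise ValueError(f"unknown library layout {library_layout!r}")


def strand_split(
    reads: Iterable[ReadInterval], library_layout: str
) -> tuple[list[ReadInterval], list[ReadInterval]]:
    """Partition reads into (forward-assigned, reverse-assigned) lists."""
    forward: list[ReadInterval] = []
    reverse: list[ReadInterval] = []
    for read in reads:
        (forward if transcribed_strand(read, library_layout) == "+" else reverse).append(read)
    return forward, reverse
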
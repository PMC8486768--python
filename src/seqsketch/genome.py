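"""Genome model: chromosome sizes, transcript annotations and the binning scheme.

All coordinates in this package are 0-based, half-open — the native convention
of refGene/BED/BedGraph.  Conversion to 1-based happens only at display
boundaries (SAM POS on input, WIG ``start`` on input).

A genome is segmented into consecutive fixed-size *bins* (the "window
resolution"); every per-bin signal container in the package is laid out on
this grid, so the :class:`GenomeIndex` is the keystone shared by all modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Feature categories produced by :func:`decompose_gene_features`, in the
#: order used for reports and pie charts.
FEATURE_CATEGORIES = (
    "promoter_proximal",
    "promoter_distal",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "downstream",
    "intergenic",
)

#: Collapsed category sets for the basic level of detail.
BASIC_CATEGORY_MAP = {
    "promoter_proximal": "promoter",
    "promoter_distal": "promoter",
    "utr5": "intragenic",
    "cds": "intragenic",
    "intron": "intragenic",
    "utr3": "intragenic",
    "downstream": "intergenic",
    "intergenic": "intergenic",
}


class GenomeFileError(ValueError):
    """Malformed ChromInfo / refGene input."""


@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome names, lengths, and the uniform binning scheme.

    Parameters
    ----------
    chrom_names:
        Chromosome identifiers in file order.
    chrom_lengths:
        Map chromosome -> length in bp (all > 0).
    bin_size:
        Window resolution in bp (>= 1); ``None`` until binning is chosen.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    bin_size: int | None = None

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise GenomeFileError(f"chromosome {name!r} has non-positive length")
        if self.bin_size is not None and self.bin_size < 1:
            raise GenomeFileError(f"bin_size must be >= 1, got {self.bin_size}")

    def with_bin_size(self, bin_size: int) -> "GenomeIndex":
        """Return a copy with the window resolution set."""
        return replace(self, bin_size=int(bin_size))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` = ceil(length / bin_size)."""
        if self.bin_size is None:
            raise ValueError("bin_size not set on this GenomeIndex")
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)


def bin_of(position: int, index: GenomeIndex, chrom: str | None = None) -> int:
    """Bin ordinal of a genomic position: ``floor(position / bin_size)``.

    ``chrom`` enables the range check against the chromosome length; without
    it only non-negativity is enforced.
    """
    if index.bin_size is None:
        raise ValueError("bin_size not set on this GenomeIndex")
    if position < 0:
        raise ValueError(f"position {position} is negative")
    if chrom is not None:
        length = index.chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if position >= length:
            raise ValueError(f"position {chrom}:{position} beyond chromosome end {length}")
    return position // index.bin_size


def load_chrom_info(path: str | Path) -> GenomeIndex:
    """Parse a UCSC-style ChromInfo.txt (chrom<TAB>length, extra columns ignored).

    Returns a :class:`GenomeIndex` without a bin size; call
    :meth:`GenomeIndex.with_bin_size` before building profiles.
    """
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenomeFileError(f"{path}:{lineno}: expected chrom<TAB>length, got {line!r}")
            chrom = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise GenomeFileError(f"{path}:{lineno}: length {parts[1]!r} is not an integer") from exc
            if length <= 0:
                raise GenomeFileError(f"{path}:{lineno}: non-positive length {length} for {chrom}")
            if chrom in lengths:
                raise GenomeFileError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            names.append(chrom)
            lengths[chrom] = length
    return GenomeIndex(tuple(names), lengths)


@dataclass(frozen=True)
class TranscriptModel:
    """One refGene transcript row decomposed into coordinates.

    TSS and TES are strand-aware single base positions: on ``+`` the TSS is
    ``tx_start`` and the TES ``tx_end - 1``; on ``-`` they swap, the TSS being
    the last covered base ``tx_end - 1`` (half-open ends are exclusive).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeFileError(f"{self.transcript_id}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise GenomeFileError(f"{self.transcript_id}: txStart {self.tx_start} >= txEnd {self.tx_end}")
        if self.cds_start > self.cds_end:
            raise GenomeFileError(f"{self.transcript_id}: cdsStart > cdsEnd")
        if len(self.exon_starts) != len(self.exon_ends):
            raise GenomeFileError(f"{self.transcript_id}: exon list lengths differ")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e or s < prev_end or e > self.tx_end:
                raise GenomeFileError(f"{self.transcript_id}: bad exon [{s},{e})")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end


def load_refgene(path: str | Path, index: GenomeIndex | None = None) -> list[TranscriptModel]:
    """Parse a UCSC refGene.txt (16 tab-separated columns with leading bin).

    Transcripts on chromosomes absent from ``index`` are retained (downstream
    consumers skip them with a warning); they are flagged here by a log line.
    """
    transcripts: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 16:
                raise GenomeFileError(f"{path}:{lineno}: expected 16 columns, got {len(cols)}")
            (_, name, chrom, strand, tx_start, tx_end, cds_start, cds_end,
             exon_count, exon_starts, exon_ends, _, name2, _, _, _) = cols
            starts = tuple(int(x) for x in exon_starts.split(",") if x != "")
            ends = tuple(int(x) for x in exon_ends.split(",") if x != "")
            if len(starts) != int(exon_count) or len(ends) != int(exon_count):
                raise GenomeFileError(
                    f"{path}:{lineno}: exonCount {exon_count} does not match list lengths"
                )
            tm = TranscriptModel(
                transcript_id=name, gene_symbol=name2, chrom=chrom, strand=strand,
                tx_start=int(tx_start), tx_end=int(tx_end),
                cds_start=int(cds_start), cds_end=int(cds_end),
                exon_starts=starts, exon_ends=ends,
            )
            if index is not None and chrom not in index:
                logger.warning("%s:%d: transcript %s on chromosome %r absent from genome index",
                               path, lineno, name, chrom)
            transcripts.append(tm)
    return transcripts


@dataclass(frozen=True)
class FeatureSegment:
    """A half-open genomic interval carrying one gene-feature category."""

    chrom: str
    start: int
    end: int
    category: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty segment [{self.start},{self.end})")
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _clip(start: int, end: int, length: int) -> tuple[int, int]:
    return max(0, start), min(end, length)


def decompose_gene_features(
    transcripts: Iterable[TranscriptModel],
    index: GenomeIndex,
    proximal_bp: int = 2500,
    distal_bp: int = 10000,
    downstream_bp: int = 1000,
) -> list[FeatureSegment]:
    """Decompose transcripts into promoter / UTR / CDS / intron / downstream segments.

    Strand-aware: the proximal promoter is the ``proximal_bp`` band immediately
    upstream of the TSS, the distal promoter the ``distal_bp - proximal_bp``
    band upstream of that, and the downstream band extends ``downstream_bp``
    past the TES.  Exonic bp are split into 5' UTR / CDS / 3' UTR using the CDS
    boundaries; a non-coding transcript's exons are labeled ``utr5`` (reported
    as "noncoding exon" in annotation output).  All segments are clipped to
    chromosome bounds; transcripts on unknown chromosomes are skipped with a
    warning.
    """
    if not (0 < proximal_bp <= distal_bp):
        raise ValueError("need 0 < proximal_bp <= distal_bp")
    segments: list[FeatureSegment] = []

    def emit(chrom: str, start: int, end: int, category: str, tid: str, length: int) -> None:
        start, end = _clip(start, end, length)
        if start < end:
            segments.append(FeatureSegment(chrom, start, end, category, tid))

    for tm in transcripts:
        length = index.chrom_lengths.get(tm.chrom)
        if length is None:
            logger.warning("transcript %s on unknown chromosome %r skipped", tm.transcript_id, tm.chrom)
            continue
        tid = tm.transcript_id
        if tm.strand == "+":
            # upstream = decreasing coordinates
            emit(tm.chrom, tm.tx_start - proximal_bp, tm.tx_start, "promoter_proximal", tid, length)
            emit(tm.chrom, tm.tx_start - distal_bp, tm.tx_start - proximal_bp, "promoter_distal", tid, length)
            emit(tm.chrom, tm.tx_end, tm.tx_end + downstream_bp, "downstream", tid, length)
        else:
            emit(tm.chrom, tm.tx_end, tm.tx_end + proximal_bp, "promoter_proximal", tid, length)
            emit(tm.chrom, tm.tx_end + proximal_bp, tm.tx_end + distal_bp, "promoter_distal", tid, length)
            emit(tm.chrom, tm.tx_start - downstream_bp, tm.tx_start, "downstream", tid, length)

        # introns: gaps between consecutive exons
        for prev_end, nxt_start in zip(tm.exon_ends[:-1], tm.exon_starts[1:]):
            emit(tm.chrom, prev_end, nxt_start, "intron", tid, length)

        for es, ee in zip(tm.exon_starts, tm.exon_ends):
            if not tm.is_coding:
                emit(tm.chrom, es, ee, "utr5", tid, length)
                continue
            # split exon bp at CDS boundaries
            left_cat, right_cat = ("utr5", "utr3") if tm.strand == "+" else ("utr3", "utr5")
            lo = max(es, tm.cds_start)
            hi = min(ee, tm.cds_end)
            if es < min(ee, tm.cds_start):
                emit(tm.chrom, es, min(ee, tm.cds_start), left_cat, tid, length)
            if lo < hi:
                emit(tm.chrom, lo, hi, "cds", tid, length)
            if max(es, tm.cds_end) < ee:
                emit(tm.chrom, max(es, tm.cds_end), ee, right_cat, tid, length)
    return segments
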
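"""Deterministic synthetic fixtures: matched ChromInfo, refGene, SAM/BAM,
BED, gene-list and fixedStep WIG files with known ground truth.

Everything is driven by a :class:`FixtureSpec`; the same spec (same seed)
regenerates byte-identical files, so tests can pin exact expectations.
Alongside the SAM, :func:`make_alignments` returns the exact per-bin
overlap-count table computed by an independent naive counter — the oracle
the profile builder is checked against.

Scale is deliberately small (genomes <= 100 kb, <= 10^4 reads): large enough
to exercise every code path, small enough that brute-force oracles run in
milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomeIndex, TranscriptModel

MAX_FIXTURE_GENOME = 100_000
MAX_FIXTURE_READS = 10_000


@dataclass(frozen=True)
class ReadPlan:
    """One planned alignment.  ``cigar`` defaults to full-match of ``length``."""

    chrom: str
    start: int                    # 0-based leftmost reference position
    length: int = 36              # reference span when cigar is None
    strand: str = "+"
    is_read2: bool = False
    paired: bool = False
    cigar: str | None = None
    mapq: int = 60
    unmapped: bool = False
    secondary: bool = False
    duplicate: bool = False


@dataclass(frozen=True)
class GenePlan:
    """One transcript to synthesize into refGene.txt."""

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


@dataclass(frozen=True)
class ConservationBlock:
    """Piecewise-constant conservation: ``score`` over [start, start+length)."""

    chrom: str
    start: int
    length: int
    score: float


@dataclass
class FixtureSpec:
    """Full recipe for one synthetic dataset."""

    seed: int = 0
    chrom_plan: list[tuple[str, int]] = field(default_factory=lambda: [("chrT", 10_000)])
    gene_plan: list[GenePlan] = field(default_factory=list)
    read_plan: list[ReadPlan] = field(default_factory=list)
    peak_plan: list[tuple[str, int, int]] = field(default_factory=list)
    conservation_plan: list[ConservationBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(length for _, length in self.chrom_plan)
        if total > MAX_FIXTURE_GENOME:
            raise ValueError(f"fixture genome {total} bp exceeds {MAX_FIXTURE_GENOME}")
        if len(self.read_plan) > MAX_FIXTURE_READS:
            raise ValueError(f"fixture read count exceeds {MAX_FIXTURE_READS}")
        lengths = dict(self.chrom_plan)
        for rp in self.read_plan:
            if rp.chrom in lengths and not rp.unmapped:
                if rp.start < 0 or rp.start + _cigar_ref_span(rp.cigar or f"{rp.length}M") > lengths[rp.chrom]:
                    raise ValueError(f"read at {rp.chrom}:{rp.start} leaves the chromosome")

    @property
    def genome_index(self) -> GenomeIndex:
        names = tuple(c for c, _ in self.chrom_plan)
        return GenomeIndex(names, dict(self.chrom_plan))


def _cigar_ref_span(cigar: str) -> int:
    """Reference bp consumed by a CIGAR string (M/D/N/=/X consume)."""
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                span += int(num)
            num = ""
    return span


def _cigar_read_len(cigar: str) -> int:
    """Query bp consumed by a CIGAR string (M/I/S/=/X consume)."""
    n = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                n += int(num)
            num = ""
    return n


def make_genome(spec: FixtureSpec, outdir: str | Path) -> tuple[Path, Path]:
    """Write ChromInfo.txt and refGene.txt in the dialects the parsers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrominfo = outdir / "ChromInfo.txt"
    with open(chrominfo, "w") as fh:
        for chrom, length in spec.chrom_plan:
            fh.write(f"{chrom}\t{length}\n")
    refgene = outdir / "refGene.txt"
    with open(refgene, "w") as fh:
        for gp in spec.gene_plan:
            starts = ",".join(str(s) for s in gp.exon_starts) + ","
            ends = ",".join(str(e) for e in gp.exon_ends) + ","
            frames = ",".join("0" for _ in gp.exon_starts) + ","
            fh.write(
                "\t".join(
                    [
                        "0", gp.transcript_id, gp.chrom, gp.strand,
                        str(gp.tx_start), str(gp.tx_end),
                        str(gp.cds_start), str(gp.cds_end),
                        str(len(gp.exon_starts)), starts, ends,
                        "0", gp.gene_symbol, "cmpl", "cmpl", frames,
                    ]
                )
                + "\n"
            )
    return chrominfo, refgene


def naive_bin_counts(
    reads: Sequence[ReadPlan], index: GenomeIndex
) -> dict[str, np.ndarray]:
    """Independent per-bin overlap counter used as the pile-up oracle.

    Walks every reference bp each read's CIGAR covers, marks the bins it
    touches, and counts each (read, bin) pair once — deliberately naive and
    structurally unlike the production pile-up.
    """
    if index.bin_size is None:
        raise ValueError("bin_size not set")
    counts = {c: np.zeros(index.n_bins(c), dtype=int) for c in index.chrom_names}
    for rp in reads:
        if rp.unmapped or rp.secondary or rp.chrom not in index:
            continue
        cigar = rp.cigar or f"{rp.length}M"
        touched: set[int] = set()
        pos = rp.start
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "M=X":
                for p in range(pos, pos + n):
                    touched.add(p // index.bin_size)
                pos += n
            elif ch in "DN":
                # consumes reference: the span covers these bp too
                for p in range(pos, pos + n):
                    touched.add(p // index.bin_size)
                pos += n
            # I and S consume no reference
        for b in touched:
            counts[rp.chrom][b] += 1
    return counts


def make_alignments(
    spec: FixtureSpec,
    outdir: str | Path,
    bam: bool = False,
    bin_size: int | None = None,
) -> tuple[Path, dict[str, np.ndarray] | None]:
    """Write a SAM (optionally also BAM) file plus the per-bin truth table.

    The truth table (from :func:`naive_bin_counts`) is returned when
    ``bin_size`` is given; it is the exact raw pile-up the profile builder
    must reproduce with normalization off.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sam_path = outdir / "reads.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in spec.chrom_plan:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, rp in enumerate(spec.read_plan):
            flag = 0
            if rp.paired or rp.is_read2:
                flag |= 0x1
                flag |= 0x80 if rp.is_read2 else 0x40
            if rp.unmapped:
                flag |= 0x4
            if rp.strand == "-":
                flag |= 0x10
            if rp.secondary:
                flag |= 0x100
            if rp.duplicate:
                flag |= 0x400
            cigar = rp.cigar or f"{rp.length}M"
            if rp.unmapped:
                rname, pos, cigar_out, mapq = "*", 0, "*", 0
            else:
                rname, pos, cigar_out, mapq = rp.chrom, rp.start + 1, cigar, rp.mapq
            seq = "A" * max(_cigar_read_len(cigar), 1)
            fh.write(
                f"read{i}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar_out}\t*\t0\t0\t{seq}\t*\n"
            )
    if bam:
        import pysam

        bam_path = outdir / "reads.bam"
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fin:
            with pysam.AlignmentFile(str(bam_path), "wb", template=fin) as fout:
                for aln in fin.fetch(until_eof=True):
                    fout.write(aln)
    truth = None
    if bin_size is not None:
        truth = naive_bin_counts(spec.read_plan, spec.genome_index.with_bin_size(bin_size))
    return sam_path, truth


def make_peaks(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Write the planned peaks as BED3 with stable names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "peaks.bed"
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(spec.peak_plan):
            fh.write(f"{chrom}\t{start}\t{end}\tpeak{i}\n")
    return path


def make_gene_list(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Write the distinct gene symbols of the gene plan, one per line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "genes.txt"
    seen: list[str] = []
    for gp in spec.gene_plan:
        if gp.gene_symbol not in seen:
            seen.append(gp.gene_symbol)
    path.write_text("".join(f"{g}\n" for g in seen))
    return path


def make_conservation(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Write the piecewise-constant conservation plan as fixedStep WIG.

    Each block becomes one ``fixedStep`` section with step=span=1, so
    per-region summaries follow from the plan in closed form.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "conservation.wig"
    with open(path, "w") as fh:
        for block in spec.conservation_plan:
            fh.write(f"fixedStep chrom={block.chrom} start={block.start + 1} step=1\n")
            for _ in range(block.length):
                fh.write(f"{block.score:g}\n")
    return path


def random_spec(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 10_000,
    n_genes: int = 4,
    n_reads: int = 500,
    n_peaks: int = 8,
    read_length: int = 36,
    gapped_fraction: float = 0.1,
) -> FixtureSpec:
    """A randomized but fully seeded FixtureSpec for property-style tests.

    Genes are non-overlapping two-exon transcripts with alternating strand;
    reads are uniform over each chromosome with a fraction carrying an
    N-gapped CIGAR (splice-like); peaks are uniform intervals.
    """
    rng = np.random.default_rng(seed)
    chrom_plan = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chroms)]
    genes: list[GenePlan] = []
    slot = chrom_length // max(n_genes, 1)
    for g in range(n_genes):
        chrom = chrom_plan[g % n_chroms][0]
        lo = (g % max(1, n_genes)) * slot
        width = int(rng.integers(slot // 4, slot // 2))
        tx_start = lo + int(rng.integers(0, slot - width))
        tx_end = tx_start + width
        e1_end = tx_start + width // 3
        e2_start = tx_end - width // 3
        cds_start = tx_start + width // 6
        cds_end = tx_end - width // 6
        genes.append(
            GenePlan(
                transcript_id=f"NM_{g:04d}",
                gene_symbol=f"Gene{g}",
                chrom=chrom,
                strand="+" if g % 2 == 0 else "-",
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=(tx_start, e2_start),
                exon_ends=(e1_end, tx_end),
            )
        )
    reads: list[ReadPlan] = []
    for _ in range(n_reads):
        chrom, length = chrom_plan[int(rng.integers(0, n_chroms))]
        if rng.random() < gapped_fraction:
            gap = int(rng.integers(10, 200))
            half = read_length // 2
            span = half * 2 + gap
            start = int(rng.integers(0, length - span))
            reads.append(
                ReadPlan(chrom, start, cigar=f"{half}M{gap}N{half}M",
                         strand="+" if rng.random() < 0.5 else "-")
            )
        else:
            start = int(rng.integers(0, length - read_length))
            reads.append(
                ReadPlan(chrom, start, length=read_length,
                         strand="+" if rng.random() < 0.5 else "-")
            )
    peaks: list[tuple[str, int, int]] = []
    for _ in range(n_peaks):
        chrom, length = chrom_plan[int(rng.integers(0, n_chroms))]
        width = int(rng.integers(50, 400))
        start = int(rng.integers(0, length - width))
        peaks.append((chrom, start, start + width))
    blocks: list[ConservationBlock] = []
    pos = 0
    while pos < chrom_length - 200:
        width = int(rng.integers(50, 200))
        if rng.random() < 0.8:  # leave gaps uncovered
            blocks.append(
                ConservationBlock(chrom_plan[0][0], pos, width,
                                  round(float(rng.random()), 3))
            )
        pos += width + int(rng.integers(0, 100))
    return FixtureSpec(
        seed=seed,
        chrom_plan=chrom_plan,
        gene_plan=genes,
        read_plan=reads,
        peak_plan=peaks,
        conservation_plan=blocks,
    )


def write_all(spec: FixtureSpec, outdir: str | Path, bam: bool = False) -> dict[str, Path]:
    """Materialize every fixture file for a spec; returns the path map."""
    outdir = Path(outdir)
    chrominfo, refgene = make_genome(spec, outdir)
    sam, _ = make_alignments(spec, outdir, bam=bam)
    paths = {
        "chrominfo": chrominfo,
        "refgene": refgene,
        "sam": sam,
        "peaks": make_peaks(spec, outdir),
        "genes": make_gene_list(spec, outdir),
        "conservation": make_conservation(spec, outdir),
    }
    if bam:
        paths["bam"] = outdir / "reads.bam"
    return paths
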
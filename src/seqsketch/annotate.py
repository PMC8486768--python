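"""Peak annotation: genomic-feature classification, spie charts, peak set
comparison and peak-to-gene association.

Classification follows the multi-counting rule: a peak overlapping several
distinct feature categories is counted once in *each* of them (not once per
segment), so category counts can exceed the number of peaks.  Peaks touching
no promoter band and no transcript-derived segment are intergenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import (
    BASIC_CATEGORY_MAP,
    FEATURE_CATEGORIES,
    FeatureSegment,
    GenomeIndex,
    TranscriptModel,
)
from .intervals import IntervalRecord


@dataclass
class FeatureDistribution:
    """Category -> peak count (multi-counted) at one level of detail."""

    counts: dict[str, int]
    n_peaks: int
    detail: str = "detailed"

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: v / total for c, v in self.counts.items()}


@dataclass
class PeakAnnotation:
    """All categories one peak overlaps (empty never happens: intergenic fallback)."""

    peak: IntervalRecord
    categories: tuple[str, ...]


def _detailed_categories(
    peak: IntervalRecord, by_chrom: dict[str, list[FeatureSegment]]
) -> tuple[str, ...]:
    hits: set[str] = set()
    for seg in by_chrom.get(peak.chrom, ()):
        if seg.start < peak.end and peak.start < seg.end:
            hits.add(seg.category)
    if not hits:
        return ("intergenic",)
    return tuple(sorted(hits, key=FEATURE_CATEGORIES.index))


def classify_peaks(
    peaks: Sequence[IntervalRecord],
    segments: Iterable[FeatureSegment],
    detail: str = "detailed",
) -> tuple[FeatureDistribution, list[PeakAnnotation]]:
    """Distribute peaks over gene-feature categories with multi-counting.

    ``detail="basic"`` collapses to {promoter, intragenic, intergenic}
    (the downstream band folds into intergenic).  Returns the distribution
    and the per-peak annotation records.
    """
    if not peaks:
        raise ValueError("empty peak list")
    if detail not in ("basic", "detailed"):
        raise ValueError(f"detail must be 'basic' or 'detailed', got {detail!r}")
    by_chrom: dict[str, list[FeatureSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    annotations: list[PeakAnnotation] = []
    counts: dict[str, int] = {}
    for peak in peaks:
        cats = _detailed_categories(peak, by_chrom)
        if detail == "basic":
            cats = tuple(dict.fromkeys(BASIC_CATEGORY_MAP[c] for c in cats))
        annotations.append(PeakAnnotation(peak, cats))
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
    return FeatureDistribution(counts, n_peaks=len(peaks), detail=detail), annotations


def genome_reference_distribution(
    segments: Iterable[FeatureSegment],
    index: GenomeIndex,
    detail: str = "detailed",
) -> FeatureDistribution:
    """bp composition of feature categories over the whole genome.

    Per category, the union of its segments in bp; intergenic is the genome
    remainder not covered by any segment.  This is the reference distribution
    spie charts compare peak classifications against.
    """
    per_cat: dict[str, dict[str, np.ndarray]] = {}
    any_mask: dict[str, np.ndarray] = {
        c: np.zeros(index.chrom_lengths[c], dtype=bool) for c in index.chrom_names
    }
    for seg in segments:
        if seg.chrom not in any_mask:
            continue
        mask = per_cat.setdefault(seg.category, {})
        if seg.chrom not in mask:
            mask[seg.chrom] = np.zeros(index.chrom_lengths[seg.chrom], dtype=bool)
        mask[seg.chrom][seg.start : seg.end] = True
        any_mask[seg.chrom][seg.start : seg.end] = True
    counts: dict[str, int] = {}
    for cat, masks in per_cat.items():
        counts[cat] = int(sum(m.sum() for m in masks.values()))
    counts["intergenic"] = int(sum((~m).sum() for m in any_mask.values()))
    if detail == "basic":
        basic: dict[str, int] = {}
        for cat, n in counts.items():
            basic[BASIC_CATEGORY_MAP[cat]] = basic.get(BASIC_CATEGORY_MAP[cat], 0) + n
        counts = basic
    return FeatureDistribution(counts, n_peaks=index.total_length, detail=detail)


@dataclass
class SpieData:
    """Spie chart geometry: angles from the reference, radii from the ratio.

    Sector angle is proportional to the reference proportion; sector radius
    is sqrt(p_obs / p_ref) so sector *area* is proportional to the observed
    proportion.  Radius 1 everywhere iff sample matches reference.
    """

    categories: list[str]
    p_ref: np.ndarray
    p_obs: np.ndarray
    angles: np.ndarray
    radii: np.ndarray
    excluded: list[str] = field(default_factory=list)


def spie_chart_data(sample: FeatureDistribution, reference: FeatureDistribution) -> SpieData:
    """Spie-chart geometry comparing a sample distribution to a reference."""
    ref_counts = {c: n for c, n in reference.counts.items() if n > 0}
    excluded = [c for c in reference.counts if reference.counts[c] == 0]
    categories = [c for c in ref_counts]
    if not set(sample.counts) & set(reference.counts):
        raise ValueError("sample and reference share no categories")
    ref_total = sum(ref_counts.values())
    obs_total = sum(sample.counts.values())
    p_ref = np.array([ref_counts[c] / ref_total for c in categories])
    p_obs = np.array([sample.counts.get(c, 0) / obs_total if obs_total else 0.0
                      for c in categories])
    angles = 2.0 * math.pi * p_ref
    radii = np.sqrt(p_obs / p_ref)
    return SpieData(categories, p_ref, p_obs, angles, radii, excluded)


def match_peaks(
    a: Sequence[IntervalRecord],
    b: Sequence[IntervalRecord],
    min_overlap_bp: int = 1,
) -> tuple[list[IntervalRecord], list[IntervalRecord], list[IntervalRecord]]:
    """Overlap two peak sets: (common intersection intervals, a_only, b_only).

    ``common`` holds the pairwise intersection [max(starts), min(ends)) of
    every overlapping (a, b) pair with width >= ``min_overlap_bp``; the
    ``*_only`` lists hold whole original peaks with no qualifying overlap.
    Sorted per-chromosome sweep, O((n+m) log(n+m) + hits).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    chroms = {p.chrom for p in a} | {p.chrom for p in b}
    common: list[IntervalRecord] = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    a_idx = {id(p): i for i, p in enumerate(a)}
    b_idx = {id(p): i for i, p in enumerate(b)}
    for chrom in sorted(chroms):
        ca = sorted((p for p in a if p.chrom == chrom), key=lambda p: p.start)
        cb = sorted((p for p in b if p.chrom == chrom), key=lambda p: p.start)
        j0 = 0
        for pa in ca:
            # b peaks ending at/before pa.start can never overlap pa or later a peaks
            while j0 < len(cb) and cb[j0].end <= pa.start:
                j0 += 1
            j = j0
            while j < len(cb) and cb[j].start < pa.end:
                lo = max(pa.start, cb[j].start)
                hi = min(pa.end, cb[j].end)
                if hi - lo >= min_overlap_bp:
                    name = None
                    if pa.name or cb[j].name:
                        name = f"{pa.name or '.'}|{cb[j].name or '.'}"
                    common.append(IntervalRecord(chrom, lo, hi, name))
                    a_hit.add(a_idx[id(pa)])
                    b_hit.add(b_idx[id(cb[j])])
                j += 1
    a_only = [p for i, p in enumerate(a) if i not in a_hit]
    b_only = [p for i, p in enumerate(b) if i not in b_hit]
    common.sort(key=lambda p: (p.chrom, p.start, p.end))
    return common, a_only, b_only


@dataclass
class PeakGeneLink:
    """One (peak, transcript) association under the matching rules.

    ``distance`` is the signed bp from the TSS to the nearest overlapping
    peak bp — 0 if the peak covers the TSS, negative upstream *in gene
    orientation* (so the sign is strand-aware).
    """

    peak: IntervalRecord
    transcript_id: str
    gene_symbol: str
    rule_hit: str           # "tss_window" | "gene_body"
    distance: int


def _tss_distance(peak: IntervalRecord, tss: int, strand: str) -> int:
    if peak.start <= tss < peak.end:
        return 0
    nearest = peak.start if peak.start > tss else peak.end - 1
    genomic = nearest - tss
    return genomic if strand == "+" else -genomic


def match_peaks_genes(
    peaks: Sequence[IntervalRecord],
    transcripts: Iterable[TranscriptModel],
    tss_window_bp: int = 2500,
    include_gene_body: bool = False,
) -> tuple[list[PeakGeneLink], list[str]]:
    """Associate peaks to genes: peak within ``tss_window_bp`` of the TSS
    (closed window, strand-agnostic in extent) or, optionally, overlapping
    the gene body.

    One link per qualifying (peak, transcript) pair; the gene-level target
    list is the distinct gene symbols with at least one link.
    """
    if tss_window_bp < 0:
        raise ValueError("tss_window_bp must be >= 0")
    links: list[PeakGeneLink] = []
    for tm in transcripts:
        win_lo = tm.tss - tss_window_bp
        win_hi = tm.tss + tss_window_bp + 1  # closed at bp granularity
        for peak in peaks:
            if peak.chrom != tm.chrom:
                continue
            if peak.start < win_hi and win_lo < peak.end:
                rule = "tss_window"
            elif include_gene_body and peak.start < tm.tx_end and tm.tx_start < peak.end:
                rule = "gene_body"
            else:
                continue
            links.append(
                PeakGeneLink(
                    peak=peak,
                    transcript_id=tm.transcript_id,
                    gene_symbol=tm.gene_symbol,
                    rule_hit=rule,
                    distance=_tss_distance(peak, tm.tss, tm.strand),
                )
            )
    genes = sorted({ln.gene_symbol for ln in links})
    return links, genes
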
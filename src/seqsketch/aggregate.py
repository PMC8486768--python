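"""Averaged occupancy (meta-)profiles around TSS/TES/peak centers and gene bodies.

An :class:`AnchorSet` fixes the viewpoint; window extraction happens once, in
:func:`extract_windows`, which both this module (column means -> the
aggregate plot) and the density-heatmap module (rows -> the barcode matrix)
consume, so plot/heatmap consistency is exact by construction.

Offsets are sampled on the bin grid.  Minus-strand anchors are read
right-to-left so that "upstream" always means 5' of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import TranscriptModel
from .intervals import IntervalRecord
from .profiles import BinnedProfile

ANCHOR_KINDS = ("TSS", "TES", "PEAK_CENTER", "GENE_BODY")


@dataclass(frozen=True)
class Anchor:
    """One viewpoint: a point (TSS/TES/peak center) or a body (start, end)."""

    chrom: str
    position: int          # point anchors: the anchor bp; bodies: unused
    strand: str = "+"
    name: str = ""
    start: int = -1        # body anchors only
    end: int = -1


@dataclass
class AnchorSet:
    kind: str
    anchors: list[Anchor]
    flank_bp: int = 2500
    body_bins: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ANCHOR_KINDS:
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.kind == "GENE_BODY" and self.body_bins < 1:
            raise ValueError("body_bins must be >= 1")


@dataclass
class MetaProfile:
    """Mean normalized signal per relative position, over contributing anchors."""

    positions: np.ndarray
    mean_signal: np.ndarray
    n_anchors: int
    n_dropped: int = 0
    kind: str = "TSS"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.mean_signal):
            raise ValueError("positions and mean_signal lengths differ")


def resolve_gene_anchors(
    gene_names: Sequence[str],
    transcripts: Iterable[TranscriptModel],
    kind: str,
    flank_bp: int = 2500,
    body_bins: int = 100,
) -> tuple[AnchorSet, list[str]]:
    """Match gene symbols (case-sensitive) to transcripts and build anchors.

    Every transcript of a matched gene contributes one anchor.  Returns the
    anchor set plus the list of unmatched names; zero matches is an error.
    """
    if kind not in ("TSS", "TES", "GENE_BODY"):
        raise ValueError(f"gene anchors must be TSS/TES/GENE_BODY, not {kind!r}")
    wanted = set(gene_names)
    anchors: list[Anchor] = []
    matched: set[str] = set()
    for tm in transcripts:
        if tm.gene_symbol not in wanted:
            continue
        matched.add(tm.gene_symbol)
        if kind == "GENE_BODY":
            anchors.append(Anchor(tm.chrom, -1, tm.strand, tm.transcript_id,
                                  start=tm.tx_start, end=tm.tx_end))
        else:
            pos = tm.tss if kind == "TSS" else tm.tes
            anchors.append(Anchor(tm.chrom, pos, tm.strand, tm.transcript_id))
    unmatched = [n for n in gene_names if n not in matched]
    if not anchors:
        raise ValueError("no gene name matched any transcript")
    return AnchorSet(kind, anchors, flank_bp=flank_bp, body_bins=body_bins), unmatched


def peak_center_anchors(peaks: Sequence[IntervalRecord], flank_bp: int = 2500) -> AnchorSet:
    """Anchors at floor((start+end)/2) of each peak, strand +."""
    if not peaks:
        raise ValueError("empty peak list")
    anchors = [
        Anchor(p.chrom, p.center, "+", p.name or f"{p.chrom}:{p.start}-{p.end}")
        for p in peaks
    ]
    return AnchorSet("PEAK_CENTER", anchors, flank_bp=flank_bp)


def _point_offsets(flank_bp: int, bin_size: int) -> np.ndarray:
    return np.arange(-(flank_bp // bin_size), flank_bp // bin_size + 1) * bin_size


def _body_positions(flank_bp: int, bin_size: int, body_bins: int) -> np.ndarray:
    """Body slices labeled 0..body_bins-1; flanks labeled in bp beyond the ends."""
    n_flank = flank_bp // bin_size
    up = -np.arange(n_flank, 0, -1) * bin_size
    body = np.arange(body_bins)
    down = body_bins - 1 + np.arange(1, n_flank + 1) * bin_size
    return np.concatenate([up, body, down]).astype(float)


def extract_windows(
    profile: BinnedProfile,
    anchor_set: AnchorSet,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Per-anchor signal windows on the bin grid.

    Returns ``(positions, matrix, row_ids, n_dropped)``; row r of ``matrix``
    is the window of anchor r (minus-strand anchors flipped so column order
    runs 5'->3').  Anchors whose window leaves the chromosome are dropped
    whole and counted — no zero padding that would dilute edge means.
    """
    index = profile.index
    bs = index.bin_size
    if bs is None:
        raise ValueError("bin_size not set on the profile's GenomeIndex")
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    dropped = 0

    if anchor_set.kind == "GENE_BODY":
        positions = _body_positions(anchor_set.flank_bp, bs, anchor_set.body_bins)
        n_flank = anchor_set.flank_bp // bs
        for a in anchor_set.anchors:
            length = index.chrom_lengths.get(a.chrom)
            if length is None or a.start - anchor_set.flank_bp < 0 or a.end + anchor_set.flank_bp > length:
                dropped += 1
                continue
            v = profile.values[a.chrom]
            body_len = a.end - a.start
            body_vals = np.empty(anchor_set.body_bins)
            for j in range(anchor_set.body_bins):
                s = a.start + body_len * j // anchor_set.body_bins
                e = a.start + body_len * (j + 1) // anchor_set.body_bins
                e = max(e, s + 1)
                body_vals[j] = v[s // bs : (e - 1) // bs + 1].mean()
            up = np.array([v[(a.start - k * bs) // bs] for k in range(n_flank, 0, -1)])
            down = np.array([v[min((a.end - 1 + k * bs) // bs, len(v) - 1)] for k in range(1, n_flank + 1)])
            window = np.concatenate([up, body_vals, down])
            if a.strand == "-":
                window = window[::-1]
            rows.append(window)
            row_ids.append(a.name)
    else:
        positions = _point_offsets(anchor_set.flank_bp, bs).astype(float)
        offsets = positions.astype(int)
        for a in anchor_set.anchors:
            length = index.chrom_lengths.get(a.chrom)
            if (
                length is None
                or a.position + offsets[0] < 0
                or a.position + offsets[-1] >= length
            ):
                dropped += 1
                continue
            v = profile.values[a.chrom]
            if a.strand == "-":
                sample = a.position - offsets
            else:
                sample = a.position + offsets
            rows.append(v[sample // bs])
            row_ids.append(a.name)

    matrix = np.vstack(rows) if rows else np.empty((0, len(positions)))
    return positions, matrix, row_ids, dropped


def aggregate(profile: BinnedProfile, anchor_set: AnchorSet) -> MetaProfile:
    """Mean signal per relative position over all retained anchors."""
    positions, matrix, _, dropped = extract_windows(profile, anchor_set)
    if matrix.shape[0] == 0:
        raise ValueError("all anchors dropped (windows exceed chromosome bounds)")
    return MetaProfile(
        positions=positions,
        mean_signal=matrix.mean(axis=0),
        n_anchors=matrix.shape[0],
        n_dropped=dropped,
        kind=anchor_set.kind,
    )


def aggregate_difference(
    a: BinnedProfile, b: BinnedProfile, anchor_set: AnchorSet
) -> MetaProfile:
    """Meta-profile of ``a - b``; by linearity of the mean this equals
    ``aggregate(a) - aggregate(b)`` pointwise."""
    from .profiles import subtract

    return aggregate(subtract(a, b), anchor_set)
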
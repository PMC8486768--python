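"""BED-style half-open genomic intervals and plain-text list IO."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class IntervalRecord:
    """One BED record: 0-based half-open, with optional name/score/strand."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:[{self.start},{self.end})")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "IntervalRecord") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def load_bed(path: str | Path) -> list[IntervalRecord]:
    """Parse BED3+ (track/browser/comment lines skipped)."""
    records: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = cols[3] if len(cols) > 3 else None
            score = float(cols[4]) if len(cols) > 4 and cols[4] not in (".", "") else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else None
            records.append(IntervalRecord(cols[0], int(cols[1]), int(cols[2]), name, score, strand))
    return records


def write_bed(
    records: Iterable[IntervalRecord],
    path: str | Path,
    track_name: str | None = None,
    color: tuple[int, int, int] = (0, 0, 160),
) -> None:
    """Write BED records, optionally with a browser track header line."""
    with open(path, "w") as fh:
        if track_name is not None:
            r, g, b = color
            fh.write(f"track name={track_name} visibility=dense color={r},{g},{b}\n")
        for iv in records:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else "0")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def load_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list: one symbol per line, '#' comments allowed."""
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                names.append(name)
    return names
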
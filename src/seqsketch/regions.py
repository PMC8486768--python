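"""Per-region signal summaries and PhastCons conservation scoring.

Signal quantification works at bin resolution — the measurement unit of the
whole toolkit; a boundary bin partially covered by the region is included
whole.  Conservation works at 1-bp resolution because PhastCons tracks are
per-bp; positions the track does not score are treated as 0 by default (an
unscored gap is legitimately unconserved) or excluded with ``skip_missing``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import IntervalRecord
from .profiles import BinnedProfile

logger = logging.getLogger(__name__)


@dataclass
class SignalSummary:
    """(mean, max, total) of signal over one region; total = mean * n_bins."""

    region: IntervalRecord
    mean: float
    max: float
    total: float
    n_bins: int
    no_data: bool = False


def quantify_regions(
    profile: BinnedProfile, regions: Sequence[IntervalRecord]
) -> tuple[list[SignalSummary], int]:
    """Mean/max/total normalized signal over the bins each region overlaps.

    Regions on chromosomes unknown to the profile's genome are skipped and
    counted; returns (summaries, n_skipped).
    """
    bs = profile.index.bin_size
    if bs is None:
        raise ValueError("bin_size not set on the profile's GenomeIndex")
    out: list[SignalSummary] = []
    skipped = 0
    for region in regions:
        if region.chrom not in profile.index:
            skipped += 1
            continue
        v = profile.values[region.chrom]
        first = region.start // bs
        last = min((region.end - 1) // bs, len(v) - 1)
        window = v[first : last + 1]
        out.append(
            SignalSummary(
                region=region,
                mean=float(window.mean()),
                max=float(window.max()),
                total=float(window.sum()),
                n_bins=len(window),
            )
        )
    return out, skipped


@dataclass
class ConservationTrack:
    """Per-bp conservation scores with an explicit coverage mask.

    Arrays grow to the highest scored position per chromosome; positions
    outside the array or with ``covered`` False are "missing".
    """

    scores: dict[str, np.ndarray] = field(default_factory=dict)
    covered: dict[str, np.ndarray] = field(default_factory=dict)

    def _ensure(self, chrom: str, upto: int) -> None:
        cur = self.scores.get(chrom)
        if cur is None:
            self.scores[chrom] = np.zeros(upto, dtype=float)
            self.covered[chrom] = np.zeros(upto, dtype=bool)
        elif len(cur) < upto:
            grow = upto - len(cur)
            self.scores[chrom] = np.concatenate([cur, np.zeros(grow)])
            self.covered[chrom] = np.concatenate([self.covered[chrom], np.zeros(grow, dtype=bool)])

    def set_block(self, chrom: str, start: int, values: np.ndarray, span: int = 1) -> None:
        """Place values at start, start+span, ... each covering ``span`` bp."""
        end = start + len(values) * span
        self._ensure(chrom, end)
        sc, cv = self.scores[chrom], self.covered[chrom]
        if cv[start:end].any():
            logger.warning("overlapping fixedStep blocks on %s near %d: last writer wins", chrom, start)
        expanded = np.repeat(values, span)
        sc[start:end] = expanded
        cv[start:end] = True

    def window(self, region: IntervalRecord) -> tuple[np.ndarray, np.ndarray]:
        """(scores, covered) over the region, zero/False beyond the track."""
        n = region.end - region.start
        sc = np.zeros(n)
        cv = np.zeros(n, dtype=bool)
        track = self.scores.get(region.chrom)
        if track is not None:
            hi = min(region.end, len(track))
            if hi > region.start:
                m = hi - region.start
                sc[:m] = track[region.start : hi]
                cv[:m] = self.covered[region.chrom][region.start : hi]
        return sc, cv


class WigFormatError(ValueError):
    """Unsupported or malformed wiggle input."""


def load_fixedstep_wig(path: str | Path) -> ConservationTrack:
    """Load a fixedStep WIG (plain or gzip) into a :class:`ConservationTrack`.

    fixedStep ``start`` is 1-based per the WIG spec; scores land at 0-based
    ``start-1, start-1+step, ...``, each covering ``span`` bp.  variableStep
    sections are rejected.  Scores outside [0, 1] draw a warning (PhastCons
    is a probability) but are kept.
    """
    track = ConservationTrack()
    opener = gzip.open if str(path).endswith(".gz") else open
    chrom: str | None = None
    start = step = span = 1
    buffer: list[float] = []

    def flush() -> None:
        nonlocal buffer
        if chrom is None or not buffer:
            buffer = []
            return
        values = np.asarray(buffer)
        if ((values < 0) | (values > 1)).any():
            logger.warning("scores outside [0,1] on %s (PhastCons is a probability)", chrom)
        if step == span:
            track.set_block(chrom, start, values, span=span)
        else:
            for i, value in enumerate(values):
                track.set_block(chrom, start + i * step, np.array([value]), span=span)
        buffer = []

    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep"):
                raise WigFormatError(f"{path}:{lineno}: variableStep is not supported (fixedStep only)")
            if line.startswith("fixedStep"):
                flush()
                attrs = dict(kv.split("=", 1) for kv in line.split()[1:])
                try:
                    chrom = attrs["chrom"]
                    start = int(attrs["start"]) - 1  # WIG is 1-based
                    step = int(attrs.get("step", 1))
                    span = int(attrs.get("span", 1))
                except KeyError as exc:
                    raise WigFormatError(f"{path}:{lineno}: fixedStep missing {exc}") from exc
                if start < 0 or step < 1 or span < 1 or span > step:
                    raise WigFormatError(f"{path}:{lineno}: bad fixedStep attributes")
                continue
            if chrom is None:
                raise WigFormatError(f"{path}:{lineno}: data before any fixedStep declaration")
            buffer.append(float(line))
    flush()
    return track


def score_conservation(
    track: ConservationTrack,
    regions: Sequence[IntervalRecord],
    skip_missing: bool = False,
) -> list[SignalSummary]:
    """Per-region (mean, max, total) of per-bp conservation scores.

    Default treats missing positions as 0; ``skip_missing`` excludes them
    from the mean (a region with zero covered bp is flagged ``no_data``).
    ``total`` is always the sum over scored bp; ``n_bins`` counts the bp that
    entered the mean.
    """
    out: list[SignalSummary] = []
    for region in regions:
        scores, covered = track.window(region)
        total = float(scores[covered].sum())
        if skip_missing:
            if not covered.any():
                out.append(SignalSummary(region, 0.0, 0.0, 0.0, 0, no_data=True))
                continue
            sel = scores[covered]
            out.append(SignalSummary(region, float(sel.mean()), float(sel.max()),
                                     total, int(covered.sum())))
        else:
            vals = np.where(covered, scores, 0.0)
            out.append(SignalSummary(region, float(vals.mean()), float(vals.max()),
                                     total, len(vals)))
    return out
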
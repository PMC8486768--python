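import numpy as np
import pytest

from seqsketch import (
    BinnedProfile,
    GenomeIndex,
    NormalizationSpec,
    ReadInterval,
    TranscriptModel,
)
from seqsketch.fixtures import random_spec, write_all


@pytest.fixture
def toy_index():
    """3 kb single-chromosome genome binned at 10 bp."""
    return GenomeIndex(("chrT",), {"chrT": 3000}, bin_size=10)


@pytest.fixture
def worked_transcript():
    """The hand-checked transcript used across modules.

    + strand, tx [1000,2000), cds [1200,1800), exons [1000,1400) and
    [1600,2000): utr5 [1000,1200), cds [1200,1400)+[1600,1800),
    intron [1400,1600), utr3 [1800,2000).
    """
    return TranscriptModel(
        transcript_id="NM_0001",
        gene_symbol="GeneA",
        chrom="chrT",
        strand="+",
        tx_start=1000,
        tx_end=2000,
        cds_start=1200,
        cds_end=1800,
        exon_starts=(1000, 1600),
        exon_ends=(1400, 2000),
    )


@pytest.fixture
def worked_transcript_minus(worked_transcript):
    """Same coordinates on the − strand (TSS at 1999)."""
    t = worked_transcript
    return TranscriptModel(
        transcript_id="NM_0002",
        gene_symbol="GeneB",
        chrom=t.chrom,
        strand="-",
        tx_start=t.tx_start,
        tx_end=t.tx_end,
        cds_start=t.cds_start,
        cds_end=t.cds_end,
        exon_starts=t.exon_starts,
        exon_ends=t.exon_ends,
    )


@pytest.fixture
def fixture_dir(tmp_path):
    """A full seeded synthetic dataset written to disk."""
    spec = random_spec(7)
    paths = write_all(spec, tmp_path / "fx")
    return spec, paths


def make_profile(index, bins_by_chrom, norm=None):
    """Profile with explicit per-bin values (test helper)."""
    values = {c: np.asarray(v, dtype=float) for c, v in bins_by_chrom.items()}
    return BinnedProfile(
        index=index, values=values,
        normalization=norm or NormalizationSpec("none"),
    )


def read(chrom, start, end, strand="+", read2=False):
    return ReadInterval(chrom, start, end, strand, read2)
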
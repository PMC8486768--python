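import numpy as np
import pytest

from seqsketch import (
    Anchor,
    AnchorSet,
    GenomeIndex,
    NormalizationSpec,
    aggregate,
    aggregate_difference,
    peak_center_anchors,
    pileup,
    resolve_gene_anchors,
)
from seqsketch.intervals import IntervalRecord

from conftest import make_profile, read

NONE = NormalizationSpec("none")


class TestResolveGeneAnchors:
    def test_plus_strand_tss(self, worked_transcript):
        aset, unmatched = resolve_gene_anchors(["GeneA"], [worked_transcript], "TSS")
        assert aset.anchors[0].position == 1000
        assert aset.anchors[0].strand == "+"
        assert not unmatched

    def test_minus_strand_tss_is_last_base(self, worked_transcript_minus):
        aset, _ = resolve_gene_anchors(["GeneB"], [worked_transcript_minus], "TSS")
        assert aset.anchors[0].position == 1999

    def test_unmatched_names_reported(self, worked_transcript):
        _, unmatched = resolve_gene_anchors(["GeneA", "Nope"], [worked_transcript], "TSS")
        assert unmatched == ["Nope"]

    def test_zero_matches_is_error(self, worked_transcript):
        with pytest.raises(ValueError, match="no gene name"):
            resolve_gene_anchors(["Nope"], [worked_transcript], "TSS")

    def test_every_transcript_of_a_gene_contributes(self, worked_transcript):
        twin = worked_transcript.__class__(
            **{**worked_transcript.__dict__, "transcript_id": "NM_0003"}
        )
        aset, _ = resolve_gene_anchors(["GeneA"], [worked_transcript, twin], "TSS")
        assert len(aset.anchors) == 2


class TestPeakCenterAnchors:
    def test_midpoint(self):
        aset = peak_center_anchors([IntervalRecord("c", 100, 200)])
        assert aset.anchors[0].position == 150

    def test_floor_on_odd_width(self):
        aset = peak_center_anchors([IntervalRecord("c", 100, 201)])
        assert aset.anchors[0].position == 150

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peak_center_anchors([])


class TestAggregate:
    def test_single_anchor_zero_flank_is_identity(self, toy_index):
        profile = make_profile(toy_index, {"chrT": [0] * 50 + [7] + [0] * 249})
        aset = AnchorSet("TSS", [Anchor("chrT", 505)], flank_bp=0)
        mp = aggregate(profile, aset)
        assert list(mp.mean_signal) == [7]
        assert mp.n_anchors == 1

    def test_hand_averaged_two_anchors(self, toy_index):
        # windows [1,3] and [3,1] -> mean [2,2]
        v = np.zeros(300)
        v[10], v[11] = 1, 3
        v[20], v[21] = 3, 1
        profile = make_profile(toy_index, {"chrT": v})
        aset = AnchorSet(
            "TSS", [Anchor("chrT", 100), Anchor("chrT", 200)], flank_bp=10
        )
        mp = aggregate(profile, aset)
        # offsets -10, 0, +10 sample bins 9,10,11 and 19,20,21
        np.testing.assert_array_equal(mp.mean_signal, [0.0, 2.0, 2.0])

    def test_minus_strand_window_read_right_to_left(self, toy_index):
        v = np.zeros(300)
        v[9], v[10], v[11] = 1, 2, 3
        profile = make_profile(toy_index, {"chrT": v})
        plus = aggregate(profile, AnchorSet("TSS", [Anchor("chrT", 105, "+")], flank_bp=10))
        minus = aggregate(profile, AnchorSet("TSS", [Anchor("chrT", 105, "-")], flank_bp=10))
        np.testing.assert_array_equal(minus.mean_signal, plus.mean_signal[::-1])

    def test_strand_symmetry_on_mirrored_fixture(self):
        """A − strand gene over mirrored signal contributes identically to its
        + strand twin over the original signal."""
        idx = GenomeIndex(("chrT",), {"chrT": 3000}, bin_size=10)
        rng = np.random.default_rng(11)
        reads = []
        mirrored = []
        L = 3000
        for _ in range(200):
            start = int(rng.integers(0, 2960))
            end = start + int(rng.integers(1, 40))
            reads.append(read("chrT", start, end))
            mirrored.append(read("chrT", L - end, L - start))
        p_fwd = pileup(reads, idx, NONE)
        p_rev = pileup(mirrored, idx, NONE)
        anchor = 1505
        mp_fwd = aggregate(p_fwd, AnchorSet("TSS", [Anchor("chrT", anchor, "+")], flank_bp=200))
        mp_rev = aggregate(p_rev, AnchorSet("TSS", [Anchor("chrT", L - 1 - anchor, "-")], flank_bp=200))
        np.testing.assert_array_equal(mp_fwd.mean_signal, mp_rev.mean_signal)

    def test_translation_invariance_by_one_bin(self, toy_index):
        reads = [read("chrT", 100, 140), read("chrT", 300, 350)]
        shifted = [read("chrT", 110, 150), read("chrT", 310, 360)]
        p0 = pileup(reads, toy_index, NONE)
        p1 = pileup(shifted, toy_index, NONE)
        mp0 = aggregate(p0, AnchorSet("TSS", [Anchor("chrT", 120)], flank_bp=50))
        mp1 = aggregate(p1, AnchorSet("TSS", [Anchor("chrT", 130)], flank_bp=50))
        np.testing.assert_array_equal(mp0.mean_signal, mp1.mean_signal)

    def test_out_of_bounds_anchors_dropped_and_counted(self, toy_index):
        profile = make_profile(toy_index, {"chrT": np.ones(300)})
        aset = AnchorSet("TSS", [Anchor("chrT", 5), Anchor("chrT", 1500)], flank_bp=100)
        mp = aggregate(profile, aset)
        assert mp.n_anchors == 1 and mp.n_dropped == 1

    def test_all_anchors_dropped_is_error(self, toy_index):
        profile = make_profile(toy_index, {"chrT": np.ones(300)})
        aset = AnchorSet("TSS", [Anchor("chrT", 5)], flank_bp=100)
        with pytest.raises(ValueError, match="dropped"):
            aggregate(profile, aset)


class TestGeneBodyAggregate:
    def test_exact_multiple_length_reproduces_block_means(self, toy_index):
        # gene [1000, 1400): 40 bins of 10 bp, body_bins=4 -> 10 bins per slice
        v = np.zeros(300)
        v[100:110] = 1  # slice 0
        v[110:120] = 2
        v[120:130] = 3
        v[130:140] = 4
        profile = make_profile(toy_index, {"chrT": v})
        aset = AnchorSet(
            "GENE_BODY",
            [Anchor("chrT", -1, "+", "g", start=1000, end=1400)],
            flank_bp=0,
            body_bins=4,
        )
        mp = aggregate(profile, aset)
        np.testing.assert_array_equal(mp.mean_signal, [1, 2, 3, 4])

    def test_minus_strand_body_reversed(self, toy_index):
        v = np.zeros(300)
        v[100:120] = 1
        profile = make_profile(toy_index, {"chrT": v})
        plus = AnchorSet("GENE_BODY", [Anchor("chrT", -1, "+", "g", start=1000, end=1400)],
                         flank_bp=0, body_bins=4)
        minus = AnchorSet("GENE_BODY", [Anchor("chrT", -1, "-", "g", start=1000, end=1400)],
                          flank_bp=0, body_bins=4)
        np.testing.assert_array_equal(
            aggregate(profile, minus).mean_signal,
            aggregate(profile, plus).mean_signal[::-1],
        )

    def test_flanks_appended_unscaled(self, toy_index):
        profile = make_profile(toy_index, {"chrT": np.arange(300.0)})
        aset = AnchorSet("GENE_BODY", [Anchor("chrT", -1, "+", "g", start=1000, end=1400)],
                         flank_bp=20, body_bins=4)
        mp = aggregate(profile, aset)
        assert len(mp.positions) == 4 + 2 + 2
        # upstream flank bins 98, 99; downstream bins 140, 141
        assert list(mp.mean_signal[:2]) == [98, 99]
        assert list(mp.mean_signal[-2:]) == [140, 141]


class TestAggregateDifference:
    def test_self_subtraction_is_flat_zero(self, toy_index):
        p = pileup([read("chrT", 100, 150)], toy_index, NONE)
        aset = AnchorSet("TSS", [Anchor("chrT", 120)], flank_bp=50)
        mp = aggregate_difference(p, p, aset)
        assert not mp.mean_signal.any()

    def test_zero_subtrahend_is_identity(self, toy_index):
        p = pileup([read("chrT", 100, 150)], toy_index, NONE)
        z = pileup([], toy_index, NONE)
        aset = AnchorSet("TSS", [Anchor("chrT", 120)], flank_bp=50)
        np.testing.assert_array_equal(
            aggregate_difference(p, z, aset).mean_signal,
            aggregate(p, aset).mean_signal,
        )

    def test_linearity_of_the_mean(self, toy_index):
        a = pileup([read("chrT", 100, 150), read("chrT", 110, 160)], toy_index, NONE)
        b = pileup([read("chrT", 130, 170)], toy_index, NONE)
        aset = AnchorSet("TSS", [Anchor("chrT", 120), Anchor("chrT", 140)], flank_bp=50)
        np.testing.assert_allclose(
            aggregate_difference(a, b, aset).mean_signal,
            aggregate(a, aset).mean_signal - aggregate(b, aset).mean_signal,
        )
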
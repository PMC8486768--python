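import numpy as np
import pytest

from seqsketch import (
    FeatureDistribution,
    GenomeIndex,
    IntervalRecord,
    classify_peaks,
    decompose_gene_features,
    genome_reference_distribution,
    match_peaks,
    match_peaks_genes,
    spie_chart_data,
)


@pytest.fixture
def worked_segments(worked_transcript, toy_index):
    return decompose_gene_features([worked_transcript], toy_index, proximal_bp=2500)


class TestClassifyPeaks:
    def test_peak_straddling_promoter_and_utr5_multi_counted(self, worked_segments):
        dist, (ann,) = classify_peaks(
            [IntervalRecord("chrT", 900, 1100)], worked_segments
        )
        assert set(ann.categories) == {"promoter_proximal", "utr5"}
        assert dist.counts["promoter_proximal"] == 1
        assert dist.counts["utr5"] == 1

    def test_peak_outside_everything_is_intergenic(self, toy_index):
        # no transcripts at all: every peak is intergenic
        dist, _ = classify_peaks([IntervalRecord("chrT", 0, 50)], [])
        assert dist.counts == {"intergenic": 1}

    def test_duplicate_peaks_double_every_count(self, worked_segments):
        peak = IntervalRecord("chrT", 900, 1100)
        single, _ = classify_peaks([peak], worked_segments)
        double, _ = classify_peaks([peak, peak], worked_segments)
        assert double.counts == {c: 2 * n for c, n in single.counts.items()}

    def test_single_category_peaks_sum_to_n_peaks(self, worked_segments):
        peaks = [
            IntervalRecord("chrT", 1250, 1300),   # inside CDS exon 1
            IntervalRecord("chrT", 1450, 1550),   # inside intron
            IntervalRecord("chrT", 2950, 2990),   # beyond downstream band
        ]
        dist, anns = classify_peaks(peaks, worked_segments)
        assert all(len(a.categories) == 1 for a in anns)
        assert sum(dist.counts.values()) == dist.n_peaks == 3

    def test_basic_detail_collapses_categories(self, worked_segments):
        dist, (ann,) = classify_peaks(
            [IntervalRecord("chrT", 900, 1100)], worked_segments, detail="basic"
        )
        assert set(ann.categories) == {"promoter", "intragenic"}

    def test_downstream_folds_into_intergenic_at_basic_detail(self, worked_segments):
        dist, (ann,) = classify_peaks(
            [IntervalRecord("chrT", 2010, 2020)], worked_segments, detail="basic"
        )
        assert ann.categories == ("intergenic",)

    def test_counts_additive_over_disjoint_union(self, worked_segments):
        a = [IntervalRecord("chrT", 900, 1100), IntervalRecord("chrT", 1450, 1550)]
        b = [IntervalRecord("chrT", 2500, 2600)]
        da, _ = classify_peaks(a, worked_segments)
        db, _ = classify_peaks(b, worked_segments)
        dab, _ = classify_peaks(a + b, worked_segments)
        merged = dict(da.counts)
        for c, n in db.counts.items():
            merged[c] = merged.get(c, 0) + n
        assert dab.counts == merged

    def test_empty_peak_list_rejected(self, worked_segments):
        with pytest.raises(ValueError, match="empty"):
            classify_peaks([], worked_segments)


class TestSpieChartData:
    def test_sample_equal_reference_gives_unit_radii(self):
        sample = FeatureDistribution({"a": 30, "b": 70}, 100)
        reference = FeatureDistribution({"a": 300, "b": 700}, 1000)
        spie = spie_chart_data(sample, reference)
        np.testing.assert_allclose(spie.radii, 1.0)
        assert spie.angles.sum() == pytest.approx(2 * np.pi)

    def test_fourfold_enrichment_gives_radius_two(self):
        sample = FeatureDistribution({"a": 4, "b": 6}, 10)
        reference = FeatureDistribution({"a": 10, "b": 90}, 100)
        spie = spie_chart_data(sample, reference)
        assert spie.radii[spie.categories.index("a")] == pytest.approx(2.0)

    def test_category_missing_from_sample_has_radius_zero(self):
        sample = FeatureDistribution({"a": 10}, 10)
        reference = FeatureDistribution({"a": 50, "b": 50}, 100)
        spie = spie_chart_data(sample, reference)
        assert spie.radii[spie.categories.index("b")] == 0.0

    def test_zero_reference_categories_excluded(self):
        sample = FeatureDistribution({"a": 5, "b": 5}, 10)
        reference = FeatureDistribution({"a": 100, "b": 0}, 100)
        spie = spie_chart_data(sample, reference)
        assert spie.excluded == ["b"]
        assert "b" not in spie.categories

    def test_disjoint_category_sets_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            spie_chart_data(
                FeatureDistribution({"x": 1}, 1), FeatureDistribution({"y": 1}, 1)
            )

    def test_genome_reference_accounts_for_every_bp(self, worked_transcript, toy_index):
        segments = decompose_gene_features(
            [worked_transcript], toy_index, proximal_bp=200, distal_bp=400,
            downstream_bp=200,
        )
        ref = genome_reference_distribution(segments, toy_index)
        # intergenic = genome remainder: 3000 - (400 promoter + 1000 gene + 200 down)
        assert ref.counts["intergenic"] == 3000 - 1600
        assert all(n <= toy_index.total_length for n in ref.counts.values())


def brute_force_match(a, b, min_overlap=1):
    common = []
    a_hit, b_hit = set(), set()
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            if pa.chrom != pb.chrom:
                continue
            lo, hi = max(pa.start, pb.start), min(pa.end, pb.end)
            if hi - lo >= min_overlap:
                common.append((pa.chrom, lo, hi))
                a_hit.add(i)
                b_hit.add(j)
    return (
        sorted(common),
        [p for i, p in enumerate(a) if i not in a_hit],
        [p for j, p in enumerate(b) if j not in b_hit],
    )


def random_peaks(rng, n, chroms=("chr1", "chr2"), length=5000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, length - 200))
        out.append(IntervalRecord(chrom, start, start + int(rng.integers(1, 200))))
    return out


class TestMatchPeaks:
    def test_single_overlapping_pair(self):
        a = [IntervalRecord("c", 100, 200)]
        b = [IntervalRecord("c", 150, 250)]
        common, a_only, b_only = match_peaks(a, b)
        assert [(p.start, p.end) for p in common] == [(150, 200)]
        assert not a_only and not b_only

    def test_non_overlapping_a_peak_reported_whole(self):
        a = [IntervalRecord("c", 100, 200), IntervalRecord("c", 300, 400)]
        b = [IntervalRecord("c", 150, 250)]
        _, a_only, _ = match_peaks(a, b)
        assert a_only == [IntervalRecord("c", 300, 400)]

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = random_peaks(rng, 30), random_peaks(rng, 30)
        common_ab, a_only, b_only = match_peaks(a, b)
        common_ba, b_only2, a_only2 = match_peaks(b, a)
        assert {(p.chrom, p.start, p.end) for p in common_ab} == {
            (p.chrom, p.start, p.end) for p in common_ba
        }
        assert a_only == a_only2 and b_only == b_only2

    def test_min_overlap_threshold(self):
        a = [IntervalRecord("c", 100, 200)]
        b = [IntervalRecord("c", 195, 300)]
        common, a_only, _ = match_peaks(a, b, min_overlap_bp=10)
        assert not common and a_only == a

    @pytest.mark.parametrize("seed", range(10))
    def test_sweep_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, int(rng.integers(1, 40)))
        b = random_peaks(rng, int(rng.integers(1, 40)))
        common, a_only, b_only = match_peaks(a, b)
        bf_common, bf_a_only, bf_b_only = brute_force_match(a, b)
        assert sorted((p.chrom, p.start, p.end) for p in common) == bf_common
        assert a_only == bf_a_only and b_only == bf_b_only
        assert len(a) == (len(a) - len(a_only)) + len(a_only)


class TestMatchPeaksGenes:
    def test_peak_at_window_edge_linked_with_signed_distance(self, worked_transcript):
        links, genes = match_peaks_genes(
            [IntervalRecord("chrT", 3000, 3600)], [worked_transcript], tss_window_bp=2500
        )
        assert genes == ["GeneA"]
        (link,) = links
        assert link.rule_hit == "tss_window"
        assert link.distance == 2000     # nearest peak bp 3000, TSS 1000
        assert abs(link.distance) <= 2500

    def test_peak_beyond_window_not_linked(self, worked_transcript):
        links, _ = match_peaks_genes(
            [IntervalRecord("chrT", 3600, 3700)], [worked_transcript],
            tss_window_bp=2500,
        )
        assert not links

    def test_upstream_distance_negative_in_gene_orientation(self, worked_transcript):
        (link,), _ = match_peaks_genes(
            [IntervalRecord("chrT", 400, 500)], [worked_transcript], tss_window_bp=600
        )
        assert link.distance == -501     # nearest bp 499, upstream of TSS 1000

    def test_minus_strand_distance_sign_flips(self, worked_transcript_minus):
        # TSS at 1999; peak downstream in genome but upstream in gene orientation
        (link,), _ = match_peaks_genes(
            [IntervalRecord("chrT", 2500, 2600)], [worked_transcript_minus],
            tss_window_bp=600,
        )
        assert link.distance == -501

    def test_zero_window_links_only_tss_covering_peaks(self, worked_transcript):
        covering = IntervalRecord("chrT", 990, 1010)
        adjacent = IntervalRecord("chrT", 1001, 1010)
        links, _ = match_peaks_genes([covering, adjacent], [worked_transcript],
                                     tss_window_bp=0)
        assert [ln.peak for ln in links] == [covering]
        assert links[0].distance == 0

    def test_monotone_in_window_size(self, worked_transcript, worked_transcript_minus):
        rng = np.random.default_rng(8)
        peaks = random_peaks(rng, 40, chroms=("chrT",), length=3000)
        transcripts = [worked_transcript, worked_transcript_minus]
        previous = set()
        for w in (0, 100, 500, 1000, 2500):
            links, _ = match_peaks_genes(peaks, transcripts, tss_window_bp=w)
            current = {(id(ln.peak), ln.transcript_id) for ln in links}
            assert previous <= current
            previous = current

    def test_gene_body_rule(self, worked_transcript):
        peak = IntervalRecord("chrT", 1700, 1750)  # inside the gene, 700 bp from TSS
        no_body, _ = match_peaks_genes([peak], [worked_transcript], tss_window_bp=100)
        with_body, _ = match_peaks_genes([peak], [worked_transcript], tss_window_bp=100,
                                         include_gene_body=True)
        assert not no_body
        assert with_body[0].rule_hit == "gene_body"
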
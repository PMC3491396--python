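"""Multi-sample comparison: overlap matrices, specific/common sets,
enhancers, nearest-TSS annotation, and target-gene summaries."""

import numpy as np
import pytest

from cobind.compare import (
    NearestTssRecord,
    active_enhancers,
    annotate_nearest_tss,
    cell_specific_peaks,
    common_peaks,
    enhancer_occupancy,
    pairwise_overlap_matrix,
    target_gene_summary,
    tss_distance_profile,
)
from cobind.core import GeneAnnotation, GenomicInterval, Peak, PeakSet
from cobind.peaks import AmplifiedRegion


def _ps(starts, label="", width=100, chrom="chr1"):
    return PeakSet(
        [Peak(GenomicInterval(chrom, s, s + width), summit=s + width // 2, score=10.0) for s in starts],
        label=label,
    )


class TestOverlapMatrix:
    def test_identical_sets(self):
        a = _ps([0, 1000], "a")
        b = _ps([0, 1000], "b")
        om = pairwise_overlap_matrix([a, b])
        np.testing.assert_allclose(om.matrix, [[1, 1], [1, 1]])

    def test_subset_asymmetry(self):
        a = _ps(range(0, 5000, 1000), "a")  # 5 peaks
        b = _ps(range(0, 10_000, 1000), "b")  # 10 peaks, superset loci
        om = pairwise_overlap_matrix([a, b])
        assert om.matrix[0, 1] == 1.0
        assert om.matrix[1, 0] == 0.5

    def test_disjoint_off_diagonal_zero(self):
        om = pairwise_overlap_matrix([_ps([0], "a"), _ps([5000], "b")])
        assert om.matrix[0, 1] == 0.0 and om.matrix[1, 0] == 0.0

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            pairwise_overlap_matrix([_ps([0]), PeakSet([])])


class TestCellSpecific:
    def test_identity_when_nothing_to_remove(self):
        t = _ps([0, 1000, 2000])
        assert len(cell_specific_peaks(t, [], [])) == 3

    def test_removes_shared_and_amplified(self):
        t = _ps([0, 1000, 2000])
        others = [_ps([1000])]
        amp = [AmplifiedRegion(GenomicInterval("chr1", 1990, 3000), 4.0)]
        out = cell_specific_peaks(t, others, amp)
        assert [p.interval.start for p in out] == [0]

    def test_fully_covered_target_empty(self):
        t = _ps([0, 1000])
        assert len(cell_specific_peaks(t, [_ps([0, 1000])], [])) == 0

    def test_partition_conservation(self, factor_peaks, amplified_regions):
        target = factor_peaks["focal"]
        others = [factor_peaks["partner"]]
        specific = cell_specific_peaks(target, others, amplified_regions)
        amp = [r.interval for r in amplified_regions]
        removed = sum(
            1
            for p in target
            if any(o.overlaps_any(p.interval) for o in others)
            or any(iv.chrom == p.chrom and min(iv.end, p.interval.end) > max(iv.start, p.interval.start) for iv in amp)
        )
        assert len(specific) + removed == len(target)


class TestCommonPeaks:
    def test_identical_sets_return_anchor(self):
        sets = [_ps([0, 1000], "a"), _ps([0, 1000], "b"), _ps([0, 1000], "c")]
        assert len(common_peaks(sets)) == 2

    def test_single_shared_locus(self):
        sets = [_ps([0, 1000, 2000]), _ps([1000, 5000]), _ps([1000, 7000])]
        out = common_peaks(sets)
        assert [p.interval.start for p in out] == [1000]

    def test_any_empty_set_gives_empty(self):
        assert len(common_peaks([_ps([0]), PeakSet([])])) == 0

    def test_adding_sets_never_grows_result(self):
        sets = [_ps([0, 1000, 2000]), _ps([0, 1000])]
        base = len(common_peaks(sets))
        assert len(common_peaks(sets + [_ps([0])])) <= base


class TestActiveEnhancers:
    def test_no_overlap_empty(self):
        assert active_enhancers(_ps([0]), _ps([5000])) == []

    def test_merged_span(self):
        k4 = PeakSet([Peak(GenomicInterval("chr1", 0, 1000), 500, 5.0)])
        k27 = PeakSet([Peak(GenomicInterval("chr1", 500, 1500), 1000, 5.0)])
        assert active_enhancers(k4, k27) == [GenomicInterval("chr1", 0, 1500)]

    def test_nested_takes_outer_span(self):
        k4 = PeakSet([Peak(GenomicInterval("chr1", 0, 2000), 1000, 5.0)])
        k27 = PeakSet([Peak(GenomicInterval("chr1", 500, 800), 600, 5.0)])
        assert active_enhancers(k4, k27) == [GenomicInterval("chr1", 0, 2000)]

    def test_every_enhancer_covered_by_both_marks(self, bundle, factor_peaks):
        from cobind.peaks import call_peaks

        libs, chrl = bundle["libs"], bundle["chrom_lengths"]
        k4 = call_peaks(libs["h3k4me1"], libs["input"], bin_width=500, min_height=8, chrom_lengths=chrl)
        k27 = call_peaks(libs["h3k27ac"], libs["input"], bin_width=500, min_height=8, chrom_lengths=chrl)
        for iv in active_enhancers(k4, k27):
            assert k4.overlaps_any(iv) and k27.overlaps_any(iv)


class TestEnhancerOccupancy:
    def test_all_peaks_inside_enhancers(self):
        k4 = PeakSet([Peak(GenomicInterval("chr1", 0, 2000), 1000, 5.0)])
        k27 = PeakSet([Peak(GenomicInterval("chr1", 0, 2000), 1000, 5.0)])
        peaks = _ps([500, 1200], width=100)
        occ = enhancer_occupancy(peaks, k4, k27)
        assert occ["pct_peaks_at_k4me1"] == 100.0
        assert occ["pct_peaks_at_enhancers"] == 100.0

    def test_no_enhancers_signalled(self):
        with pytest.raises(ValueError):
            enhancer_occupancy(_ps([0]), _ps([5000]), _ps([9000]))

    def test_synthetic_bundle_matches_planted_fraction(self, bundle, factor_peaks):
        """~60% of sites sit in enhancers, so ~60% of focal peaks do too."""
        from cobind.peaks import call_peaks

        libs, chrl = bundle["libs"], bundle["chrom_lengths"]
        k4 = call_peaks(libs["h3k4me1"], libs["input"], bin_width=500, min_height=8, chrom_lengths=chrl)
        k27 = call_peaks(libs["h3k27ac"], libs["input"], bin_width=500, min_height=8, chrom_lengths=chrl)
        occ = enhancer_occupancy(factor_peaks["focal"], k4, k27)
        planted_pct = 100 * bundle["config"].enhancer_fraction
        assert abs(occ["pct_peaks_at_enhancers"] - planted_pct) <= 5


def _gene(gid, tss, strand="+", chrom="chr1"):
    span = GenomicInterval(chrom, tss, tss + 5000, strand) if strand == "+" else GenomicInterval(chrom, max(0, tss - 5000), tss + 1, strand)
    return GeneAnnotation(gid, chrom, strand, tss, span)


class TestNearestTss:
    def test_peak_at_tss_distance_zero(self):
        recs = annotate_nearest_tss(_ps([950]), [_gene("g1", 1000)])
        assert recs[0].gene_id == "g1" and recs[0].distance == 0

    def test_upstream_of_plus_strand_is_negative(self):
        genes = [_gene("near", 10_000), _gene("far", 110_000)]
        recs = annotate_nearest_tss(_ps([4950]), genes)  # center 5,000
        assert recs[0].gene_id == "near"
        assert recs[0].distance == -5000

    def test_downstream_sign_respects_gene_strand(self):
        recs = annotate_nearest_tss(_ps([1950]), [_gene("g", 1000, strand="-")])
        # center 2000 is 1 kb past the TSS but upstream in gene orientation
        assert recs[0].distance == -1000

    def test_equidistant_tie_broken_lexicographically(self):
        genes = [_gene("b", 2000), _gene("a", 0)]
        recs = annotate_nearest_tss(_ps([950]), genes)  # center 1000, both 1 kb away
        assert recs[0].gene_id == "a"

    def test_empty_annotation_error(self):
        with pytest.raises(ValueError):
            annotate_nearest_tss(_ps([0]), [])


class TestTargetSummary:
    @pytest.mark.parametrize(
        "total,genes,expected",
        [(116_270, 14_193, 8.2), (1_864, 1_287, 1.4), (30_259, 10_910, 2.8), (52_810, 11_334, 4.7)],
    )
    def test_printed_count_pairs(self, total, genes, expected):
        """Peaks-per-gene ratios recomputed from published count pairs."""
        recs = [
            NearestTssRecord("chr1", i, f"g{i % genes}", 0, "0-1kb") for i in range(total)
        ]
        assert target_gene_summary(recs).peaks_per_gene == expected

    def test_each_peak_own_gene(self):
        recs = [NearestTssRecord("chr1", i, f"g{i}", 0, "0-1kb") for i in range(7)]
        s = target_gene_summary(recs)
        assert s.peaks_per_gene == 1.0 and s.nearest_gene_count == 7


class TestTssDistanceProfile:
    def test_percentages_sum_to_100(self, factor_peaks, bundle):
        recs = annotate_nearest_tss(factor_peaks["focal"], bundle["truth"].genes)
        prof = tss_distance_profile(recs)
        assert sum(prof.percentages) == pytest.approx(100.0, abs=0.1)
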
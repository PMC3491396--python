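"""Overlap-class partition, class-wise motif enrichment, the tethering
verdict, and knockdown co-regulation classification."""

import numpy as np
import pytest

from cobind.compare import NearestTssRecord, annotate_nearest_tss
from cobind.core import GenomicInterval, Peak, PeakSet
from cobind.motifs import ConsensusMotif
from cobind.tethering import (
    EnrichmentResult,
    call_tethering,
    class_motif_enrichment,
    classify_coregulation,
    cobound_gene_set,
    partition_overlap_classes,
)


def _ps(starts, label="", width=100, chrom="chr1"):
    return PeakSet(
        [Peak(GenomicInterval(chrom, s, s + width), summit=s + width // 2, score=10.0) for s in starts],
        label=label,
    )


class TestPartition:
    def test_identical_sets_all_shared(self):
        a = _ps([0, 1000], "A")
        classes = partition_overlap_classes(a, _ps([0, 1000], "B"))
        assert len(classes.a_only) == 0 and len(classes.shared) == 2

    def test_counts_on_partial_overlap(self):
        a = _ps(range(0, 10_000, 1000), "A")  # 10 peaks
        b = _ps([0, 1000, 2000, 3000, 50_000], "B")
        classes = partition_overlap_classes(a, b)
        assert len(classes.shared) == 4
        assert len(classes.a_only) == 6
        assert len(classes.b_only) == 1

    def test_disjoint_sets_no_shared(self):
        classes = partition_overlap_classes(_ps([0]), _ps([5000]))
        assert len(classes.shared) == 0

    def test_cardinality_conservation(self, factor_peaks):
        a, b = factor_peaks["focal"], factor_peaks["partner"]
        classes = partition_overlap_classes(a, b)
        assert len(classes.a_only) + len(classes.shared) == len(a)


class TestClassEnrichment:
    def test_planted_word_fully_enriched(self, rng):
        """Focal word at every a_only center: fraction 1, tiny q."""
        L = 200_000
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        a_starts = list(range(1000, 60_000, 2000))
        for s in a_starts:
            c = s + 50
            genome = genome[:c] + "GCTTTGAA" + genome[c + 8 :]
        b_starts = list(range(100_000, 150_000, 2000))
        table = class_motif_enrichment(
            partition_overlap_classes(_ps(a_starts, "A"), _ps(b_starts, "B")),
            [ConsensusMotif("focal", "SCTTTGAW")],
            {"chr1": genome},
            seed=4,
        )
        row = next(r for r in table if r.class_label == "a_only")
        assert row.fraction_with_motif == 1.0
        assert row.q_value < 1e-6

    def test_null_not_enriched_across_seeds(self):
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            genome = "".join("ACGT"[i] for i in r.integers(0, 4, 100_000))
            a = _ps(range(1000, 40_000, 2000), "A")
            b = _ps(range(60_000, 90_000, 2000), "B")
            table = class_motif_enrichment(
                partition_overlap_classes(a, b),
                [ConsensusMotif("focal", "SCTTTGAW")],
                {"chr1": genome},
                seed=seed,
            )
            if all(r_.q_value >= 0.05 for r_ in table):
                ok += 1
        assert ok >= 9

    def test_empty_class_omitted_with_warning(self, rng):
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))}
        classes = partition_overlap_classes(_ps([1000]), _ps([1000]))  # a_only empty
        with pytest.warns(UserWarning, match="a_only"):
            table = class_motif_enrichment(classes, [ConsensusMotif("m", "WGATAR")], genome, seed=0)
        assert {r.class_label for r in table} == {"shared"}


def _row(cls, motif, frac, bg, q):
    fold = frac / bg if bg else float("inf")
    return EnrichmentResult(cls, motif, 50, frac, bg, fold, q / 2, q)


class TestCallTethering:
    def test_tethered_pattern(self):
        table = [
            _row("a_only", "focal", 0.9, 0.05, 1e-10),
            _row("a_only", "partner", 0.2, 0.18, 0.6),
            _row("shared", "focal", 0.06, 0.05, 0.7),
            _row("shared", "partner", 0.95, 0.15, 1e-12),
        ]
        assert call_tethering(table, "focal", "partner").verdict == "tethered_via_partner"

    def test_adjacent_pattern(self):
        table = [
            _row("a_only", "focal", 0.9, 0.05, 1e-10),
            _row("a_only", "partner", 0.2, 0.18, 0.6),
            _row("shared", "focal", 0.9, 0.05, 1e-11),
            _row("shared", "partner", 0.95, 0.15, 1e-12),
        ]
        assert call_tethering(table, "focal", "partner").verdict == "direct_co_occupancy"

    def test_null_pattern_indeterminate(self):
        table = [
            _row("a_only", "focal", 0.06, 0.05, 0.5),
            _row("shared", "focal", 0.06, 0.05, 0.6),
            _row("shared", "partner", 0.2, 0.18, 0.4),
        ]
        assert call_tethering(table, "focal", "partner").verdict == "indeterminate"

    def test_missing_row_is_error(self):
        with pytest.raises(ValueError, match="lacks row"):
            call_tethering([_row("shared", "partner", 0.9, 0.1, 1e-9)], "focal", "partner")

    def test_pure_function(self):
        table = [
            _row("a_only", "focal", 0.9, 0.05, 1e-10),
            _row("shared", "focal", 0.06, 0.05, 0.7),
            _row("shared", "partner", 0.95, 0.15, 1e-12),
        ]
        v1 = call_tethering(table, "focal", "partner")
        v2 = call_tethering(list(table), "focal", "partner")
        assert v1.verdict == v2.verdict and v1.thresholds == v2.thresholds

    def test_end_to_end_mode_recovery(self):
        """Across seeded simulations the verdict matches the generating mode."""
        from cobind.peaks import call_peaks
        from cobind.simulate import SimConfig, generate_reads, plant_sites

        def run_mode(cfg, seed):
            genome, truth = plant_sites(cfg, seed)
            libs = generate_reads(truth, cfg, seed)
            chrl = {c: cfg.chrom_length for c in genome}
            f = call_peaks(libs["focal_rep1"].merge(libs["focal_rep2"]), libs["input"], chrom_lengths=chrl)
            p = call_peaks(libs["partner_rep1"].merge(libs["partner_rep2"]), libs["input"], chrom_lengths=chrl)
            table = class_motif_enrichment(
                partition_overlap_classes(f, p),
                [ConsensusMotif("focal", cfg.focal_motif), ConsensusMotif("partner", cfg.partner_motif)],
                genome,
                seed=seed,
            )
            return call_tethering(table, "focal", "partner").verdict

        teth = SimConfig(n_adjacent=0, n_direct=80, n_tethered=80, n_partner_only=40)
        adj = SimConfig(n_tethered=0, n_direct=80, n_adjacent=80, n_partner_only=40)
        teth_hits = sum(run_mode(teth, s) == "tethered_via_partner" for s in range(1, 11))
        adj_hits = sum(run_mode(adj, s) == "direct_co_occupancy" for s in range(1, 11))
        assert teth_hits >= 9
        assert adj_hits >= 9


class TestCoboundGenes:
    def test_intersection(self):
        a = [NearestTssRecord("chr1", 0, g, 0, "0-1kb") for g in ("g1", "g2", "g3")]
        b = [NearestTssRecord("chr1", 0, g, 0, "0-1kb") for g in ("g2", "g3", "g4")]
        assert cobound_gene_set(a, b) == ["g2", "g3"]

    def test_disjoint_empty(self):
        a = [NearestTssRecord("chr1", 0, "g1", 0, "0-1kb")]
        b = [NearestTssRecord("chr1", 0, "g2", 0, "0-1kb")]
        assert cobound_gene_set(a, b) == []

    def test_on_bundle_includes_tethered_targets(self, bundle, factor_peaks):
        genes = bundle["truth"].genes
        a = annotate_nearest_tss(factor_peaks["focal"], genes)
        b = annotate_nearest_tss(factor_peaks["partner"], genes)
        cobound = set(cobound_gene_set(a, b))
        up_up = {g for g, v in bundle["truth"].expression_effects.items() if v == ("up", "up")}
        assert len(up_up & cobound) / len(up_up) >= 0.7


class TestCoRegulation:
    @pytest.mark.parametrize(
        "focal,partner,category",
        [
            ("up", "up", "cooperative_repression"),
            ("up", "down", "partner_activation_antagonized"),
            ("down", "down", "cooperative_activation"),
            ("down", "up", "focal_activation_antagonized"),
            ("ns", "up", "unclassified"),
            ("up", "ns", "unclassified"),
        ],
    )
    def test_category_mapping(self, focal, partner, category):
        calls = classify_coregulation(["g"], {"g": focal}, {"g": partner})
        assert calls[0].category == category

    def test_missing_gene_treated_as_ns(self):
        calls = classify_coregulation(["g"], {}, {})
        assert calls[0].category == "unclassified"

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="unknown direction"):
            classify_coregulation(["g"], {"g": "higher"}, {"g": "up"})

    def test_every_gene_gets_exactly_one_category(self, bundle):
        effects = bundle["truth"].expression_effects
        genes = sorted(effects)
        calls = classify_coregulation(
            genes, {g: v[0] for g, v in effects.items()}, {g: v[1] for g, v in effects.items()}
        )
        assert [c.gene_id for c in calls] == genes
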
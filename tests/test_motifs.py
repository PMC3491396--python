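"""Consensus scanning, dinucleotide shuffling, k-mer discovery, recovery
curves, and density profiles."""

import numpy as np
import pytest

from cobind.core import GenomicInterval, Peak, PeakSet
from cobind.motifs import (
    IUPAC,
    ConsensusMotif,
    canonical_kmer,
    consensus_scan,
    dinucleotide_shuffle,
    instantiate_iupac,
    kmer_discovery,
    motif_density_profile,
    motif_recovery_curve,
    reverse_complement,
)


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestConsensusScan:
    def test_tcf_consensus_matches(self):
        hits = consensus_scan("GCTTTGAA", ConsensusMotif("tcf", "SCTTTGAW"), both_strands=False)
        assert [h.position for h in hits] == [0]

    def test_gata_consensus_matches(self):
        hits = consensus_scan("TGATAA", ConsensusMotif("gata", "WGATAR"), both_strands=False)
        assert [h.position for h in hits] == [0]

    def test_reverse_complement_hit(self):
        hits = consensus_scan("TTCAAAG", ConsensusMotif("w1", "CTTTGA"))
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_invalid_sequence_letters_rejected(self):
        with pytest.raises(ValueError):
            consensus_scan("ACGU", ConsensusMotif("m", "ACGT"))

    def test_n_matched_only_by_tolerant_letters(self):
        assert consensus_scan("ANT", ConsensusMotif("m", "AWT"), both_strands=False) == []
        assert len(consensus_scan("ANT", ConsensusMotif("m", "ANT"), both_strands=False)) == 1

    def test_agrees_with_naive_matcher_on_random_strings(self, rng):
        """Oracle equivalence against per-position set matching."""

        def naive(seq, iupac, both):
            hits = set()
            pats = [iupac] + ([reverse_complement(iupac)] if both and reverse_complement(iupac) != iupac else [])
            for strand, pat in zip("+-", pats):
                for i in range(len(seq) - len(pat) + 1):
                    if all(seq[i + j] in IUPAC[c].replace("N", "ACGTN") for j, c in enumerate(pat)):
                        hits.add((i, strand))
            return hits

        for motif in ("SCTTTGAW", "WGATAR", "CTTTGA", "NRYSWN"):
            for _ in range(5):
                seq = _rand_seq(rng, int(rng.integers(200, 2000)))
                got = {(h.position, h.strand) for h in consensus_scan(seq, ConsensusMotif("m", motif))}
                assert got == naive(seq, motif, True)

    def test_instantiation_always_matches_consensus(self, rng):
        m = ConsensusMotif("m", "SCTTTGAW")
        for _ in range(20):
            word = instantiate_iupac(m.iupac, rng)
            assert consensus_scan(word, m, both_strands=False)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out

        for _ in range(20):
            seq = _rand_seq(rng, 300)
            shuf = dinucleotide_shuffle(seq, rng)
            assert dinucs(shuf) == dinucs(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_actually_shuffles(self, rng):
        seq = _rand_seq(rng, 500)
        assert any(dinucleotide_shuffle(seq, rng) != seq for _ in range(3))


class TestKmerDiscovery:
    def test_null_fg_equals_bg(self, rng):
        seqs = [_rand_seq(rng, 200) for _ in range(100)]
        res = kmer_discovery(seqs, list(seqs), k=6)
        assert all(r.q_value >= 0.05 for r in res)

    def test_planted_6mer_recovered(self, rng):
        fg = []
        for i in range(500):
            s = _rand_seq(rng, 300)
            if i < 300:  # 60%
                pos = int(rng.integers(0, 294))
                s = s[:pos] + "CTTTGA" + s[pos + 6 :]
            fg.append(s)
        res = kmer_discovery(fg, None, k=6, seed=11)
        assert res[0].kmer == canonical_kmer("CTTTGA")
        assert res[0].q_value < 1e-6

    def test_planted_8mer_recovered(self, rng):
        fg = []
        for i in range(500):
            s = _rand_seq(rng, 300)
            if i < 300:
                pos = int(rng.integers(0, 292))
                s = s[:pos] + "CTTTGATC" + s[pos + 8 :]
            fg.append(s)
        res = kmer_discovery(fg, None, k=8, seed=12)
        assert res[0].kmer == canonical_kmer("CTTTGATC")

    def test_order_invariance(self, rng):
        fg = [_rand_seq(rng, 100) for _ in range(50)]
        bg = [_rand_seq(rng, 100) for _ in range(50)]
        r1 = kmer_discovery(fg, bg, k=5)
        r2 = kmer_discovery(list(reversed(fg)), bg, k=5)
        assert [x.kmer for x in r1[:20]] == [x.kmer for x in r2[:20]]

    def test_rc_collapse_conserves_presence(self, rng):
        """Each sequence contributes at most once per canonical k-mer."""
        fg = [("CTTTGA" + _rand_seq(rng, 20) + "TCAAAG") for _ in range(10)]
        res = kmer_discovery(fg, [_rand_seq(rng, 32) for _ in range(10)], k=6)
        top = {r.kmer: r for r in res}
        assert top[canonical_kmer("CTTTGA")].fg_count == 10

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            kmer_discovery([], ["ACGT"], k=4)


def _peakset_on(genome_len, centers, scores):
    return PeakSet(
        [
            Peak(GenomicInterval("chr1", c - 150, c + 150), summit=c, score=s)
            for c, s in zip(centers, scores)
        ]
    )


class TestRecoveryCurve:
    def test_motif_at_every_site_gives_one(self, rng):
        centers = list(range(1000, 99_000, 2000))
        genome_seq = _rand_seq(rng, 100_000)
        for c in centers:
            genome_seq = genome_seq[:c] + "GCTTTGAA" + genome_seq[c + 8 :]
        ps = _peakset_on(100_000, [c + 4 for c in centers], scores=range(1, len(centers) + 1))
        curve = motif_recovery_curve(ps, {"chr1": genome_seq}, ConsensusMotif("m", "SCTTTGAW"), steps=[10, len(centers)])
        assert all(f == 1.0 for _, f in curve)

    def test_top_half_planting_gives_declining_curve(self, rng):
        genome_seq = _rand_seq(rng, 100_000)
        centers = list(range(1000, 99_000, 2000))
        n = len(centers)
        scores = list(range(n, 0, -1))  # first peaks rank highest
        for c in centers[: n // 2]:
            genome_seq = genome_seq[:c] + "CTTTGATC" + genome_seq[c + 8 :]
        ps = _peakset_on(100_000, [c + 4 for c in centers], scores)
        curve = motif_recovery_curve(
            ps, {"chr1": genome_seq}, ConsensusMotif("m", "CTTTGATC"), steps=[n // 2, n]
        )
        fractions = [f for _, f in curve]
        assert fractions[0] > fractions[1]
        assert fractions[1] == pytest.approx(0.5, abs=0.1)

    def test_background_matches_analytic_rate(self, rng):
        """Chance hit rate for an 8-bp word with 4 concrete instantiations."""
        genome_seq = _rand_seq(rng, 400_000)
        centers = list(range(1000, 399_000, 1000))
        ps = _peakset_on(400_000, centers, scores=range(1, len(centers) + 1))
        curve = motif_recovery_curve(ps, {"chr1": genome_seq}, ConsensusMotif("m", "SCTTTGAW"), steps=[len(centers)])
        # P(hit in 300bp window, both strands) ~ 1-(1-4/4^8)^(2*293)
        p_hit = 1 - (1 - 4 / 4**8) ** (2 * 293)
        _, frac = curve[0]
        se = np.sqrt(p_hit * (1 - p_hit) / len(centers))
        assert abs(frac - p_hit) < 5 * se

    def test_oversized_step_clamped_with_warning(self, rng):
        genome_seq = _rand_seq(rng, 10_000)
        ps = _peakset_on(10_000, [2000, 5000], scores=[2, 1])
        with pytest.warns(UserWarning, match="clamped"):
            curve = motif_recovery_curve(ps, {"chr1": genome_seq}, ConsensusMotif("m", "CTTTGA"), steps=[10])
        assert curve[0][0] == 2


class TestDensityProfile:
    def test_central_planting_gives_central_mode(self, rng):
        genome_seq = _rand_seq(rng, 50_000)
        centers = list(range(1000, 49_000, 1000))
        for c in centers:
            genome_seq = genome_seq[: c - 3] + "TGATAA" + genome_seq[c + 3 :]
        ps = _peakset_on(50_000, centers, scores=range(1, len(centers) + 1))
        prof = motif_density_profile(ps, {"chr1": genome_seq}, ConsensusMotif("m", "WGATAR"))
        modal = np.argmax(prof.density)
        lo, hi = prof.bin_edges[modal], prof.bin_edges[modal + 1]
        assert lo <= 0 < hi

    def test_no_hits_gives_zero_profile(self):
        genome_seq = "AC" * 25_000
        ps = _peakset_on(50_000, [10_000], scores=[1])
        prof = motif_density_profile(ps, {"chr1": genome_seq}, ConsensusMotif("m", "TTTTTT"))
        assert prof.total == 0

    def test_uniform_planting_gives_flat_profile(self, rng):
        from scipy import stats

        flat_ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            genome_seq = _rand_seq(r, 200_000)
            centers = list(range(1000, 199_000, 1000))
            for c in centers:
                off = int(r.integers(-450, 450))
                genome_seq = genome_seq[: c + off] + "CTTTGATC" + genome_seq[c + off + 8 :]
            ps = _peakset_on(200_000, centers, scores=range(1, len(centers) + 1))
            prof = motif_density_profile(ps, {"chr1": genome_seq}, ConsensusMotif("m", "CTTTGATC"))
            counts = prof.density * len(centers)
            # bins fully inside the planting range, pooled into coarse groups
            # so expected counts are large enough for the chi-square test
            inner = counts[6:86]
            groups = inner.reshape(8, 10).sum(axis=1)
            if stats.chisquare(groups).pvalue > 0.01:
                flat_ok += 1
        assert flat_ok >= 9
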
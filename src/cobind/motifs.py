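"""Consensus-motif scanning, de novo k-mer discovery, motif-recovery curves,
and motif-density profiles around peak centers.

Motifs are IUPAC-degenerate words (e.g. ``SCTTTGAW`` for the TCF/LEF family,
``WGATAR`` for GATA factors).  Discovery works at the k-mer level: each
foreground/background sequence is reduced to the set of strand-collapsed
k-mers it contains, and per-k-mer enrichment is tested with a one-sided
Fisher exact test followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenomicInterval, PeakSet

__all__ = [
    "IUPAC",
    "ConsensusMotif",
    "MotifHit",
    "KmerResult",
    "MotifDensityProfile",
    "reverse_complement",
    "canonical_kmer",
    "instantiate_iupac",
    "consensus_scan",
    "dinucleotide_shuffle",
    "kmer_discovery",
    "peak_sequences",
    "motif_recovery_curve",
    "motif_density_profile",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement, valid for plain and IUPAC-degenerate strings."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def instantiate_iupac(iupac: str, rng: np.random.Generator) -> str:
    """Resolve every degenerate position uniformly at random."""
    out = []
    for ch in iupac.upper():
        choices = IUPAC.get(ch)
        if choices is None:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        choices = choices.replace("N", "") or "ACGT"
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _iupac_regex(iupac: str) -> re.Pattern:
    parts = []
    for ch in iupac.upper():
        cls = IUPAC.get(ch)
        if cls is None:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class ConsensusMotif:
    """A named IUPAC-degenerate consensus word."""

    name: str
    iupac: str

    def __post_init__(self):
        if not self.iupac:
            raise ValueError("motif must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifHit:
    """One match of a consensus on a sequence; position is the match start
    on the forward strand regardless of the matched strand."""

    position: int
    strand: str
    matched: str


def consensus_scan(sequence: str, motif: ConsensusMotif, both_strands: bool = True) -> list[MotifHit]:
    """All occurrences of the consensus in the sequence (and, optionally, of
    its reverse complement), including overlapping ones.

    ``N`` in the sequence is matched only by N-tolerant IUPAC letters.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid letters: {sorted(bad)}")
    hits = [
        MotifHit(m.start(), "+", m.group(1))
        for m in _iupac_regex(motif.iupac).finditer(sequence)
    ]
    if both_strands:
        rc = reverse_complement(motif.iupac)
        if rc != motif.iupac:  # palindromic consensus: forward hits suffice
            hits += [
                MotifHit(m.start(), "-", m.group(1))
                for m in _iupac_regex(rc).finditer(sequence)
            ]
    return sorted(hits, key=lambda h: (h.position, h.strand))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide composition.

    Altschul-Erickson style: build the transition multigraph, pick a random
    last-exit edge ordering that keeps the walk connected to the terminal
    vertex, then walk an Eulerian path.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges)
    # choose last-exit edges: for each non-terminal vertex pick a random
    # successor; accept only if the last-exit graph connects every vertex to `last`
    for _ in range(1000):
        last_exit = {}
        for v in vertices:
            if v != last:
                last_exit[v] = edges[v][rng.integers(0, len(edges[v]))]
        reach_ok = True
        for v in vertices:
            if v == last:
                continue
            seen, cur = set(), v
            while cur != last:
                if cur in seen or cur not in last_exit:
                    reach_ok = False
                    break
                seen.add(cur)
                cur = last_exit[cur]
            if not reach_ok:
                break
        if reach_ok:
            break
    else:  # extremely skewed composition; fall back to identity
        return seq
    shuffled_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_exit[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v != last:
            ordered.append(last_exit[v])
        shuffled_edges[v] = ordered
    out = [first]
    counters = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass(frozen=True)
class KmerResult:
    kmer: str
    fg_count: int
    fg_fraction: float
    bg_count: int
    bg_fraction: float
    enrichment: float
    p_value: float
    q_value: float
    rank: int


def _present_kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            out.add(canonical_kmer(kmer))
    return out


def kmer_discovery(
    fg_seqs: list[str],
    bg_seqs: list[str] | None,
    k: int,
    seed: int | None = None,
) -> list[KmerResult]:
    """Rank k-mers by foreground enrichment over background.

    Presence/absence per sequence (both strands, reverse-complement pairs
    collapsed) feeds a one-sided Fisher exact test; q-values are
    Benjamini-Hochberg.  When ``bg_seqs`` is None the background is a
    dinucleotide shuffle of the foreground (requires ``seed``).
    """
    if not fg_seqs:
        raise ValueError("foreground must be nonempty")
    if k < 4:
        raise ValueError("k must be >= 4")
    if bg_seqs is None:
        if seed is None:
            raise ValueError("background missing: provide bg_seqs or a shuffle seed")
        rng = np.random.default_rng(seed)
        bg_seqs = [dinucleotide_shuffle(s, rng) for s in fg_seqs]
    if not bg_seqs:
        raise ValueError("background must be nonempty")

    n_fg, n_bg = len(fg_seqs), len(bg_seqs)
    fg_counts: dict[str, int] = {}
    for s in fg_seqs:
        for km in _present_kmers(s, k):
            fg_counts[km] = fg_counts.get(km, 0) + 1
    bg_counts: dict[str, int] = {}
    for s in bg_seqs:
        for km in _present_kmers(s, k):
            bg_counts[km] = bg_counts.get(km, 0) + 1

    kmers = sorted(set(fg_counts) | set(bg_counts))
    pvals = np.empty(len(kmers))
    for i, km in enumerate(kmers):
        a = fg_counts.get(km, 0)
        b = bg_counts.get(km, 0)
        # hypergeometric tail == one-sided Fisher on [[a, n_fg-a],[b, n_bg-b]]
        pvals[i] = stats.hypergeom.sf(a - 1, n_fg + n_bg, a + b, n_fg)
    qvals = stats.false_discovery_control(pvals, method="bh")

    results = []
    for i, km in enumerate(kmers):
        a, b = fg_counts.get(km, 0), bg_counts.get(km, 0)
        fg_frac, bg_frac = a / n_fg, b / n_bg
        enr = fg_frac / bg_frac if bg_frac > 0 else float("inf")
        results.append((pvals[i], -enr if np.isfinite(enr) else -np.inf, km, a, b, fg_frac, bg_frac, enr, qvals[i]))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return [
        KmerResult(
            kmer=km, fg_count=a, fg_fraction=fg_frac, bg_count=b, bg_fraction=bg_frac,
            enrichment=enr, p_value=float(p), q_value=float(q), rank=rank,
        )
        for rank, (p, _negenr, km, a, b, fg_frac, bg_frac, enr, q) in enumerate(results, start=1)
    ]


def peak_sequences(
    peaks: PeakSet | list, genome: dict[str, str], window: int = 300
) -> list[str]:
    """Center +/- window/2 sequence for each peak (center = summit)."""
    out = []
    half = window // 2
    for p in peaks:
        if isinstance(p, GenomicInterval):
            chrom, center = p.chrom, p.center
        else:
            chrom, center = p.interval.chrom, p.center
        seq = genome[chrom]
        start = max(0, center - half)
        out.append(seq[start : min(len(seq), center + half)])
    return out


def motif_recovery_curve(
    peaks: PeakSet,
    genome: dict[str, str],
    motif: ConsensusMotif,
    steps: list[int],
    window: int = 300,
) -> list[tuple[int, float]]:
    """Fraction of the top-N peaks (by score) whose central window contains a
    motif hit, for each N in ``steps``.  N larger than the set is clamped."""
    ranked = peaks.ranked()
    seqs = peak_sequences(ranked, genome, window=window)
    has_hit = np.array([bool(consensus_scan(s, motif)) for s in seqs])
    out = []
    for n in steps:
        n_eff = min(n, len(ranked))
        if n_eff < n:
            import warnings

            warnings.warn(f"step {n} exceeds peak count {len(ranked)}; clamped")
        if n_eff == 0:
            continue
        out.append((n_eff, float(has_hit[:n_eff].mean())))
    return out


@dataclass
class MotifDensityProfile:
    """Histogram of motif-hit midpoints relative to peak centers."""

    bin_edges: np.ndarray  # length n_bins+1, bp relative to center
    density: np.ndarray  # hits per site per bin

    @property
    def total(self) -> float:
        return float(self.density.sum())


def motif_density_profile(
    peaks: PeakSet | list,
    genome: dict[str, str],
    motif: ConsensusMotif,
    window: int = 500,
    bin_width: int = 10,
) -> MotifDensityProfile:
    """Per-site-normalized histogram of hit midpoints within +/- window of
    each peak center."""
    edges = np.arange(-window, window + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    items = list(peaks)
    if not items:
        return MotifDensityProfile(edges, counts)
    half_motif = len(motif) / 2.0
    for p in items:
        if isinstance(p, GenomicInterval):
            chrom, center = p.chrom, p.center
        else:
            chrom, center = p.interval.chrom, p.center
        seq = genome[chrom]
        start = max(0, center - window - len(motif))
        sub = seq[start : min(len(seq), center + window + len(motif))]
        for h in consensus_scan(sub, motif):
            rel = start + h.position + half_motif - center
            if -window <= rel < window:
                counts[int((rel + window) // bin_width)] += 1
    return MotifDensityProfile(edges, counts / len(items))
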
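"""Multi-cell-type peak comparison: pairwise overlap matrices, cell-type
specific and common peak sets, active-enhancer derivation and occupancy,
nearest-TSS annotation, and target-gene summaries."""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .core import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    intervals_overlap,
    merge_intervals,
    overlap_fraction,
)
from .peaks import AmplifiedRegion

__all__ = [
    "OverlapMatrix",
    "TargetSummary",
    "TssDistanceProfile",
    "NearestTssRecord",
    "pairwise_overlap_matrix",
    "cell_specific_peaks",
    "common_peaks",
    "active_enhancers",
    "enhancer_occupancy",
    "annotate_nearest_tss",
    "target_gene_summary",
    "tss_distance_profile",
    "DEFAULT_TSS_BINS",
]

# absolute distance bin edges in bp: 0-1 kb, 1-5, 5-10, 10-50, 50-100, >100 kb
DEFAULT_TSS_BINS = [0, 1_000, 5_000, 10_000, 50_000, 100_000, float("inf")]


@dataclass
class OverlapMatrix:
    labels: list[str]
    matrix: np.ndarray  # matrix[i][j] = fraction of set i peaks overlapping set j


def pairwise_overlap_matrix(sets: list[PeakSet]) -> OverlapMatrix:
    """Two-way overlap fractions between every pair of peak sets."""
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    for s in sets:
        if len(s) == 0:
            raise ValueError(f"peak set {s.label!r} is empty")
    n = len(sets)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = overlap_fraction(sets[i], sets[j])
    return OverlapMatrix(labels=[s.label for s in sets], matrix=m)


def cell_specific_peaks(
    target: PeakSet,
    others: list[PeakSet],
    amplified: list[AmplifiedRegion] | None = None,
) -> PeakSet:
    """Peaks of ``target`` overlapping no other-set peak and no amplified region."""
    amp = merge_intervals([r.interval for r in (amplified or [])])
    out = []
    for p in target:
        if any(o.overlaps_any(p.interval) for o in others):
            continue
        if any(intervals_overlap(p.interval, iv) for iv in amp):
            continue
        out.append(p)
    return PeakSet(out, label=f"{target.label}_specific" if target.label else "specific")


def common_peaks(sets: list[PeakSet], anchor: int = 0) -> PeakSet:
    """Peaks of the anchor set overlapping >= 1 peak in every other set."""
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    anchor_set = sets[anchor]
    others = [s for i, s in enumerate(sets) if i != anchor]
    out = [p for p in anchor_set if all(o.overlaps_any(p.interval) for o in others)]
    return PeakSet(out, label="common")


def active_enhancers(k4me1: PeakSet, k27ac: PeakSet) -> list[GenomicInterval]:
    """Regions with both marks: the merged span of every overlapping
    (H3K4me1, H3K27ac) peak pair, reduced to disjoint intervals."""
    spans = []
    for p in k4me1:
        for q in k27ac.overlapping(p.interval):
            spans.append(
                GenomicInterval(
                    p.interval.chrom,
                    min(p.interval.start, q.interval.start),
                    max(p.interval.end, q.interval.end),
                )
            )
    return merge_intervals(spans)


def enhancer_occupancy(peaks: PeakSet, k4me1: PeakSet, k27ac: PeakSet) -> dict[str, float]:
    """Percentages tying factor peaks to enhancer chromatin.

    Returns pct_peaks_at_k4me1, pct_peaks_at_k27ac, pct_peaks_at_enhancers
    (denominator: peaks) and pct_enhancers_with_peak (denominator: active
    enhancers).
    """
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    enh = active_enhancers(k4me1, k27ac)
    if not enh:
        raise ValueError("no active enhancers: pct_enhancers_with_peak undefined")
    at_k4 = 100.0 * overlap_fraction(peaks, k4me1)
    at_k27 = 100.0 * overlap_fraction(peaks, k27ac)
    at_enh = 100.0 * sum(
        1 for p in peaks if any(intervals_overlap(p.interval, iv) for iv in enh)
    ) / len(peaks)
    enh_with_peak = 100.0 * sum(1 for iv in enh if peaks.overlaps_any(iv)) / len(enh)
    return {
        "pct_peaks_at_k4me1": at_k4,
        "pct_peaks_at_k27ac": at_k27,
        "pct_peaks_at_enhancers": at_enh,
        "pct_enhancers_with_peak": enh_with_peak,
    }


@dataclass(frozen=True)
class NearestTssRecord:
    peak_chrom: str
    peak_center: int
    gene_id: str | None
    distance: int | None  # signed; positive = downstream of the TSS in gene orientation
    bin_label: str


def _bin_label(abs_dist: int, edges: list[float]) -> str:
    for lo, hi in zip(edges, edges[1:]):
        if lo <= abs_dist < hi:
            hi_s = f"{hi / 1000:g}kb" if np.isfinite(hi) else "inf"
            return f"{lo / 1000:g}-{hi_s}" if np.isfinite(hi) else f">{lo / 1000:g}kb"
    return "NA"


def annotate_nearest_tss(
    peaks: PeakSet,
    genes: list[GeneAnnotation],
    bin_edges: list[float] | None = None,
) -> list[NearestTssRecord]:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Distance is center-to-TSS, signed positive when the peak lies downstream
    of the TSS in the gene's orientation.  Equidistant TSSs are broken by
    lexicographic gene_id.  Peaks on chromosomes without genes get gene None.
    """
    if not genes:
        raise ValueError("gene annotation is empty")
    edges = bin_edges or DEFAULT_TSS_BINS
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in sorted(genes, key=lambda g: (g.tss, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_sorted = {c: [g.tss for g in gl] for c, gl in by_chrom.items()}

    records = []
    for p in peaks:
        chrom, center = p.interval.chrom, p.center
        gl = by_chrom.get(chrom)
        if not gl:
            records.append(NearestTssRecord(chrom, center, None, None, "NA"))
            continue
        i = bisect.bisect_left(tss_sorted[chrom], center)
        candidates = [g for g in gl[max(0, i - 2) : i + 2]]
        best = min(candidates, key=lambda g: (abs(g.tss - center), g.gene_id))
        signed = center - best.tss if best.strand == "+" else best.tss - center
        records.append(
            NearestTssRecord(chrom, center, best.gene_id, signed, _bin_label(abs(signed), edges))
        )
    return records


@dataclass(frozen=True)
class TargetSummary:
    label: str
    total_peaks: int
    nearest_gene_count: int
    peaks_per_gene: float  # rounded to one decimal


def target_gene_summary(records: list[NearestTssRecord], label: str = "") -> TargetSummary:
    """Count peaks and distinct nearest genes; ratio rounded to one decimal."""
    genes = {r.gene_id for r in records if r.gene_id is not None}
    if not genes:
        raise ValueError("no peaks could be assigned a nearest gene")
    return TargetSummary(
        label=label,
        total_peaks=len(records),
        nearest_gene_count=len(genes),
        peaks_per_gene=round(len(records) / len(genes), 1),
    )


@dataclass
class TssDistanceProfile:
    bin_labels: list[str]
    percentages: list[float]


def tss_distance_profile(
    records: list[NearestTssRecord], bin_edges: list[float] | None = None
) -> TssDistanceProfile:
    """Percentage of peaks per absolute distance-to-TSS bin (sums to 100)."""
    edges = bin_edges or DEFAULT_TSS_BINS
    labels = [_bin_label(lo, edges) for lo in edges[:-1]]
    assigned = [r for r in records if r.distance is not None]
    if not assigned:
        raise ValueError("no annotated peaks")
    counts = {lab: 0 for lab in labels}
    for r in assigned:
        counts[r.bin_label] += 1
    pct = [100.0 * counts[lab] / len(assigned) for lab in labels]
    return TssDistanceProfile(bin_labels=labels, percentages=pct)
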
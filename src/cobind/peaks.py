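"""Bin-based ChIP-seq peak calling with an input-referenced empirical FDR,
plus copy-number amplification detection from the input library.

The caller extends each tag to the assumed fragment length, counts fragments
per fixed-width bin, scales the input track to the ChIP library size, and
picks the smallest height threshold ``h`` for which

    eFDR(h) = (# scaled input bins >= h) / (# ChIP bins >= h) <= fdr

Runs of threshold-exceeding bins are merged into peaks; the summit is the
center of the maximal bin and the score is the maximal bin count per million
ChIP tags.  Peaks falling in amplified regions are flagged, not dropped;
downstream specificity analyses exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, Peak, PeakSet, TagLibrary, merge_intervals

__all__ = [
    "BinTrack",
    "AmplifiedRegion",
    "bin_counts",
    "call_peaks",
    "detect_amplified_regions",
    "flag_amplified_peaks",
    "infer_chrom_lengths",
]


@dataclass(frozen=True)
class AmplifiedRegion:
    """A genomic segment whose input coverage exceeds the genome median."""

    interval: GenomicInterval
    fold: float


@dataclass
class BinTrack:
    """Per-chromosome fragment counts in fixed-width bins."""

    bin_width: int
    counts: dict[str, np.ndarray]
    total_tags: int

    def all_counts(self) -> np.ndarray:
        if not self.counts:
            return np.array([], dtype=np.int64)
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])


def infer_chrom_lengths(*libs: TagLibrary) -> dict[str, int]:
    """Smallest per-chromosome length containing every extended fragment."""
    lengths: dict[str, int] = {}
    for lib in libs:
        for chrom in lib.chroms:
            _, ends = lib.fragments(chrom)
            if len(ends):
                lengths[chrom] = max(lengths.get(chrom, 0), int(ends.max()))
    return lengths


def bin_counts(lib: TagLibrary, chrom_lengths: dict[str, int], bin_width: int) -> BinTrack:
    """Count, per bin, the fragments overlapping that bin.

    A fragment [s, e) contributes one count to every bin it touches, via a
    +1/-1 difference track cumulated along the chromosome.
    """
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_width)
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        if chrom in lib.tags:
            starts, ends = lib.fragments(chrom)
            b0 = np.clip(starts // bin_width, 0, n_bins - 1)
            b1 = np.clip((ends - 1) // bin_width, 0, n_bins - 1)
            np.add.at(diff, b0, 1)
            np.add.at(diff, b1 + 1, -1)
        counts[chrom] = np.cumsum(diff[:-1])
    return BinTrack(bin_width=bin_width, counts=counts, total_tags=lib.total)


def _efdr_threshold(chip_counts: np.ndarray, input_scaled: np.ndarray, fdr: float) -> int | None:
    """Smallest integer height h with empirical FDR <= fdr, or None."""
    max_h = int(chip_counts.max(initial=0))
    chip_sorted = np.sort(chip_counts)
    input_sorted = np.sort(input_scaled)
    n_chip, n_input = len(chip_sorted), len(input_sorted)
    for h in range(1, max_h + 1):
        chip_ge = n_chip - np.searchsorted(chip_sorted, h, side="left")
        if chip_ge == 0:
            return None
        input_ge = n_input - np.searchsorted(input_sorted, h, side="left")
        if input_ge / chip_ge <= fdr:
            return h
    return None


def call_peaks(
    chip: TagLibrary,
    input_lib: TagLibrary,
    bin_width: int = 100,
    fdr: float = 0.05,
    min_height: int = 4,
    chrom_lengths: dict[str, int] | None = None,
    exclude: list[GenomicInterval] | None = None,
    label: str = "",
) -> PeakSet:
    """Call peaks on a ChIP library against its matched input control.

    Parameters
    ----------
    bin_width : genomic bin size in bp for the coverage tracks.
    fdr : target empirical FDR used to choose the height threshold.
    min_height : floor on the height threshold in ChIP fragments per bin,
        guarding against degenerate thresholds in very sparse tracks.
    chrom_lengths : per-chromosome lengths; inferred from the two libraries
        when omitted.
    exclude : regions (typically detected amplified segments) whose bins
        are left out of the threshold estimation, so that copy-number
        inflation of the input does not drive the empirical-FDR null;
        candidate bins there still form peaks and are flagged downstream.
    """
    if chip.total == 0:
        raise ValueError("ChIP library is empty")
    if input_lib.total == 0:
        raise ValueError("input library is empty: no null model for the empirical FDR")
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(chip, input_lib)

    chip_track = bin_counts(chip, chrom_lengths, bin_width)
    input_track = bin_counts(input_lib, chrom_lengths, bin_width)
    scale = chip.total / input_lib.total
    if exclude:
        keep: list[np.ndarray] = []
        for chrom in sorted(chrom_lengths):
            n_bins = len(chip_track.counts[chrom])
            mask = np.ones(n_bins, dtype=bool)
            for iv in exclude:
                if iv.chrom == chrom:
                    mask[iv.start // bin_width : -(-iv.end // bin_width)] = False
            keep.append(mask)
        keep_mask = np.concatenate(keep)
        chip_all = chip_track.all_counts()[keep_mask]
        input_all = input_track.all_counts()[keep_mask] * scale
    else:
        chip_all = chip_track.all_counts()
        input_all = input_track.all_counts() * scale

    h = _efdr_threshold(chip_all, input_all, fdr)
    if h is None:
        return PeakSet([], label=label)
    h = max(h, min_height)

    peaks: list[Peak] = []
    per_million = 1e6 / chip.total
    fl = chip.fragment_length
    for chrom in sorted(chrom_lengths):
        counts = chip_track.counts[chrom]
        above = counts >= h
        if not above.any():
            continue
        frag_starts, frag_ends = chip.fragments(chrom)
        # runs of consecutive candidate bins
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for run_start, run_end in edges.reshape(-1, 2):
            seg = counts[run_start:run_end]
            start = run_start * bin_width
            end = min(run_end * bin_width, chrom_lengths[chrom])
            # base-pair summit from local fragment coverage (fragment starts
            # and ends are both sorted because the extension length is fixed)
            i_lo = np.searchsorted(frag_starts, start - fl, side="right")
            i_hi = np.searchsorted(frag_starts, end, side="left")
            local = np.zeros(end - start + 1, dtype=np.int64)
            s_local = np.clip(frag_starts[i_lo:i_hi] - start, 0, end - start)
            e_local = np.clip(frag_ends[i_lo:i_hi] - start, 0, end - start)
            np.add.at(local, s_local, 1)
            np.add.at(local, e_local, -1)
            coverage = np.cumsum(local[:-1])
            summit = start + int(np.argmax(coverage))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    summit=summit,
                    score=float(seg.max()) * per_million,
                )
            )
    return PeakSet(peaks, label=label)


def detect_amplified_regions(
    input_lib: TagLibrary,
    window: int = 10_000,
    fold_min: float = 3.0,
    chrom_lengths: dict[str, int] | None = None,
) -> list[AmplifiedRegion]:
    """Find copy-number-amplified segments as windows of elevated input coverage.

    Non-overlapping windows whose (pseudo-counted) coverage ratio to the
    genome-wide median reaches ``fold_min`` are merged; the reported fold is
    the mean ratio across the merged windows.
    """
    if input_lib.total == 0:
        raise ValueError("input library is empty")
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(input_lib)
    track = bin_counts(input_lib, chrom_lengths, window)
    all_counts = track.all_counts()
    median = float(np.median(all_counts))
    regions: list[AmplifiedRegion] = []
    for chrom in sorted(chrom_lengths):
        counts = track.counts[chrom]
        ratios = (counts + 1.0) / (median + 1.0)
        above = ratios >= fold_min
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for run_start, run_end in edges.reshape(-1, 2):
            iv = GenomicInterval(
                chrom, run_start * window, min(run_end * window, chrom_lengths[chrom])
            )
            regions.append(AmplifiedRegion(iv, fold=float(ratios[run_start:run_end].mean())))
    return regions


def flag_amplified_peaks(peaks: PeakSet, regions: list[AmplifiedRegion]) -> PeakSet:
    """Mark (in place) every peak overlapping an amplified region; returns the set."""
    merged = merge_intervals([r.interval for r in regions])
    for p in peaks:
        p.amplified = any(
            iv.chrom == p.interval.chrom
            and min(iv.end, p.interval.end) > max(iv.start, p.interval.start)
            for iv in merged
        )
    return peaks
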
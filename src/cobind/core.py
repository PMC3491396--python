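"""Genomic interval algebra, core domain types, and on-disk formats.

Everything downstream of the peak caller speaks in the types defined here:
0-based half-open :class:`GenomicInterval`, scored :class:`Peak` /
:class:`PeakSet`, aligned-tag :class:`TagLibrary`, and TSS-bearing
:class:`GeneAnnotation`.  Overlap means at least one shared base pair under
the half-open convention unless a larger ``min_overlap`` is requested.
External 1-based inclusive coordinates (as printed in genome browsers) are
converted on ingestion via :func:`from_one_based`.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "BedParseError",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "TagLibrary",
    "GeneAnnotation",
    "from_one_based",
    "intervals_overlap",
    "merge_intervals",
    "overlap_fraction",
    "read_bed",
    "write_bed",
    "read_peaks",
    "write_peaks",
    "read_tags",
    "write_tags",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_fasta",
    "write_fasta",
]


class BedParseError(ValueError):
    """A malformed record in a BED-like file, reported with its line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +,-,. got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def from_one_based(chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval:
    """Convert 1-based inclusive coordinates (browser style) to half-open."""
    return GenomicInterval(chrom, start - 1, end, strand)


@dataclass
class Peak:
    """A scored ChIP-seq peak with a summit (position of maximal coverage)."""

    interval: GenomicInterval
    summit: int
    score: float
    rank: int | None = None
    name: str = ""
    amplified: bool = False

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.score <= 0:
            raise ValueError(f"score must be > 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> int:
        return self.summit


def _score_sort_key(p: Peak):
    # descending score, ties broken by genomic position for deterministic ranks
    return (-p.score, p.interval.chrom, p.interval.start)


class PeakSet:
    """An ordered collection of peaks for one factor/cell-type combination.

    Peaks are stored sorted by (chrom, start); ranks are assigned by
    descending score with (chrom, start) tie-break.  Overlap queries are
    served from a per-chromosome interval tree.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = ""):
        peaks = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        seen: set[tuple[str, int, int]] = set()
        for p in peaks:
            key = (p.interval.chrom, p.interval.start, p.interval.end)
            if key in seen:
                raise ValueError(f"duplicate peak {key}")
            seen.add(key)
        self.label = label
        self.peaks: list[Peak] = peaks
        for rank, p in enumerate(sorted(self.peaks, key=_score_sort_key), start=1):
            p.rank = rank
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    def ranked(self) -> list[Peak]:
        """Peaks in rank order (descending score, deterministic ties)."""
        return sorted(self.peaks, key=_score_sort_key)

    def top(self, n: int, label: str | None = None) -> "PeakSet":
        return PeakSet(self.ranked()[:n], label=label if label is not None else self.label)

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            for p in self.peaks:
                self._trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                    p.interval.start, p.interval.end, p
                )
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, iv: GenomicInterval, min_overlap: int = 1) -> list[Peak]:
        hits = self._tree(iv.chrom).overlap(iv.start, iv.end)
        out = [
            h.data
            for h in hits
            if min(h.end, iv.end) - max(h.begin, iv.start) >= min_overlap
        ]
        return sorted(out, key=lambda p: (p.interval.start, p.interval.end))

    def overlaps_any(self, iv: GenomicInterval, min_overlap: int = 1) -> bool:
        return bool(self.overlapping(iv, min_overlap))

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def intervals_overlap(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff the two intervals share at least ``min_overlap`` bp."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


def merge_intervals(items: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint set of intervals covering the union of the input.

    Adjacent (book-ended) intervals are not merged: merging requires >= 1
    shared bp under half-open coordinates.
    """
    if not items:
        return []
    items = sorted(items, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = items[0].chrom, items[0].start, items[0].end
    for iv in items[1:]:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def overlap_fraction(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> float:
    """Fraction of peaks in ``a`` overlapping at least one peak of ``b``."""
    if len(a) == 0:
        raise ValueError("overlap_fraction undefined for empty query set")
    n = sum(1 for p in a if b.overlaps_any(p.interval, min_overlap))
    return n / len(a)


@dataclass
class TagLibrary:
    """Aligned 5' tag positions with strand, keyed by chromosome.

    ``tags[chrom]`` is a pair of parallel arrays: int positions and strand
    signs (+1 for plus, -1 for minus).  ``fragment_length`` is the assumed
    sonication fragment size used when tags are extended into coverage.
    """

    tags: dict[str, tuple[np.ndarray, np.ndarray]]
    fragment_length: int = 200

    def __post_init__(self):
        clean = {}
        for chrom, (pos, strand) in sorted(self.tags.items()):
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            if pos.shape != strand.shape:
                raise ValueError("positions and strands must be parallel arrays")
            if len(pos) and pos.min() < 0:
                raise ValueError("tag positions must be >= 0")
            order = np.argsort(pos, kind="stable")
            clean[chrom] = (pos[order], strand[order])
        self.tags = clean

    @property
    def total(self) -> int:
        return sum(len(pos) for pos, _ in self.tags.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self.tags)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str]], fragment_length: int = 200
    ) -> "TagLibrary":
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, pos, strand in records:
            lst = by_chrom.setdefault(chrom, ([], []))
            lst[0].append(pos)
            lst[1].append(1 if strand == "+" else -1)
        return cls(
            {c: (np.array(p, dtype=np.int64), np.array(s, dtype=np.int8)) for c, (p, s) in by_chrom.items()},
            fragment_length=fragment_length,
        )

    def fragments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Fragment [start, end) arrays obtained by extending each tag."""
        pos, strand = self.tags.get(chrom, (np.array([], dtype=np.int64),) * 2)
        fl = self.fragment_length
        starts = np.where(strand > 0, pos, pos - fl + 1)
        starts = np.maximum(starts, 0)
        return starts, starts + fl

    def subsample(self, fraction: float, rng: np.random.Generator) -> "TagLibrary":
        """Uniform subsample without replacement of ``floor(fraction*total)`` tags."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n_keep = int(np.floor(fraction * self.total))
        if n_keep < 1:
            raise ValueError("subsample would keep fewer than one tag")
        if n_keep == self.total:
            return self
        keep = rng.choice(self.total, size=n_keep, replace=False)
        mask = np.zeros(self.total, dtype=bool)
        mask[keep] = True
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        offset = 0
        for chrom in self.chroms:
            pos, strand = self.tags[chrom]
            m = mask[offset : offset + len(pos)]
            offset += len(pos)
            if m.any():
                out[chrom] = (pos[m], strand[m])
        return TagLibrary(out, fragment_length=self.fragment_length)

    def split_binomial(self, p: float, rng: np.random.Generator) -> tuple["TagLibrary", "TagLibrary"]:
        """Binomially thin the library into two disjoint pseudo-replicates."""
        a: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        b: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chroms:
            pos, strand = self.tags[chrom]
            m = rng.random(len(pos)) < p
            if m.any():
                a[chrom] = (pos[m], strand[m])
            if (~m).any():
                b[chrom] = (pos[~m], strand[~m])
        fl = self.fragment_length
        return TagLibrary(a, fragment_length=fl), TagLibrary(b, fragment_length=fl)

    def merge(self, other: "TagLibrary") -> "TagLibrary":
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(set(self.chroms) | set(other.chroms)):
            parts = [lib.tags[chrom] for lib in (self, other) if chrom in lib.tags]
            out[chrom] = (
                np.concatenate([p for p, _ in parts]),
                np.concatenate([s for _, s in parts]),
            )
        return TagLibrary(out, fragment_length=self.fragment_length)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its transcription start site and genomic span."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (self.span.start <= self.tss < self.span.end):
            raise ValueError(f"tss {self.tss} outside span")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_bed_line(line: str, lineno: int) -> tuple[list[str], GenomicInterval]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"expected >=3 tab-separated fields, got {len(fields)}", lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"non-integer coordinate: {exc}", lineno) from None
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
    try:
        iv = GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise BedParseError(str(exc), lineno) from None
    return fields, iv


def read_bed(source: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file as plain intervals (columns beyond 3/6 ignored)."""
    out = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            _, iv = _parse_bed_line(line, lineno)
            out.append(iv)
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(items: Iterable[GenomicInterval], dest: str | Path) -> None:
    with open(dest, "w") as fh:
        for iv in sorted(items, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_peaks(source: str | Path, label: str = "") -> PeakSet:
    """Read a peak BED5 where column 4 encodes ``name|summit`` and column 5 the score."""
    peaks = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields, iv = _parse_bed_line(line, lineno)
            if len(fields) < 5:
                raise BedParseError("peak BED requires 5 columns", lineno)
            name = fields[3]
            if "|" in name:
                name, summit_s = name.rsplit("|", 1)
                summit = int(summit_s)
            else:
                summit = iv.center
            try:
                peaks.append(Peak(iv, summit=summit, score=float(fields[4]), name=name))
            except ValueError as exc:
                raise BedParseError(str(exc), lineno) from None
    return PeakSet(peaks, label=label)


def write_peaks(peaks: PeakSet, dest: str | Path) -> None:
    with open(dest, "w") as fh:
        for p in peaks:
            name = f"{p.name or 'peak'}|{p.summit}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}\t{p.score:g}\n"
            )


def read_tags(source: str | Path, fragment_length: int = 200) -> TagLibrary:
    """Read tags as BED6 with the 5' position encoded as a 1-bp interval."""
    records = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields, iv = _parse_bed_line(line, lineno)
            if len(fields) < 6:
                raise BedParseError("tag BED requires 6 columns (strand)", lineno)
            records.append((iv.chrom, iv.start, fields[5]))
    return TagLibrary.from_records(records, fragment_length=fragment_length)


def write_tags(lib: TagLibrary, dest: str | Path) -> None:
    with open(dest, "w") as fh:
        for chrom in lib.chroms:
            pos, strand = lib.tags[chrom]
            for p, s in zip(pos.tolist(), strand.tolist()):
                c = "+" if s > 0 else "-"
                fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{c}\n")


def read_gene_annotation(source: str | Path) -> list[GeneAnnotation]:
    """Read the 6-column annotation TSV: gene_id, chrom, strand, tss, span_start, span_end."""
    genes = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise BedParseError("annotation requires 6 columns", lineno)
            genes.append(
                GeneAnnotation(
                    gene_id=f[0],
                    chrom=f[1],
                    strand=f[2],
                    tss=int(f[3]),
                    span=GenomicInterval(f[1], int(f[4]), int(f[5]), f[2]),
                )
            )
    return sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))


def write_gene_annotation(genes: Iterable[GeneAnnotation], dest: str | Path) -> None:
    with open(dest, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tspan_start\tspan_end\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.span.start}\t{g.span.end}\n")


def read_fasta(source: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}


def write_fasta(genome: dict[str, str], dest: str | Path, width: int = 80) -> None:
    with open(dest, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
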
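"""Seeded simulator of a small genome with planted transcription-factor
binding sites in two modes (direct vs tethered), ChIP/input/histone tag
libraries, copy-number-amplified segments, and knockdown expression calls.

The generator emulates the data layout of a two-factor co-binding study:

* a *focal* factor (a TCF/LEF-type protein recognising ``SCTTTGAW``) and a
  *partner* factor (a GATA-type protein recognising ``WGATAR``);
* **direct** sites carry a focal-motif instance and focal ChIP signal;
* **tethered** sites carry only a partner-motif instance yet show ChIP
  signal for *both* factors — the focal factor is held there by
  protein-protein contact with the DNA-bound partner;
* **partner_only** sites carry the partner motif and partner signal only;
* **adjacent_cobound** sites carry both motifs and both signals (the
  alternative hypothesis: two factors each on their own motif);
* a subset of sites sit inside broad enhancer domains covered by two
  histone-mark libraries;
* the input library is uniform except for amplified segments;
* genes nearest tethered sites respond "up" under knockdown of either
  factor (the repression model), genes near adjacent co-bound sites
  respond per configuration, all others are unchanged.

Everything is reproducible bit-exactly from ``(SimConfig, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    GeneAnnotation,
    GenomicInterval,
    TagLibrary,
    write_fasta,
    write_gene_annotation,
    write_tags,
)
from .motifs import ConsensusMotif, instantiate_iupac

__all__ = ["SiteSpec", "SyntheticTruth", "SimConfig", "plant_sites", "generate_reads", "simulate_dataset"]

MODES = ("direct", "tethered", "partner_only", "adjacent_cobound")


@dataclass(frozen=True)
class SiteSpec:
    """A planted binding site with its mode and motif provenance."""

    mode: str
    chrom: str
    position: int  # site center used for read placement
    occupancy: float  # expected ChIP fold-enrichment over background
    planted_motifs: dict = field(default_factory=dict)  # name -> (start, word)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        expected = {
            "direct": {"focal"},
            "tethered": {"partner"},
            "partner_only": {"partner"},
            "adjacent_cobound": {"focal", "partner"},
        }[self.mode]
        if set(self.planted_motifs) != expected:
            raise ValueError(f"{self.mode} site must plant {expected}")


@dataclass
class SyntheticTruth:
    """The recovery oracle: everything the generator planted."""

    sites: list[SiteSpec]
    amplified: list[tuple[GenomicInterval, float]]
    enhancers: list[GenomicInterval]
    genes: list[GeneAnnotation]
    expression_effects: dict[str, tuple[str, str]]  # gene -> (focal KD, partner KD)

    def sites_for_factor(self, factor: str) -> list[SiteSpec]:
        """Sites carrying ChIP signal for ``factor`` ('focal' or 'partner')."""
        occupied = {
            "focal": ("direct", "tethered", "adjacent_cobound"),
            "partner": ("tethered", "partner_only", "adjacent_cobound"),
        }[factor]
        return [s for s in self.sites if s.mode in occupied]

    def to_json_dict(self) -> dict:
        return {
            "sites": [
                {
                    "mode": s.mode,
                    "chrom": s.chrom,
                    "position": s.position,
                    "occupancy": s.occupancy,
                    "planted_motifs": {k: [int(v[0]), v[1]] for k, v in sorted(s.planted_motifs.items())},
                }
                for s in self.sites
            ],
            "amplified": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "fold": fold}
                for iv, fold in self.amplified
            ],
            "enhancers": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in self.enhancers
            ],
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "tss": g.tss,
                    "span": [g.span.start, g.span.end],
                }
                for g in self.genes
            ],
            "expression_effects": {
                g: list(v) for g, v in sorted(self.expression_effects.items())
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            sites=[
                SiteSpec(
                    mode=s["mode"],
                    chrom=s["chrom"],
                    position=s["position"],
                    occupancy=s["occupancy"],
                    planted_motifs={k: (v[0], v[1]) for k, v in s["planted_motifs"].items()},
                )
                for s in d["sites"]
            ],
            amplified=[
                (GenomicInterval(a["chrom"], a["start"], a["end"]), a["fold"]) for a in d["amplified"]
            ],
            enhancers=[GenomicInterval(e["chrom"], e["start"], e["end"]) for e in d["enhancers"]],
            genes=[
                GeneAnnotation(
                    g["gene_id"],
                    g["chrom"],
                    g["strand"],
                    g["tss"],
                    GenomicInterval(g["chrom"], g["span"][0], g["span"][1], g["strand"]),
                )
                for g in d["genes"]
            ],
            expression_effects={g: tuple(v) for g, v in d["expression_effects"].items()},
        )


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a desk-scale genome (2 chromosomes x 1 Mb, ~200 sites,
    background 0.02 tags/bp, 200 bp fragments) on which the whole pipeline
    runs in minutes.
    """

    chrom_count: int = 2
    chrom_length: int = 1_000_000
    n_direct: int = 60
    n_tethered: int = 60
    n_partner_only: int = 40
    n_adjacent: int = 40
    occupancy_low: float = 10.0
    occupancy_high: float = 20.0
    background_density: float = 0.02  # tags per bp per library
    fragment_length: int = 200
    jitter_sd: float = 30.0
    replicate_count: int = 2
    amp_count: int = 2
    amp_length: int = 100_000
    amp_fold: float = 5.0
    enhancer_fraction: float = 0.6
    enhancer_width: int = 1_500
    enhancer_occupancy: float = 8.0
    n_genes: int = 120
    repression_prob: float = 0.9
    adjacent_direction: tuple[str, str] = ("down", "down")
    focal_motif: str = "SCTTTGAW"
    partner_motif: str = "WGATAR"
    min_spacing: int = 3_000
    adjacent_gap: int = 15
    seed: int = 1

    def __post_init__(self):
        for name in ("chrom_count", "chrom_length", "n_direct", "n_tethered",
                     "n_partner_only", "n_adjacent", "replicate_count", "amp_count",
                     "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_density <= 0:
            raise ValueError("background_density must be > 0")
        if self.amp_count and self.amp_fold <= 1:
            raise ValueError("amp_fold must exceed 1")
        if isinstance(self.adjacent_direction, list):
            self.adjacent_direction = tuple(self.adjacent_direction)

    @property
    def n_sites(self) -> int:
        return self.n_direct + self.n_tethered + self.n_partner_only + self.n_adjacent

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.chrom_count)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adjacent_direction"] = list(self.adjacent_direction)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def plant_sites(config: SimConfig, seed: int | None = None) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate the genome and plant motif instances at non-overlapping sites.

    Background nucleotides are i.i.d. uniform; at each site a concrete
    instantiation of the relevant consensus word(s) (degenerate positions
    resolved uniformly at random) is written into the sequence.  Returns the
    genome and the full truth record.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    chroms = config.chrom_names()
    L = config.chrom_length
    margin = 2_000

    # feasibility of the site packing
    slots_per_chrom = max(0, (L - 2 * margin) // config.min_spacing)
    total_slots = slots_per_chrom * len(chroms)
    if config.n_sites > total_slots:
        raise ValueError(
            f"cannot pack {config.n_sites} sites at spacing {config.min_spacing} "
            f"into {config.chrom_count} x {L} bp"
        )

    genome = {c: rng.integers(0, 4, size=L, dtype=np.uint8) for c in chroms}

    # assign site slots round-robin-ish via a global random slot draw
    slot_ids = rng.choice(total_slots, size=config.n_sites, replace=False)
    modes = (
        ["direct"] * config.n_direct
        + ["tethered"] * config.n_tethered
        + ["partner_only"] * config.n_partner_only
        + ["adjacent_cobound"] * config.n_adjacent
    )
    rng.shuffle(modes)

    focal = ConsensusMotif("focal", config.focal_motif)
    partner = ConsensusMotif("partner", config.partner_motif)

    sites: list[SiteSpec] = []
    for slot, mode in zip(np.sort(slot_ids).tolist(), modes):
        chrom = chroms[slot // slots_per_chrom]
        base = margin + (slot % slots_per_chrom) * config.min_spacing
        offset = int(rng.integers(0, config.min_spacing // 3))
        pos = base + offset
        occupancy = float(rng.uniform(config.occupancy_low, config.occupancy_high))
        planted: dict[str, tuple[int, str]] = {}

        def _write(motif: ConsensusMotif, at: int) -> tuple[int, str]:
            word = instantiate_iupac(motif.iupac, rng)
            arr = np.frombuffer(word.encode(), dtype=np.uint8)
            idx = np.searchsorted(_BASES, arr)
            genome[chrom][at : at + len(word)] = idx
            return at, word

        if mode == "direct":
            planted["focal"] = _write(focal, pos)
        elif mode in ("tethered", "partner_only"):
            planted["partner"] = _write(partner, pos)
        else:  # adjacent_cobound: partner word then focal word a small gap away
            planted["partner"] = _write(partner, pos)
            planted["focal"] = _write(focal, pos + len(partner.iupac) + config.adjacent_gap)
        sites.append(SiteSpec(mode=mode, chrom=chrom, position=pos, occupancy=occupancy, planted_motifs=planted))

    # amplified segments: placed in the upper quarter of each chromosome in turn
    amplified: list[tuple[GenomicInterval, float]] = []
    for i in range(config.amp_count):
        chrom = chroms[i % len(chroms)]
        hi = L - config.amp_length
        start = int(rng.integers(hi * 3 // 4, hi)) if hi > 0 else 0
        amplified.append((GenomicInterval(chrom, start, start + config.amp_length), config.amp_fold))

    # enhancers over a random subset of sites
    n_enh = int(round(config.enhancer_fraction * len(sites)))
    enh_idx = np.sort(rng.choice(len(sites), size=n_enh, replace=False))
    half = config.enhancer_width // 2
    enhancers = [
        GenomicInterval(
            sites[i].chrom,
            max(0, sites[i].position - half),
            min(L, sites[i].position + half),
        )
        for i in enh_idx.tolist()
    ]

    # genes on a jittered grid so TSSs are unique and sorted
    genes: list[GeneAnnotation] = []
    per_chrom = -(-config.n_genes // len(chroms))
    gid = 0
    for chrom in chroms:
        step = (L - 2 * margin) // max(per_chrom, 1)
        for j in range(per_chrom):
            if gid >= config.n_genes:
                break
            tss = margin + j * step + int(rng.integers(0, max(step // 2, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            span_len = int(rng.integers(2_000, 10_000))
            if strand == "+":
                span = GenomicInterval(chrom, tss, min(L, tss + span_len), strand)
            else:
                span = GenomicInterval(chrom, max(0, tss - span_len), tss + 1, strand)
            genes.append(GeneAnnotation(f"gene{gid:04d}", chrom, strand, tss, span))
            gid += 1

    # expression effects: nearest gene per tethered / adjacent site
    effects: dict[str, tuple[str, str]] = {g.gene_id: ("ns", "ns") for g in genes}

    def _nearest_gene(site: SiteSpec) -> GeneAnnotation | None:
        same = [g for g in genes if g.chrom == site.chrom]
        if not same:
            return None
        return min(same, key=lambda g: (abs(g.tss - site.position), g.gene_id))

    for s in sites:
        if s.mode == "tethered":
            g = _nearest_gene(s)
            if g is not None and rng.random() < config.repression_prob:
                effects[g.gene_id] = ("up", "up")
        elif s.mode == "adjacent_cobound":
            g = _nearest_gene(s)
            if g is not None and rng.random() < config.repression_prob:
                effects[g.gene_id] = config.adjacent_direction

    genome_str = {c: arr.tobytes().translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode() for c, arr in genome.items()}
    truth = SyntheticTruth(sites=sites, amplified=amplified, enhancers=enhancers, genes=genes, expression_effects=effects)
    return genome_str, truth


def _point_source_tags(
    rng: np.random.Generator,
    center: int,
    n: int,
    fragment_length: int,
    jitter_sd: float,
    L: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-asymmetric bimodal 5' positions around a point source."""
    strand = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
    offset = fragment_length // 2
    jitter = rng.normal(0.0, jitter_sd, size=n)
    pos = np.where(strand > 0, center - offset + jitter, center + offset + jitter)
    pos = np.clip(np.rint(pos), 0, L - 1).astype(np.int64)
    return pos, strand


def _uniform_tags(rng: np.random.Generator, n: int, L: int) -> tuple[np.ndarray, np.ndarray]:
    pos = rng.integers(0, L, size=n, dtype=np.int64)
    strand = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
    return pos, strand


def generate_reads(
    truth: SyntheticTruth, config: SimConfig, seed: int | None = None
) -> dict[str, TagLibrary]:
    """Draw tag libraries for every condition from the planted truth.

    Returns a mapping with keys ``focal_rep{i}``, ``partner_rep{i}``,
    ``input``, ``h3k4me1``, ``h3k27ac``.  Expected per-site ChIP tag count
    is ``occupancy x background_density x fragment_length``; 5' positions
    are strand-shifted by half a fragment with Gaussian jitter.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0B1)))
    chroms = config.chrom_names()
    L = config.chrom_length
    bg_per_chrom = config.background_density * L
    site_mu = config.background_density * config.fragment_length

    libs: dict[str, TagLibrary] = {}

    def _chip_library(factor: str) -> TagLibrary:
        tags: dict[str, tuple[list[np.ndarray], list[np.ndarray]]] = {c: ([], []) for c in chroms}
        for c in chroms:
            p, s = _uniform_tags(rng, rng.poisson(bg_per_chrom), L)
            tags[c][0].append(p)
            tags[c][1].append(s)
        for site in truth.sites_for_factor(factor):
            n = rng.poisson(site.occupancy * site_mu)
            if n:
                p, s = _point_source_tags(rng, site.position, n, config.fragment_length, config.jitter_sd, L)
                tags[site.chrom][0].append(p)
                tags[site.chrom][1].append(s)
        return TagLibrary(
            {c: (np.concatenate(ps), np.concatenate(ss)) for c, (ps, ss) in tags.items()},
            fragment_length=config.fragment_length,
        )

    for factor in ("focal", "partner"):
        for rep in range(1, config.replicate_count + 1):
            libs[f"{factor}_rep{rep}"] = _chip_library(factor)

    # input: uniform background plus amplified segments at (fold-1)x extra density
    tags = {c: ([], []) for c in chroms}
    for c in chroms:
        p, s = _uniform_tags(rng, rng.poisson(bg_per_chrom), L)
        tags[c][0].append(p)
        tags[c][1].append(s)
    for iv, fold in truth.amplified:
        n = rng.poisson(config.background_density * (fold - 1.0) * len(iv))
        if n:
            p = rng.integers(iv.start, iv.end, size=n, dtype=np.int64)
            s = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
            tags[iv.chrom][0].append(p)
            tags[iv.chrom][1].append(s)
    libs["input"] = TagLibrary(
        {c: (np.concatenate(ps), np.concatenate(ss)) for c, (ps, ss) in tags.items()},
        fragment_length=config.fragment_length,
    )

    # histone marks: broad kernels over enhancer regions plus uniform background
    for mark in ("h3k4me1", "h3k27ac"):
        tags = {c: ([], []) for c in chroms}
        for c in chroms:
            p, s = _uniform_tags(rng, rng.poisson(bg_per_chrom), L)
            tags[c][0].append(p)
            tags[c][1].append(s)
        for iv in truth.enhancers:
            n = rng.poisson(config.enhancer_occupancy * config.background_density * len(iv))
            if n:
                # broad-domain mark: box kernel over the enhancer interval
                p = rng.integers(iv.start, iv.end, size=n, dtype=np.int64)
                s = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
                tags[iv.chrom][0].append(p)
                tags[iv.chrom][1].append(s)
        libs[mark] = TagLibrary(
            {c: (np.concatenate(ps), np.concatenate(ss)) for c, (ps, ss) in tags.items()},
            fragment_length=config.fragment_length,
        )
    return libs


def write_expression_table(truth: SyntheticTruth, dest: str | Path) -> None:
    """3-column TSV: gene, direction under focal KD, direction under partner KD."""
    with open(dest, "w") as fh:
        fh.write("gene_id\tdirection_focalKD\tdirection_partnerKD\n")
        for gene in sorted(truth.expression_effects):
            f, p = truth.expression_effects[gene]
            fh.write(f"{gene}\t{f}\t{p}\n")


def read_expression_table(source: str | Path) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    with open(source) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            gene, f, p = line.rstrip("\n").split("\t")
            out[gene] = (f, p)
    return out


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write the full on-disk bundle and return a manifest dict.

    Files: ``genome.fa``, ``tags/<condition>.bed``, ``genes.tsv``,
    ``expression.tsv``, ``truth.json``, ``config.yaml``.  Regenerable
    bit-exactly from (config, seed).
    """
    import yaml

    outdir = Path(outdir)
    (outdir / "tags").mkdir(parents=True, exist_ok=True)
    genome, truth = plant_sites(config)
    libs = generate_reads(truth, config)

    write_fasta(genome, outdir / "genome.fa")
    tag_counts = {}
    for cond in sorted(libs):
        write_tags(libs[cond], outdir / "tags" / f"{cond}.bed")
        tag_counts[cond] = libs[cond].total
    write_gene_annotation(truth.genes, outdir / "genes.tsv")
    write_expression_table(truth, outdir / "expression.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    manifest = {
        "genome": "genome.fa",
        "tags": {c: f"tags/{c}.bed" for c in sorted(libs)},
        "tag_counts": tag_counts,
        "genes": "genes.tsv",
        "expression": "expression.tsv",
        "truth": "truth.json",
        "config": "config.yaml",
        "n_sites": len(truth.sites),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
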
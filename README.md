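# cobind

Comparative ChIP-seq analysis of transcription-factor co-binding and
tethering.

## The problem

When two transcription factors occupy the same genomic locus, two very
different mechanisms can explain it. In **direct (adjacent)
co-occupancy** each factor binds its own DNA motif; in **tethering** the
focal factor has no DNA contact at the shared sites and is held there
through protein–protein interaction with the DNA-bound partner. The two
mechanisms leave opposite sequence signatures, famously used to show that
the Wnt effector TCF7L2 is tethered to breast-cancer-specific sites by
GATA3: shared sites are enriched for the partner's motif (the GATA word
`WGATAR`) but **not** for the focal factor's own motif (the TCF/LEF word
`SCTTTGAW`), while focal-only sites carry the focal motif as usual.

`cobind` implements the full analysis chain needed to make that inference
from aligned-tag data, end to end:

1. **Peak calling** — fragment-extended bin coverage with an
   input-referenced empirical FDR: the height threshold *h* is the
   smallest with `eFDR(h) = (# scaled input bins ≥ h)/(# ChIP bins ≥ h)
   ≤ 0.05`. Copy-number-amplified segments are detected from the input
   (windowed coverage / genome median ≥ 3) and their bins are kept out of
   the null; peaks inside them are flagged.
2. **Replicate QC** — the 80%-of-top-40% replicate-overlap rule, and
   saturation curves from subsampled libraries.
3. **Comparative binding** — pairwise overlap matrices, cell-type
   specific and common peak sets, H3K4me1+H3K27ac active-enhancer
   derivation and occupancy, nearest-TSS annotation and peaks-per-gene
   summaries.
4. **Signal profiles** — per-million tag-density matrices around summits,
   k-means-ordered heatmaps, average profiles.
5. **Motif analysis** — IUPAC consensus scanning, de novo k-mer discovery
   (presence/absence Fisher exact vs dinucleotide-shuffled background,
   Benjamini–Hochberg corrected), motif-recovery curves and
   center-relative motif density.
6. **Tethering inference** — overlap-class partition, class-wise motif
   enrichment, and a three-way verdict (`tethered_via_partner`,
   `direct_co_occupancy`, `indeterminate`).
7. **Knockdown co-regulation** — co-bound genes classified by their
   expression response to knocking down either factor (cooperative
   repression, antagonized activation, ...).

A seeded synthetic-data generator with a machine-readable planted truth
(binding modes, motif instances, enhancers, amplifications, expression
effects) drives all recovery tests and the demo pipeline.

## Worked example

```python
from cobind.simulate import SimConfig, plant_sites, generate_reads
from cobind.peaks import call_peaks
from cobind.motifs import ConsensusMotif
from cobind.tethering import (partition_overlap_classes,
                              class_motif_enrichment, call_tethering)

cfg = SimConfig(seed=1, n_direct=80, n_tethered=80, n_partner_only=40, n_adjacent=0)
genome, truth = plant_sites(cfg)
libs = generate_reads(truth, cfg)
chrl = {c: len(s) for c, s in genome.items()}

focal = call_peaks(libs["focal_rep1"].merge(libs["focal_rep2"]), libs["input"], chrom_lengths=chrl)
partner = call_peaks(libs["partner_rep1"].merge(libs["partner_rep2"]), libs["input"], chrom_lengths=chrl)
classes = partition_overlap_classes(focal, partner)
table = class_motif_enrichment(
    classes,
    [ConsensusMotif("focal", cfg.focal_motif), ConsensusMotif("partner", cfg.partner_motif)],
    genome, seed=1,
)
for r in table:
    print(f"{r.class_label:>8} {r.motif_name:>7}: {100*r.fraction_with_motif:5.1f}% "
          f"(bg {100*r.background_fraction:4.1f}%)  q={r.q_value:.2g}")
print(call_tethering(table, "focal", "partner").verdict)
```

prints

```
  a_only   focal:  97.5% (bg  0.0%)  q=2.2e-43
  a_only partner:  22.5% (bg 17.5%)  q=0.28
  b_only   focal:   5.0% (bg  0.0%)  q=0.28
  b_only partner: 100.0% (bg 17.5%)  q=1.2e-15
  shared   focal:   2.5% (bg  0.0%)  q=0.28
  shared partner: 100.0% (bg 27.5%)  q=3.9e-25
tethered_via_partner
```

Read this as the tethering signature: the 80 shared peaks all sit on a
GATA-type word but essentially never on a TCF-type word, while the 80
focal-only peaks carry the TCF-type word (the positive control) — so the
focal factor is being recruited to shared sites by the partner, not by
its own motif. Re-running with `n_tethered=0, n_adjacent=80` plants both
words at shared sites and the verdict flips to `direct_co_occupancy`.

The `examples/` directory has one short script per capability
(simulation, peak calling, replicate QC, motif analysis, tethering,
full pipeline); each prints the numbers it computes and what they mean.
The same functionality is available from the shell:

```bash
cobind simulate --seed 1 --out bundle/
cobind callpeaks --chip bundle/tags/focal_rep1.bed --input bundle/tags/input.bed --out peaks.bed
cobind run --config config.yaml --out results/
```

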
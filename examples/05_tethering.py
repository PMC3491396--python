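"""The headline analysis: is the focal factor tethered to shared sites by
the partner, or do the two factors bind adjacently on their own motifs?

Runs one tethered-mode simulation and one adjacent-mode simulation and
prints the class-wise motif enrichment and the verdict for each.
"""

from cobind.compare import annotate_nearest_tss
from cobind.motifs import ConsensusMotif
from cobind.peaks import call_peaks
from cobind.simulate import SimConfig, generate_reads, plant_sites
from cobind.tethering import (
    call_tethering,
    class_motif_enrichment,
    classify_coregulation,
    cobound_gene_set,
    partition_overlap_classes,
)


def analyze(config, label):
    genome, truth = plant_sites(config)
    libs = generate_reads(truth, config)
    chrl = {c: len(s) for c, s in genome.items()}
    focal = call_peaks(libs["focal_rep1"].merge(libs["focal_rep2"]), libs["input"], chrom_lengths=chrl, label="focal")
    partner = call_peaks(libs["partner_rep1"].merge(libs["partner_rep2"]), libs["input"], chrom_lengths=chrl, label="partner")
    classes = partition_overlap_classes(focal, partner)
    table = class_motif_enrichment(
        classes,
        [ConsensusMotif("focal", config.focal_motif), ConsensusMotif("partner", config.partner_motif)],
        genome,
        seed=config.seed,
    )
    print(f"--- {label} ---")
    print(f"classes: focal-only {len(classes.a_only)}, partner-only {len(classes.b_only)}, shared {len(classes.shared)}")
    for r in table:
        print(f"  {r.class_label:>8} {r.motif_name:>7}: {100 * r.fraction_with_motif:5.1f}% "
              f"(bg {100 * r.background_fraction:4.1f}%)  fold {r.enrichment:5.1f}  q={r.q_value:.2g}")
    verdict = call_tethering(table, "focal", "partner")
    print(f"verdict: {verdict.verdict}\n")
    return genome, truth, focal, partner


tethered_cfg = SimConfig(seed=1, n_adjacent=0, n_direct=80, n_tethered=80, n_partner_only=40)
genome, truth, focal, partner = analyze(tethered_cfg, "tethered-mode simulation")

adjacent_cfg = SimConfig(seed=1, n_tethered=0, n_direct=80, n_adjacent=80, n_partner_only=40)
analyze(adjacent_cfg, "adjacent-mode simulation")

# knockdown co-regulation at co-bound genes (tethered-mode bundle)
annot_f = annotate_nearest_tss(focal, truth.genes)
annot_p = annotate_nearest_tss(partner, truth.genes)
cobound = cobound_gene_set(annot_f, annot_p)
effects = truth.expression_effects
calls = classify_coregulation(
    cobound, {g: v[0] for g, v in effects.items()}, {g: v[1] for g, v in effects.items()}
)
counts = {}
for c in calls:
    counts[c.category] = counts.get(c.category, 0) + 1
print(f"co-bound genes: {len(cobound)}; knockdown response classes: {counts}")
print(
    "\nTethered mode shows the diagnostic asymmetry (partner motif enriched\n"
    "at shared sites, focal motif absent) and co-bound genes going up under\n"
    "either knockdown - repression through the tether. Adjacent mode shows\n"
    "both motifs enriched at shared sites instead."
)
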
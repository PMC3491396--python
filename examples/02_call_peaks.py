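"""Call peaks with the input-referenced empirical FDR and score recovery
against the planted truth."""

from cobind.peaks import call_peaks, detect_amplified_regions
from cobind.simulate import SimConfig, generate_reads, plant_sites

config = SimConfig(seed=1)
genome, truth = plant_sites(config)
libs = generate_reads(truth, config)
chrom_lengths = {c: len(s) for c, s in genome.items()}

amplified = detect_amplified_regions(libs["input"], chrom_lengths=chrom_lengths)
print("amplified regions detected:")
for r in amplified:
    print(f"  {r.interval.chrom}:{r.interval.start:,}-{r.interval.end:,}  fold {r.fold:.1f}")

chip = libs["focal_rep1"].merge(libs["focal_rep2"])
peaks = call_peaks(
    chip, libs["input"], chrom_lengths=chrom_lengths,
    exclude=[r.interval for r in amplified],
)
sites = truth.sites_for_factor("focal")
recall = sum(
    any(p.chrom == s.chrom and abs(p.summit - s.position) <= 250 for p in peaks) for s in sites
) / len(sites)
precision = sum(
    any(p.chrom == s.chrom and abs(p.summit - s.position) <= 250 for s in sites) for p in peaks
) / len(peaks)

print(f"\npeaks called : {len(peaks)} (truth: {len(sites)} focal-occupied sites)")
print(f"recall       : {recall:.3f}")
print(f"precision    : {precision:.3f}")
print(
    "\nRecall/precision near 1 mean the bin-threshold caller with empirical\n"
    "FDR recovers essentially every planted site and calls almost nothing\n"
    "else; masking amplified bins keeps copy-number noise out of the null."
)
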
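"""De novo k-mer discovery, motif-recovery curve, and center-relative
motif density on called peaks."""

import numpy as np

from cobind.motifs import (
    ConsensusMotif,
    kmer_discovery,
    motif_density_profile,
    motif_recovery_curve,
    peak_sequences,
)
from cobind.peaks import call_peaks
from cobind.simulate import SimConfig, generate_reads, plant_sites

config = SimConfig(seed=1)
genome, truth = plant_sites(config)
libs = generate_reads(truth, config)
chrl = {c: len(s) for c, s in genome.items()}
peaks = call_peaks(libs["focal_rep1"].merge(libs["focal_rep2"]), libs["input"], chrom_lengths=chrl)

# discovery: 300 bp around the summits of the top peaks vs shuffled background
foreground = peak_sequences(peaks.ranked(), genome, window=300)
print("top 6-mers (foreground vs dinucleotide-shuffled background):")
for r in kmer_discovery(foreground, None, k=6, seed=1)[:5]:
    print(f"  {r.rank}. {r.kmer}  fg {r.fg_count}/{len(foreground)}  fold {r.enrichment:.1f}  q={r.q_value:.2g}")

focal = ConsensusMotif("focal", config.focal_motif)
curve = motif_recovery_curve(peaks, genome, focal, steps=[50, 100, len(peaks)])
print("\nmotif recovery (top-N peaks containing the focal consensus):")
for n, frac in curve:
    print(f"  top {n:>4} : {100 * frac:.0f}%")

profile = motif_density_profile(peaks, genome, focal)
center_bin = int(np.argmax(profile.density))
lo, hi = profile.bin_edges[center_bin], profile.bin_edges[center_bin + 1]
print(f"\ndensity profile mode: [{lo:+.0f}, {hi:+.0f}) bp from peak center")
print(
    "\nThe planted TCF-type core word dominates discovery, most high-ranked\n"
    "peaks contain it, and hits pile up at peak centers - the signature of\n"
    "direct, motif-driven binding. Tethered sites dilute the recovery\n"
    "fraction at larger N."
)
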
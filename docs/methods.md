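# Methods

`cobind` implements a comparative ChIP-seq analysis for distinguishing two
mechanisms by which a transcription factor can occupy the same genomic
locus as a partner factor: **direct (adjacent) co-binding**, in which each
factor sits on its own DNA motif, and **tethering**, in which the focal
factor carries no DNA contact of its own and is held at the site through
protein–protein interaction with the DNA-bound partner. The diagnostic is
purely sequence-based: partition the focal factor's peaks by overlap with
the partner's peaks, then ask which consensus motifs are enriched in each
class. Shared sites enriched for the partner motif but *not* the focal
motif — while focal-only sites do carry the focal motif — indicate
tethering; both motifs enriched at shared sites indicate adjacent binding.

## Peak calling

Tags (aligned 5′ read positions with strand) are extended to the assumed
fragment length (default 200 bp, the typical sonication size selection)
in the strand direction and counted per fixed-width bin (default 100 bp
for point-source factors, 500 bp for broad histone marks). The input
(non-immunoprecipitated chromatin) track is scaled to the ChIP library
size by the total-tag ratio, and the peak-height threshold *h* is the
smallest integer with empirical FDR

    eFDR(h) = (# scaled input bins ≥ h) / (# ChIP bins ≥ h) ≤ fdr

(default fdr = 0.05), floored at `min_height` fragments per bin (default
4; 8 for histone marks) to guard against degenerate thresholds in sparse
tracks. Runs of threshold-exceeding bins become peaks; the summit is the
base pair of maximal local fragment coverage (first position on ties, so
results are deterministic), and the score is the maximal bin count per
million ChIP tags. Score ties in ranking are broken by (chromosome,
start).

Copy-number-amplified segments are detected from the input alone: 10 kb
windows whose pseudo-counted coverage ratio to the genome-wide median
reaches 3 are merged, with the mean ratio reported as the fold. Two
design choices follow from amplification:

* **Amplified bins are excluded from the eFDR null** when regions are
  supplied. Without this, the inflated input tail forces the threshold up
  to the amplified coverage level and sensitivity collapses genome-wide —
  the null should describe ordinary background, not copy-number gain.
* **Peaks inside amplified regions are flagged, not dropped**; the
  cell-type-specificity analysis removes them downstream, so the
  information is preserved for inspection.

## Replicate QC and saturation

Reproducibility uses the replicate-overlap rule: truncate both replicate
peak lists to the shorter length L, then require that 80% of the top
⌈0.4·L⌉ peaks of each list overlap the other truncated list, in both
directions. The rule is applied against the truncated partner list by
default (a switch selects the full list; the choice only matters when the
lists differ greatly in depth). "Top 40%" counts ⌈0.4·L⌉ peaks.

Saturation subsamples the ChIP library without replacement at fractions
0.1–1.0 (without replacement, since resampling with replacement would
fabricate duplicate tags), calls peaks on each subsample (3 independent
draws per fraction), and reports mean ± sd peak counts. A plateau —
the 80% count within ~10% of the full count — indicates the library
depth suffices to find the large majority of sites.

## Comparative binding and enhancers

Overlap means ≥ 1 shared bp under 0-based half-open coordinates
(book-ended intervals do not overlap); a minimum-overlap parameter is
exposed everywhere. Common peaks are anchored on the first listed set
(the anchor is a parameter — the common-set size is anchor-dependent and
there is no canonical choice). Active enhancers are the merged spans of
overlapping H3K4me1/H3K27ac peak pairs, reduced to disjoint intervals:
both marks together are the standard signature of active enhancer
chromatin. Nearest-gene assignment measures peak-center (summit) to TSS
distance, signed positive downstream in gene orientation; equidistant
TSSs break lexicographically by gene id. Distance histogram bins default
to 0–1, 1–5, 5–10, 10–50, 50–100 and >100 kb.

## Signal profiles

The heatmap matrix assigns each tag once — to the bin containing its
extended-fragment midpoint — within ±3 kb of each site center, scaled per
million library tags so libraries of different depth are comparable (and
so the matrix total conserves the in-window tag count). Rows are ordered
by k-means (default k = 3, fixed seed, `n_init` = 10) with clusters
relabelled by descending mean signal and rows sorted by descending row
mean within clusters, making the ordering reproducible and invariant to
input row order.

## Motif statistics

Consensus motifs are IUPAC-degenerate words (TCF/LEF core `SCTTTGAW`,
GATA `WGATAR`); scanning uses compiled regular expressions with a
lookahead so overlapping occurrences are reported, plus the reverse
complement when the word is not palindromic. `N` in the sequence is
matched only by N-tolerant letters.

De novo discovery is at the k-mer level: each sequence is reduced to the
set of strand-collapsed (canonical) k-mers it contains; per-k-mer
enrichment of foreground presence counts over background is tested with
a one-sided Fisher exact test (hypergeometric tail) and
Benjamini–Hochberg corrected. Presence/absence per sequence, rather than
occurrence counts, is deliberate: the question is how many peaks contain
the motif. The default background is an exact dinucleotide shuffle of the
foreground (Altschul–Erickson style Euler-path shuffle, preserving the
full dinucleotide composition of every sequence), so base-composition and
CpG-type biases cannot masquerade as enrichment. Foreground windows are
300 bp around the summits of the top 1,000 peaks by score.

Class-wise enrichment for the tethering call uses the same Fisher/BH
machinery but a **100 bp** window centered on the summit rather than
300 bp. This is a deliberate asymmetry: a 6-bp word with four concrete
instantiations (like the GATA consensus) hits ≈45% of random 300-mers by
chance, which caps the achievable enrichment fold near 2 regardless of
the biology; at 100 bp the chance rate drops to ≈17% while genuinely
motif-driven peaks still carry the word at their center (summits are
base-pair accurate). Discovery keeps the 300 bp window, where the
foreground/background contrast — not the absolute rate — carries the
signal.

The tethering verdict is a pure function of the enrichment table and
three thresholds: *enriched* means q < 0.01 and fold ≥ 2; *not enriched*
means q ≥ 0.05 or fold < 2. `tethered_via_partner` requires the shared
class to have the partner motif enriched and the focal motif not, with
the focal motif enriched in the focal-only class as positive control;
`direct_co_occupancy` requires both motifs enriched in the shared class;
anything else is `indeterminate`. The thresholds are free choices (the
underlying argument is qualitative presence/absence); they are exposed in
configuration and echoed in the verdict record.

## Knockdown co-regulation

Expression inputs are categorical per-gene change calls (up/down/ns)
under knockdown of each factor — differential-expression testing from
read counts is upstream of this package. Co-bound genes (intersection of
the two factors' distinct nearest-gene sets) are classified by their
change pair: (up, up) cooperative repression; (up under focal knockdown,
down under partner knockdown) partner activation antagonized by the focal
factor; (down, down) cooperative activation; (down, up) focal activation
antagonized; any ns leaves the gene unclassified. Every co-bound gene
receives exactly one category.

## The synthetic-data generator

The generator is first-class, tested code, not a fixture. It emulates:

* a toy genome (2 chromosomes × 1 Mb, i.i.d. uniform nucleotides) with
  ~200 non-overlapping planted sites (≥ 3 kb spacing) in four modes —
  direct (focal word), tethered (partner word only, but ChIP signal for
  both factors), partner-only, and adjacent co-bound (both words ~15 bp
  apart); degenerate consensus positions are instantiated uniformly;
* point-source ChIP physics: per-site tag counts Poisson with mean
  occupancy × background density × fragment length (occupancy uniform in
  [10, 20]; background 0.02 tags/bp), 5′ positions strand-shifted by half
  a fragment with Gaussian jitter (sd 30 bp) — the standard bimodal
  strand asymmetry of point-source factors;
* uniform input with amplified segments (2 × 100 kb at fold 5);
* broad histone-mark libraries as box kernels over 1.5 kb enhancer
  domains planted over 60% of sites at occupancy 8;
* independent replicate libraries (2 per factor) from the same model;
* expression calls consistent with repression at tethered sites: the
  gene nearest each tethered site is "up" under either knockdown with
  probability 0.9, genes near adjacent co-bound sites respond per
  configuration (default down/down), all others "ns".

Everything is reproducible bit-exactly from (config, seed), the written
bundle (FASTA, BED6 tags, TSVs, truth JSON, YAML config) regenerates
byte-identically, and every planted word is literally present in the
FASTA at its recorded position.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mappability and repeat structure, GC and
chromatin-accessibility bias in input, realistic motif information
content (real PWMs are softer than consensus words), overlapping or
clustered binding sites, read sequences and sequencing error, diploid
copy number, and the indirect, noisy coupling between binding and
expression. Recovery rates near 1.0 on this generator demonstrate
correctness of the machinery under its stated model, not expected
performance on ENCODE-scale data; the published study's absolute peak
counts and overlap percentages are not reproducible at this scale and are
not targets.

## Problem sizes and determinism

Default scale (2 Mb genome, ~50 k tags per library, 200 sites) was chosen
so the full pipeline completes in seconds and multi-seed robustness
checks (10–20 simulations) complete in a couple of minutes on one CPU.
All randomness flows through `numpy.random.default_rng` seeded from the
single config seed; the pipeline writes a manifest of SHA-256 checksums
and reruns are bit-identical. TSV floats are formatted with `%.6g` so
output bytes do not depend on platform repr differences.

## Known limitations

* The peak caller is a transparent bin-threshold design; it does not
  model local background (no per-window lambda), fragment-size
  estimation, or duplicate filtering, and broad-mark calling is the same
  thresholding with larger bins.
* The empirical FDR is genome-global; strong local artifacts other than
  detected amplifications can still distort the threshold.
* k-mer discovery ranks words, not position weight matrices; a PWM can
  be derived from aligned top-k-mer instances but no EM/Gibbs refinement
  is attempted.
* The tethering verdict consumes marginal enrichment only; it does not
  model joint motif spacing or orientation at shared sites.
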
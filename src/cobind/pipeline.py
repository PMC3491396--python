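"""Config-driven orchestration: simulate -> call peaks -> replicate QC ->
saturation -> comparative binding -> motifs -> tethering -> co-regulation,
with a checksummed manifest so a rerun under the same config and seed is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import compare, motifs, peaks, profiles, qc, simulate, tethering
from .core import (
    read_fasta,
    read_gene_annotation,
    read_tags,
    write_peaks,
)

__all__ = ["ConfigError", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("cobind.pipeline")


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULTS = {
    "peak_calling": {"bin_width": 100, "fdr": 0.05, "min_height": 4},
    "histone_peak_calling": {"bin_width": 500, "fdr": 0.05, "min_height": 8},
    "amplified": {"window": 10_000, "fold_min": 3.0},
    "reproducibility": {"top_fraction": 0.40, "threshold": 0.80},
    "saturation": {"fractions": [0.25, 0.5, 0.75, 1.0], "reps": 2, "enabled": True},
    "motifs": {"k": 6, "top_n": 1000, "window": 300},
    "tethering": {"q_enriched": 0.01, "fold_min": 2.0, "q_not": 0.05, "window": 100},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _merged(cfg: dict, section: str) -> dict:
    out = dict(DEFAULTS.get(section, {}))
    out.update(cfg.get(section, {}) or {})
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for v in row) + "\n")


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the full analysis described by ``config``; returns the manifest.

    The config is a flat YAML mapping with a ``simulate`` block (SimConfig
    fields) or an ``inputs`` block (paths to genome/tags/genes/expression),
    optional per-stage parameter blocks, and ``seed``/``outdir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if outdir is None:
        outdir = config.get("outdir")
    if outdir is None:
        raise ConfigError("no output directory: pass outdir or set it in the config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))

    if "simulate" not in config and "inputs" not in config:
        raise ConfigError("config must contain a 'simulate' block or an 'inputs' block")

    artifacts: list[tuple[str, Path]] = []  # (stage, path)

    def _record(stage: str, path: Path) -> None:
        artifacts.append((stage, path))

    # ---- stage: inputs -------------------------------------------------
    try:
        if "simulate" in config:
            sim_cfg = simulate.SimConfig.from_dict({**(config["simulate"] or {}), "seed": seed})
            sim_dir = outdir / "data"
            simulate.simulate_dataset(sim_cfg, sim_dir)
            for rel in ["genome.fa", "genes.tsv", "expression.tsv", "truth.json", "config.yaml", "manifest.json"]:
                _record("simulate", sim_dir / rel)
            for f in sorted((sim_dir / "tags").iterdir()):
                _record("simulate", f)
            genome = read_fasta(sim_dir / "genome.fa")
            genes = read_gene_annotation(sim_dir / "genes.tsv")
            expression = simulate.read_expression_table(sim_dir / "expression.tsv")
            fl = sim_cfg.fragment_length
            libs = {
                f.stem: read_tags(f, fragment_length=fl)
                for f in sorted((sim_dir / "tags").iterdir())
            }
            focal_iupac, partner_iupac = sim_cfg.focal_motif, sim_cfg.partner_motif
            chrom_lengths = {c: len(s) for c, s in genome.items()}
        else:
            inp = config["inputs"]
            for key in ("genome", "tags", "genes", "expression"):
                if key not in inp:
                    raise ConfigError(f"inputs block missing {key!r}")
            genome = read_fasta(inp["genome"])
            genes = read_gene_annotation(inp["genes"])
            expression = simulate.read_expression_table(inp["expression"])
            fl = int(inp.get("fragment_length", 200))
            libs = {name: read_tags(path, fragment_length=fl) for name, path in sorted(inp["tags"].items())}
            focal_iupac = inp.get("focal_motif", "SCTTTGAW")
            partner_iupac = inp.get("partner_motif", "WGATAR")
            chrom_lengths = {c: len(s) for c, s in genome.items()}
        if "input" not in libs:
            raise ConfigError("no 'input' (control) tag library")
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(f"inputs: {exc}") from exc

    focal_motif = motifs.ConsensusMotif("focal", focal_iupac)
    partner_motif = motifs.ConsensusMotif("partner", partner_iupac)
    input_lib = libs["input"]
    log.info("inputs ready: %d libraries, %d genes", len(libs), len(genes))

    # ---- stage: amplified regions --------------------------------------
    try:
        amp_params = _merged(config, "amplified")
        regions = peaks.detect_amplified_regions(
            input_lib, chrom_lengths=chrom_lengths, **amp_params
        )
        path = outdir / "amplified_regions.bed"
        with open(path, "w") as fh:
            for r in regions:
                fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\tamp\t{r.fold:.3f}\n")
        _record("amplified", path)
        log.info("amplified regions: %d", len(regions))
    except Exception as exc:
        raise StageError(f"amplified: {exc}") from exc

    # ---- stage: peak calling -------------------------------------------
    try:
        pk_params = _merged(config, "peak_calling")
        amp_iv = [r.interval for r in regions]
        rep_names = {f: sorted(n for n in libs if n.startswith(f + "_rep")) for f in ("focal", "partner")}
        rep_peaks: dict[str, object] = {}
        factor_peaks: dict[str, object] = {}
        for factor, names in rep_names.items():
            if not names:
                raise ValueError(f"no replicate libraries for factor {factor!r}")
            merged_lib = None
            for name in names:
                rep_peaks[name] = peaks.call_peaks(
                    libs[name], input_lib, chrom_lengths=chrom_lengths, exclude=amp_iv,
                    label=name, **pk_params
                )
                merged_lib = libs[name] if merged_lib is None else merged_lib.merge(libs[name])
            ps = peaks.call_peaks(
                merged_lib, input_lib, chrom_lengths=chrom_lengths, exclude=amp_iv,
                label=factor, **pk_params
            )
            peaks.flag_amplified_peaks(ps, regions)
            factor_peaks[factor] = ps
            path = outdir / f"peaks_{factor}.bed"
            write_peaks(ps, path)
            _record("peak_calling", path)
            log.info("peaks %s: %d (replicates: %s)", factor, len(ps), {n: len(rep_peaks[n]) for n in names})
        merged_libs = {
            f: libs[rep_names[f][0]] if len(rep_names[f]) == 1
            else libs[rep_names[f][0]].merge(libs[rep_names[f][1]])
            for f in rep_names
        }
    except Exception as exc:
        raise StageError(f"peak_calling: {exc}") from exc

    # ---- stage: replicate QC -------------------------------------------
    try:
        qc_params = _merged(config, "reproducibility")
        rows = []
        for factor, names in rep_names.items():
            if len(names) >= 2:
                rep = qc.encode_overlap_check(rep_peaks[names[0]], rep_peaks[names[1]], **qc_params)
                rows.append(
                    (factor, rep.truncated_length, rep.fraction_a_in_b, rep.fraction_b_in_a,
                     "pass" if rep.passed else "fail")
                )
        path = outdir / "reproducibility.tsv"
        _write_tsv(path, ["factor", "truncated_length", "frac_a_in_b", "frac_b_in_a", "status"], rows)
        _record("replicate_qc", path)
    except Exception as exc:
        raise StageError(f"replicate_qc: {exc}") from exc

    # ---- stage: saturation ---------------------------------------------
    try:
        sat = _merged(config, "saturation")
        if sat.pop("enabled", True):
            curve = qc.saturation_curve(
                merged_libs["focal"], input_lib, call_params={**pk_params, "chrom_lengths": chrom_lengths, "exclude": amp_iv},
                seed=seed, **sat,
            )
            path = outdir / "saturation.tsv"
            _write_tsv(path, ["fraction", "mean_peaks", "sd_peaks"], curve.as_rows())
            _record("replicate_qc", path)
    except Exception as exc:
        raise StageError(f"saturation: {exc}") from exc

    # ---- stage: comparative binding ------------------------------------
    try:
        focal_ps, partner_ps = factor_peaks["focal"], factor_peaks["partner"]
        om = compare.pairwise_overlap_matrix([focal_ps, partner_ps])
        path = outdir / "overlap_matrix.tsv"
        _write_tsv(
            path,
            ["label"] + om.labels,
            [(lab, *map(float, om.matrix[i])) for i, lab in enumerate(om.labels)],
        )
        _record("comparative_binding", path)

        hist_params = _merged(config, "histone_peak_calling")
        k4 = peaks.call_peaks(libs["h3k4me1"], input_lib, chrom_lengths=chrom_lengths,
                              exclude=amp_iv, label="h3k4me1", **hist_params)
        k27 = peaks.call_peaks(libs["h3k27ac"], input_lib, chrom_lengths=chrom_lengths,
                               exclude=amp_iv, label="h3k27ac", **hist_params)
        enh = compare.active_enhancers(k4, k27)
        path = outdir / "active_enhancers.bed"
        with open(path, "w") as fh:
            for iv in enh:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        _record("comparative_binding", path)
        occ = compare.enhancer_occupancy(focal_ps, k4, k27) if enh else {}
        path = outdir / "enhancer_occupancy.tsv"
        _write_tsv(path, ["metric", "percent"], sorted((k, float(v)) for k, v in occ.items()))
        _record("comparative_binding", path)

        annotated = {}
        summary_rows = []
        for factor, ps in factor_peaks.items():
            recs = compare.annotate_nearest_tss(ps, genes)
            annotated[factor] = recs
            s = compare.target_gene_summary(recs, label=factor)
            summary_rows.append((s.label, s.total_peaks, s.nearest_gene_count, s.peaks_per_gene))
        path = outdir / "target_gene_summary.tsv"
        _write_tsv(path, ["label", "total_peaks", "nearest_genes", "peaks_per_gene"], summary_rows)
        _record("comparative_binding", path)

        prof = compare.tss_distance_profile(annotated["focal"])
        path = outdir / "tss_distance_profile.tsv"
        _write_tsv(path, ["bin", "percent"], list(zip(prof.bin_labels, map(float, prof.percentages))))
        _record("comparative_binding", path)
    except Exception as exc:
        raise StageError(f"comparative_binding: {exc}") from exc

    # ---- stage: signal profiles ----------------------------------------
    try:
        mat = profiles.tag_density_matrix(focal_ps, merged_libs["focal"])
        avg = profiles.average_profile(mat)
        path = outdir / "average_profile_focal.tsv"
        _write_tsv(path, ["bin_center_bp", "tags_per_million"], list(zip(map(int, mat.bin_centers), map(float, avg))))
        _record("signal_profiles", path)
    except Exception as exc:
        raise StageError(f"signal_profiles: {exc}") from exc

    # ---- stage: motif analysis -----------------------------------------
    try:
        mo = _merged(config, "motifs")
        top = focal_ps.top(min(mo["top_n"], len(focal_ps)))
        fg = motifs.peak_sequences(top.ranked(), genome, window=mo["window"])
        kmers = motifs.kmer_discovery(fg, None, k=mo["k"], seed=seed)
        path = outdir / "kmer_discovery.tsv"
        _write_tsv(
            path,
            ["rank", "kmer", "fg_count", "bg_count", "enrichment", "p", "q"],
            [(r.rank, r.kmer, r.fg_count, r.bg_count, float(r.enrichment), r.p_value, r.q_value)
             for r in kmers[:50]],
        )
        _record("motif_analysis", path)

        steps = [n for n in (100, 250, 500, 1000, len(focal_ps)) if n <= len(focal_ps)]
        curve = motifs.motif_recovery_curve(focal_ps, genome, focal_motif, steps=sorted(set(steps)))
        path = outdir / "motif_recovery.tsv"
        _write_tsv(path, ["top_n", "fraction_with_motif"], [(n, float(f)) for n, f in curve])
        _record("motif_analysis", path)

        rows = []
        for m in (focal_motif, partner_motif):
            prof_m = motifs.motif_density_profile(focal_ps, genome, m)
            centers = (prof_m.bin_edges[:-1] + prof_m.bin_edges[1:]) / 2
            rows += [(m.name, int(c), float(d)) for c, d in zip(centers, prof_m.density)]
        path = outdir / "motif_density.tsv"
        _write_tsv(path, ["motif", "bin_center_bp", "hits_per_site"], rows)
        _record("motif_analysis", path)
    except Exception as exc:
        raise StageError(f"motif_analysis: {exc}") from exc

    # ---- stage: tethering ----------------------------------------------
    try:
        te = _merged(config, "tethering")
        classes = tethering.partition_overlap_classes(focal_ps, partner_ps)
        table = tethering.class_motif_enrichment(
            classes, [focal_motif, partner_motif], genome, window=te["window"], seed=seed
        )
        path = outdir / "class_enrichment.tsv"
        _write_tsv(
            path,
            ["class", "motif", "n_sites", "fraction", "background", "fold", "p", "q"],
            [(r.class_label, r.motif_name, r.n_sites, r.fraction_with_motif,
              r.background_fraction, float(r.enrichment), r.p_value, r.q_value) for r in table],
        )
        _record("tethering", path)
        verdict = tethering.call_tethering(
            table, focal_motif="focal", partner_motif="partner",
            q_enriched=te["q_enriched"], fold_min=te["fold_min"], q_not=te["q_not"],
        )
        path = outdir / "tethering_verdict.json"
        with open(path, "w") as fh:
            json.dump(
                {
                    "verdict": verdict.verdict,
                    "thresholds": verdict.thresholds,
                    "class_sizes": {"a_only": len(classes.a_only), "b_only": len(classes.b_only),
                                    "shared": len(classes.shared)},
                },
                fh, indent=1, sort_keys=True,
            )
        _record("tethering", path)
        log.info("tethering verdict: %s", verdict.verdict)
    except Exception as exc:
        raise StageError(f"tethering: {exc}") from exc

    # ---- stage: co-regulation ------------------------------------------
    try:
        cobound = tethering.cobound_gene_set(annotated["focal"], annotated["partner"])
        focal_changes = {g: v[0] for g, v in expression.items()}
        partner_changes = {g: v[1] for g, v in expression.items()}
        calls = tethering.classify_coregulation(cobound, focal_changes, partner_changes)
        path = outdir / "coregulation.tsv"
        _write_tsv(path, ["gene_id", "category"], [(c.gene_id, c.category) for c in calls])
        _record("coregulation", path)
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.category] = counts.get(c.category, 0) + 1
        path = outdir / "coregulation_summary.tsv"
        _write_tsv(path, ["category", "genes"], sorted(counts.items()))
        _record("coregulation", path)
    except Exception as exc:
        raise StageError(f"coregulation: {exc}") from exc

    # ---- manifest ------------------------------------------------------
    manifest = {
        "seed": seed,
        "artifacts": [
            {"stage": stage, "file": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for stage, p in artifacts
        ],
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
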
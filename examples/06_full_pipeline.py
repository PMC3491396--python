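"""Run the whole pipeline from a single config and inspect the manifest.

Equivalent shell command:
    cobind run --config config.yaml --out scratch/pipeline_demo
"""

import json
from pathlib import Path

from cobind.pipeline import run_pipeline

config = {
    "simulate": {"n_direct": 60, "n_tethered": 60, "n_partner_only": 40, "n_adjacent": 40},
    "seed": 1,
    "saturation": {"fractions": [0.5, 1.0], "reps": 2},
}
outdir = Path("scratch/pipeline_demo")
manifest = run_pipeline(config, outdir)

stages = {}
for a in manifest["artifacts"]:
    stages.setdefault(a["stage"], []).append(a["file"])
for stage, files in stages.items():
    print(f"{stage:>20}: {len(files)} file(s)")

verdict = json.loads((outdir / "tethering_verdict.json").read_text())
print(f"\ntethering verdict: {verdict['verdict']} (classes {verdict['class_sizes']})")
print((outdir / "target_gene_summary.tsv").read_text())
print(
    "Every artifact is checksummed in run_manifest.json; rerunning with the\n"
    "same config and seed reproduces the checksums bit-exactly. This default\n"
    "config mixes tethered and adjacent sites, so shared sites carry both\n"
    "motifs and the verdict is direct co-occupancy."
)
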
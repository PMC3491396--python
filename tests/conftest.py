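import numpy as np
import pytest

from cobind.peaks import call_peaks, detect_amplified_regions
from cobind.simulate import SimConfig, generate_reads, plant_sites


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """Default synthetic dataset, generated once per session."""
    genome, truth = plant_sites(sim_config)
    libs = generate_reads(truth, sim_config)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    return {
        "config": sim_config,
        "genome": genome,
        "truth": truth,
        "libs": libs,
        "chrom_lengths": chrom_lengths,
    }


@pytest.fixture(scope="session")
def amplified_regions(bundle):
    return detect_amplified_regions(bundle["libs"]["input"], chrom_lengths=bundle["chrom_lengths"])


@pytest.fixture(scope="session")
def factor_peaks(bundle, amplified_regions):
    """Merged-replicate peak sets for both factors on the default bundle."""
    libs = bundle["libs"]
    chrl = bundle["chrom_lengths"]
    amp = [r.interval for r in amplified_regions]
    out = {}
    for factor in ("focal", "partner"):
        merged = libs[f"{factor}_rep1"].merge(libs[f"{factor}_rep2"])
        out[factor] = call_peaks(merged, libs["input"], chrom_lengths=chrl, exclude=amp, label=factor)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
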
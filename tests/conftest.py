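import numpy as np
import pytest
from hypothesis import settings

import sumdemux as sd

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_small():
    """Compact two-species reference for unit tests."""
    return sd.make_toy_reference(seed=11, size=50_000, n_genes=8, n_peaks=12)


@pytest.fixture(scope="session")
def ref_default():
    """Full-size default reference (100 kb per species)."""
    return sd.make_toy_reference(seed=1)


@pytest.fixture(scope="session")
def sim_noiseless(ref_default, tmp_path_factory):
    """Default-size run with every noise process off: the exactness oracle."""
    cfg = sd.SimConfig(seed=7, seq_error_rate=0.0, ambient_fraction_atac=0.0,
                       ambient_fraction_rna=0.0, hopping_rate=0.0)
    outdir = tmp_path_factory.mktemp("sim_noiseless")
    return sd.simulate_experiment(cfg, ref_default, outdir)


@pytest.fixture(scope="session")
def demux_noiseless(sim_noiseless, ref_default):
    """ATAC and RNA demultiplexing results on the noiseless run."""
    res = sim_noiseless
    atac = sd.demux_atac(res.fastq_paths["ATAC"], ref_default,
                         res.whitelists["ATAC_sample"],
                         res.whitelists["droplet"], res.sample_maps["ATAC"])
    rna = sd.demux_rna(res.fastq_paths["RNA"], ref_default,
                       res.whitelists["RNA_sample"],
                       res.whitelists["droplet"], res.sample_maps["RNA"])
    return atac, rna


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
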
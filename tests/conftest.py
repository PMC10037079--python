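import numpy as np
import pandas as pd
import pytest

from svpopgen.simulate import SimConfig, Simulation, identity_profiles
from svpopgen.vcfio import GenotypeMatrix


def make_matrix(dosages, positions=None, chrom="chr1", populations=None, types=None):
    """Small dosage matrix from a nested list (sites x samples)."""
    d = np.asarray(dosages, dtype=np.int16)
    n_sites, n_samples = d.shape
    pos = positions if positions is not None else (np.arange(n_sites) + 1) * 10_000
    pops = populations if populations is not None else ["P1"] * n_samples
    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "type": types if types is not None else "SNP",
        "end": None, "length": 1,
        "id": [f"v{i}" for i in range(n_sites)],
    })
    samples = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n_samples)],
        "population": pops,
        "batch": "b1",
    })
    return GenotypeMatrix(d, sites, samples)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_snps=2000, n_svs=60)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small simulated study shared across read-only tests."""
    return Simulation(small_config).run()


@pytest.fixture(scope="session")
def identity_study():
    cfg = SimConfig(seed=7, n_snps=600, n_svs=40, caller_profiles=identity_profiles())
    return cfg, Simulation(cfg).run()
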
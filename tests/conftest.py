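import numpy as np
import pandas as pd
import pytest

from spetpanel import GenotypeMatrix, SimConfig, simulate_founders, simulate_reference


def make_matrix(codes, positions=None, chrom="chr1", sample_prefix="S"):
    """Small GenotypeMatrix from a (samples x sites) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_sites = codes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    ref = ["A"] * n_sites
    alt = ["G"] * n_sites
    sites = pd.DataFrame(
        {"chrom": [chrom] * n_sites, "pos": positions, "ref": ref, "alt": alt}
    )
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
        sites=sites,
        codes=codes,
    )


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(
        seed=11, n_sites=400, n_samples=40, n_chrom=2, chrom_len_bp=150_000
    )


@pytest.fixture(scope="session")
def sim_reference(sim_cfg):
    return simulate_reference(sim_cfg)


@pytest.fixture(scope="session")
def sim_founders(sim_cfg, sim_reference):
    seqs, _ = sim_reference
    matrix, true_q = simulate_founders(sim_cfg, reference=seqs)
    return matrix, true_q
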
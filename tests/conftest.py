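import numpy as np
import pandas as pd
import pytest

from polynet.io import CountMatrix, HomoeologPairing
from polynet.simulate import SimParams, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """10 genes x 4 samples with simple metadata."""
    counts = pd.DataFrame(rng.integers(0, 50, size=(10, 4)),
                          index=[f"g{i}_A" for i in range(5)] + [f"g{i}_D" for i in range(5)],
                          columns=["s1", "s2", "s3", "s4"])
    meta = pd.DataFrame({
        "accession": ["W1", "W2", "D1", "D2"],
        "group": ["wild", "wild", "domesticated", "domesticated"],
        "stage_dpa": [5, 10, 5, 10],
    }, index=counts.columns)
    return CountMatrix(counts, meta)


@pytest.fixture
def small_pairing():
    return HomoeologPairing(pd.DataFrame({
        "gene_A": [f"g{i}_A" for i in range(5)],
        "gene_D": [f"g{i}_D" for i in range(5)],
        "pair_id": [f"g{i}" for i in range(5)],
    }))


@pytest.fixture(scope="session")
def sim_dataset():
    """Mid-size simulated dataset shared across tests (read-only)."""
    params = SimParams(n_pairs=200, module_sizes=(40, 40, 40),
                       split_fraction=0.2, rewire_fraction=0.1,
                       bias_fraction=0.2, bias_lfc=2.0,
                       noise_sd=0.1, dispersion=0.05, seed=77)
    truth, counts, pairing = simulate_dataset(params)
    return params, truth, counts, pairing
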
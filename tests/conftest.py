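import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from trmsig import CountMatrix, SimulationConfig, generate_droplet_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """The default study-conditions droplet experiment (500 cells at mean
    2000 UMI, 5000 empties at mean 50), shared across modules."""
    config = SimulationConfig(seed=1)
    rna, prot, truth = generate_droplet_experiment(config)
    return config, rna, prot, truth


@pytest.fixture(scope="session")
def small_experiment():
    """A lighter experiment for stages that don't need the full fixture."""
    config = SimulationConfig(
        seed=2, n_cells=200, n_empty_droplets=1500, n_genes=400
    )
    rna, prot, truth = generate_droplet_experiment(config)
    return config, rna, prot, truth


@pytest.fixture
def sample_map():
    return {f"HTO{i + 1}": f"sample{i + 1}" for i in range(4)}


def make_count_matrix(dense, genes=None, barcodes=None) -> CountMatrix:
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"b{i}" for i in range(dense.shape[1])]
    return CountMatrix(sp.csr_matrix(dense), genes, barcodes)
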
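import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from loycite import (
    AnnotationTable,
    CountMatrix,
    SimulationConfig,
    simulate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def tiny_annotation():
    return AnnotationTable(
        pd.DataFrame(
            {
                "symbol": ["RPS4Y1", "DDX3Y", "EIF1AY", "CD99", "CD19", "MT-CO1", "RPS4X"],
                "chromosome": ["Y", "Y", "Y", "X;Y", "16", "MT", "X"],
                "region_class": [
                    "MSY", "MSY", "MSY", "PAR", "AUTOSOME", "AUTOSOME", "X_nonPAR",
                ],
            }
        )
    )


def random_count_matrix(rng, n_features=30, n_cells=20, density=0.3, assay="RNA"):
    m = sp.random(
        n_features, n_cells, density=density, random_state=np.random.RandomState(rng.integers(2**31)),
        data_rvs=lambda k: rng.integers(1, 50, size=k),
    )
    features = [f"G{i:03d}" for i in range(n_features)]
    barcodes = [f"BC{i:03d}" for i in range(n_cells)]
    return CountMatrix(m.astype(np.int64), features, barcodes, assay)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic dataset shared across read-only tests."""
    return simulate(SimulationConfig(seed=7))
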
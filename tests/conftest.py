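import numpy as np
import pytest

import circgat as cg


@pytest.fixture(scope="session")
def tiny_dataset() -> cg.SyntheticDataset:
    """Desk-size planted-block dataset shared by fast pipeline tests."""
    return cg.generate_synthetic(
        nc=20, nd=10, k_blocks=2, density_in=0.6, density_out=0.05,
        seq_len=60, mut_rate=0.05, seed=7,
    )


@pytest.fixture()
def toy_graph() -> cg.HetGraph:
    """A small random heterogeneous graph for model-level tests."""
    rng = np.random.default_rng(11)
    nc, nd = 4, 3
    A = (rng.random((nc, nd)) < 0.5).astype(int)
    A[0, 0] = 1  # guarantee at least one edge
    SC = rng.random((nc, nc))
    SC = (SC + SC.T) / 2
    np.fill_diagonal(SC, 1.0)
    SD = rng.random((nd, nd))
    SD = (SD + SD.T) / 2
    np.fill_diagonal(SD, 1.0)
    return cg.build_hetgraph(SC, SD, A, mu=0.6)
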
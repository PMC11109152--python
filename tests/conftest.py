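import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from chromclone import CellCountMatrix
from chromclone.synthdata import SimConfig, simulate_multiome


@pytest.fixture(scope="session")
def small_sim():
    """A small planted multiome shared across unit tests."""
    cfg = SimConfig(
        n_cells=600,
        n_peaks=1200,
        n_genes=120,
        dorc_genes=15,
        peaks_per_dorc=4,
        depth_mean=3000.0,
        seed=11,
    )
    return cfg, simulate_multiome(cfg)


@pytest.fixture(scope="session")
def full_sim():
    """The default study-condition multiome used for parameter-recovery checks."""
    cfg = SimConfig(seed=7)
    return cfg, simulate_multiome(cfg)


@pytest.fixture()
def toy_ccm():
    """3 peaks x 2 cells with counts [[2,0],[1,1],[1,3]]."""
    vals = sp.csr_matrix(np.array([[2, 0], [1, 1], [1, 3]]))
    return CellCountMatrix(
        vals,
        pd.Index(["p0", "p1", "p2"]),
        pd.Index(["c0", "c1"]),
    )
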
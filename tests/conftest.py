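import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from embryoaxis import GeneMatrix, SyntheticCountParams, simulate_counts, simulate_stage_counts


@pytest.fixture
def toy_matrix() -> GeneMatrix:
    """5 genes x 4 cells with one mitochondrial gene and hand-checkable counts."""
    genes = ["MT-CO1", "GAPDH", "POU5F1", "GATA6", "CGA"]
    counts = np.array(
        [
            [30, 0, 0, 2],   # MT-CO1
            [70, 0, 5, 8],   # GAPDH
            [0, 0, 9, 0],    # POU5F1
            [0, 0, 0, 4],    # GATA6
            [0, 0, 1, 6],    # CGA
        ]
    )
    meta = pd.DataFrame(
        {
            "embryo_id": pd.array(["E1", "E1", "E2", "E2"], dtype="string"),
            "stage_dpf": pd.array([9, 9, 11, 11], dtype="Int64"),
            "source": pd.array(["t"] * 4, dtype="string"),
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="barcode"),
    )
    return GeneMatrix(genes, ["c1", "c2", "c3", "c4"], sp.csr_matrix(counts), meta)


@pytest.fixture(scope="session")
def default_sim():
    """Full-size synthetic embryo dataset at the generator's defaults."""
    return simulate_counts(SyntheticCountParams(seed=0))


@pytest.fixture(scope="session")
def stage_sim():
    """Epiblast cells across the four pluripotency stages."""
    return simulate_stage_counts(seed=0)
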
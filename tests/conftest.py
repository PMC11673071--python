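import numpy as np
import pandas as pd
import pytest

from npvuln import GeneExpressionMatrix, GeneList


@pytest.fixture
def np_list():
    return GeneList("np", ["VGF", "SST", "TAC1", "NPY"])


@pytest.fixture
def small_counts():
    """4 genes x 3 cells of raw counts with one NP-free cell."""
    data = pd.DataFrame(
        {
            "c1": [3, 1, 2, 50],
            "c2": [0, 0, 0, 10],
            "c3": [1, 0, 4, 5],
        },
        index=["VGF", "SST", "TAC1", "GAPDH"],
    )
    return GeneExpressionMatrix(data, "raw_counts")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
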
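import numpy as np
import pandas as pd
import pytest

from cofracbench.dataio import Dataset


def make_dataset(matrix, dataset_id="d1", proteins=None):
    """Build a Dataset from a 2-D array (NaN = missing)."""
    mat = np.asarray(matrix, dtype=float)
    if proteins is None:
        proteins = [f"P{i:03d}" for i in range(mat.shape[0])]
    df = pd.DataFrame(mat, index=pd.Index(proteins, name="protein"),
                      columns=pd.RangeIndex(1, mat.shape[1] + 1))
    return Dataset(dataset_id=dataset_id, data=df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_dataset(rng):
    """30 proteins x 12 fractions with ~15% missing cells, no structure."""
    mat = rng.gamma(2.0, 2.0, size=(30, 12))
    mask = rng.random(mat.shape) < 0.15
    mat[mask] = np.nan
    return make_dataset(mat)
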
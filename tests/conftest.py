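import numpy as np
import pandas as pd
import pytest

from drbench.data import ResponseDataset


@pytest.fixture
def tiny_train():
    """Three-record training set used throughout the naive-predictor docs."""
    df = pd.DataFrame(
        {
            "cell_line_id": ["c1", "c1", "c2"],
            "drug_id": ["dX", "dY", "dX"],
            "tissue": ["lung", "lung", "skin"],
            "LN_IC50": [1.0, 3.0, 2.0],
        }
    )
    return ResponseDataset(df, measure="LN_IC50", name="tiny")


def random_response_dataset(rng: np.random.Generator, n_cells=None, n_drugs=None,
                            n_tissues=3, n_records=None) -> ResponseDataset:
    """Small random dataset with tissues, possibly with replicate pairs."""
    n_cells = n_cells or int(rng.integers(6, 16))
    n_drugs = n_drugs or int(rng.integers(5, 12))
    cells = [f"c{i}" for i in range(n_cells)]
    drugs = [f"d{j}" for j in range(n_drugs)]
    tissues = [f"t{t}" for t in range(n_tissues)]
    n_records = n_records or int(rng.integers(n_cells * 2, n_cells * n_drugs))
    ci = rng.integers(0, n_cells, n_records)
    dj = rng.integers(0, n_drugs, n_records)
    df = pd.DataFrame(
        {
            "cell_line_id": [cells[i] for i in ci],
            "drug_id": [drugs[j] for j in dj],
            "tissue": [tissues[i % n_tissues] for i in ci],
            "LN_IC50": rng.normal(0, 1, n_records),
        }
    )
    return ResponseDataset(df, measure="LN_IC50", name="random")
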
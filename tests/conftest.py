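import numpy as np
import pandas as pd
import pytest

import statepath as sp
from statepath.io import ExpressionMatrix
from statepath.ordering import PathOrdering


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 cells, linear scale, hand-set values."""
    data = pd.DataFrame(
        [[0.0, 1.0, 7.0, 3.0], [2.0, 0.0, 0.0, 5.0], [1.0, 1.0, 1.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return ExpressionMatrix(data, scale="linear")


@pytest.fixture
def tiny_annotation() -> pd.Series:
    return pd.Series(
        {"c1": "early", "c2": "early", "c3": "late", "c4": "late"}, name="group"
    )


@pytest.fixture(scope="session")
def y_dataset() -> sp.SyntheticDataset:
    """One fixed draw of the canonical Y-shaped branching dataset."""
    return sp.simulate_branching(sp.y_topology(), n_genes=100, noise_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def y_trajectory(y_dataset):
    """Full landmark/network inference on the fixed Y dataset."""
    m = sp.log_transform(y_dataset.expression)
    ls, nn, stn = sp.infer_trajectory(m, y_dataset.annotation)
    return m, ls, nn, stn


def make_ordering(n: int, total_length: float = 1.0) -> PathOrdering:
    """A straight-line ordering of n synthetic cells for statistics tests."""
    cells = [f"c{i:04d}" for i in range(n)]
    tab = pd.DataFrame(
        {
            "path_name": "a-b",
            "segment_index": 0,
            "t": np.linspace(0.0, 1.0, n),
            "pseudotime": np.linspace(0.0, total_length, n),
            "residual": 0.0,
            "rank": np.arange(n),
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return PathOrdering(path=["a", "b"], table=tab, segment_lengths=[total_length])


def matrix_from_array(Y: np.ndarray, cells: list[str], scale: str = "log2") -> ExpressionMatrix:
    genes = [f"g{i:05d}" for i in range(Y.shape[0])]
    return ExpressionMatrix(pd.DataFrame(Y, index=genes, columns=cells), scale=scale)
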
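import numpy as np
import pandas as pd
import pytest

from gwclhs import GridSpec, make_stack, stack_to_table
from gwclhs.grids import PixelTable


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=4, n_cols=4, cell_size=100.0, x_origin=0.0, y_origin=400.0)


@pytest.fixture
def grid40():
    return GridSpec(n_rows=40, n_cols=40, cell_size=100.0, x_origin=0.0, y_origin=4000.0)


@pytest.fixture
def homogeneous_table(grid40):
    return stack_to_table(make_stack(grid40, n_continuous=5, seed=3))


def toy_table(X: np.ndarray, kinds: dict | None = None, cell_size: float = 100.0) -> PixelTable:
    """Wrap a plain value matrix as a pixel table on a 1-row strip grid."""
    n, p = X.shape
    grid = GridSpec(n_rows=1, n_cols=n, cell_size=cell_size, x_origin=0.0, y_origin=cell_size)
    names = [chr(ord("a") + j) for j in range(p)]
    data = {"cell_id": np.arange(n), "x": (np.arange(n) + 0.5) * cell_size,
            "y": np.full(n, cell_size / 2)}
    for j, name in enumerate(names):
        data[name] = X[:, j]
    if kinds is None:
        kinds = {name: "continuous" for name in names}
    return PixelTable(data=pd.DataFrame(data), kinds=kinds, grid=grid)
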
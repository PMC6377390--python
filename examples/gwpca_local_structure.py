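"""Recover spatially varying covariate structure with weighted PCA.

Builds a stack whose dominant correlation structure differs between the
west and east halves of the map, fits a locally weighted PCA, and checks
the local leading loadings and the winning-variable map against the known
regime structure.
"""

import numpy as np

from gwclhs import (
    GridSpec, gwpca_fit, make_two_regime_stack, stack_to_table, winning_variable,
)
from gwclhs.gwpca import KernelSpec

grid = GridSpec(n_rows=40, n_cols=40, cell_size=100.0, x_origin=0.0, y_origin=4000.0)
stack, truth = make_two_regime_stack(grid, p=4, seed=1)
table = stack_to_table(stack)

bandwidth = 800.0  # one fifth of the 4 km domain
result = gwpca_fit(table, KernelSpec(bandwidth=bandwidth))

x, _ = grid.cell_centers(result.cell_ids)
split_x = truth.split_col * grid.cell_size
lead = result.loadings[:, :, 0]
for name, direction, sel in (
    ("west", truth.west_direction, x < split_x - 2 * bandwidth),
    ("east", truth.east_direction, x > split_x + 2 * bandwidth),
):
    cos = np.abs(lead[sel] @ direction)
    print(f"{name}: |cos| to true leading direction > 0.9 on "
          f"{100 * np.mean(cos > 0.9):.1f}% of {sel.sum()} interior cells")

win = winning_variable(result).values
print(f"west half dominated by var0 on {100 * np.mean(win[:, :16] == 0):.1f}% of cells; "
      f"east half by var1 on {100 * np.mean(win[:, 24:] == 1):.1f}%")
print("A fraction near 100% means the local analysis separates the two regimes"
      " that a single global PCA would blend.")
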
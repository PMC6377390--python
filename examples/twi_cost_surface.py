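"""From DEM to wetness index to sampling-cost surface.

Uses an analytic south-sloping plane so every number has a closed form:
row r accumulates r upslope cells, hence TWI = ln(((r+1)*cell)/tanb).
"""

import numpy as np

from gwclhs import GridSpec, make_dem_plane, twi, twi_to_cost

grid = GridSpec(n_rows=10, n_cols=10, cell_size=100.0, x_origin=0.0, y_origin=1000.0)
dem = make_dem_plane(grid, gx=0.0, gy=0.1)  # drops 0.1 m per m southward

twi_layer = twi(dem, grid.cell_size)
cost = twi_to_cost(twi_layer, grid)

print("row  TWI (computed)  TWI (closed form)  cost")
for r in range(10):
    expected = np.log(((r + 1) * grid.cell_size) / 0.1)
    print(f"{r:3d}  {twi_layer.values[r, 0]:13.4f}  {expected:17.4f}  {cost.values[r, 0]:.3f}")
print("\nThe driest cells (top row, crest-like: least upslope area) carry cost 1,")
print("the wettest (bottom row, depression-like) cost 0 — annealing with this")
print("surface avoids placing samples on crests.")
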
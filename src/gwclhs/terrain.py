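"""Terrain derivatives: slope, D8 flow accumulation, TWI, and the cost surface.

The topographic wetness index TWI = ln(a / tan beta) combines the specific
catchment area ``a`` (here ``(upslope cell count + 1) * cell_size``, i.e.
unit contour width) with the local slope gradient ``tan beta``.  Low TWI
marks crests and ridges, high TWI depressions.  The cost surface inverts
and min-max rescales TWI so that crest cells — areas of minor influence on
soil moisture — carry the highest sampling penalty.

Flow routing is single-direction D8: each cell drains to the 8-neighbor
with the steepest distance-weighted drop; pits and flats drain nowhere and
are flagged rather than filled (depression filling is considered DEM
preprocessing, outside this module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .grids import CATEGORICAL, CONTINUOUS, GridSpec, Layer

# fixed tie-break order: N, NE, E, SE, S, SW, W, NW
_D8_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])


@dataclass
class CostSurface:
    """Per-cell nonnegative sampling penalty aligned to the covariate grid."""

    grid: GridSpec
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("cost values do not match the grid shape")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise ValueError("cost must be nonnegative")

    def at_cells(self, cell_ids: np.ndarray) -> np.ndarray:
        return self.values.ravel()[np.asarray(cell_ids, dtype=int)]


class FlowResult(NamedTuple):
    counts: Layer          # upslope cell count (self excluded)
    receiver: np.ndarray   # flat index of the downslope neighbor, -1 if none
    unresolved: np.ndarray  # bool grid: pits/flats with no lower neighbor


def slope_gradient(dem: Layer, cell_size: float) -> Layer:
    """Slope gradient magnitude tan(beta) by central differences.

    One-sided differences at the borders; exact on planar surfaces.
    """
    z = dem.values
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("DEM must be at least 2x2")
    dz_drow, dz_dcol = np.gradient(z, cell_size)
    tanb = np.hypot(dz_drow, dz_dcol)
    return Layer(name="slope", kind=CONTINUOUS, values=tanb)


def d8_flow_accumulation(dem: Layer) -> FlowResult:
    """Upslope contributing cell count under D8 single-direction routing.

    Each cell drains to the neighbor maximizing (z - z_nb) / distance over
    the 8 neighbors, requiring a strictly positive drop; ties take the
    first neighbor in N, NE, E, SE, S, SW, W, NW order.  Counts exclude the
    cell itself.  Cells with no lower neighbor are flagged unresolved and
    pass nothing on.
    """
    z = dem.values
    if np.any(dem.missing):
        raise ValueError("DEM has missing cells; fill or crop first")
    nr, nc = z.shape
    receiver = np.full(nr * nc, -1, dtype=int)
    best_drop = np.zeros((nr, nc))
    for k, (dr, dc) in enumerate(_D8_OFFSETS):
        drop = np.full((nr, nc), -np.inf)
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        drop[r0:r1, c0:c1] = (
            z[r0:r1, c0:c1] - z[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ) / _D8_DIST[k]
        better = drop > best_drop  # strict ">" keeps the first direction on ties
        best_drop = np.where(better, drop, best_drop)
        rr, cc = np.nonzero(better)
        receiver[rr * nc + cc] = (rr + dr) * nc + (cc + dc)
    unresolved = (receiver < 0).reshape(nr, nc)
    if unresolved.all():
        warnings.warn("DEM is flat: no cell has a lower neighbor; all counts are 0")
    # accumulate from high to low; a receiver is always strictly lower
    acc = np.zeros(nr * nc, dtype=np.int64)
    order = np.argsort(-z.ravel(), kind="stable")
    for idx in order:
        rcv = receiver[idx]
        if rcv >= 0:
            acc[rcv] += acc[idx] + 1
    counts = Layer(name="flow_accumulation", kind=CONTINUOUS, values=acc.reshape(nr, nc).astype(float))
    return FlowResult(counts=counts, receiver=receiver, unresolved=unresolved)


def twi(dem: Layer, cell_size: float, slope_floor: float = 1e-4) -> Layer:
    """Topographic wetness index ln(a / tan beta).

    a = (upslope count + 1) * cell_size (specific catchment area per unit
    contour width); tan beta is floored at ``slope_floor`` so flats yield a
    large finite value rather than infinity.
    """
    flow = d8_flow_accumulation(dem)
    tanb = slope_gradient(dem, cell_size).values
    tanb = np.maximum(tanb, slope_floor)
    a = (flow.counts.values + 1.0) * cell_size
    return Layer(name="twi", kind=CONTINUOUS, values=np.log(a / tanb))


def twi_to_cost(twi_layer: Layer, grid: GridSpec) -> CostSurface:
    """Invert and min-max rescale TWI into a [0, 1] cost surface.

    cost = (max TWI - TWI) / (max TWI - min TWI): crest cells (low TWI)
    cost 1, depression cells (high TWI) cost 0, so annealing is steered
    away from ridges.
    """
    v = twi_layer.values
    if not np.all(np.isfinite(v[~twi_layer.missing])):
        raise ValueError("TWI must be finite")
    lo, hi = np.nanmin(np.where(twi_layer.missing, np.nan, v)), np.nanmax(
        np.where(twi_layer.missing, np.nan, v)
    )
    if hi == lo:
        warnings.warn("constant TWI: cost surface is all zeros")
        cost = np.zeros_like(v)
    else:
        cost = (hi - v) / (hi - lo)
    cost = np.where(twi_layer.missing, np.nan, cost)
    return CostSurface(grid=grid, values=cost, provenance="inverted min-max TWI")
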
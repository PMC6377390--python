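"""Gridded covariate containers and plain-text raster I/O.

Grid convention
---------------
Rasters are row-major with the origin at the **top-left corner** of the
grid.  Row ``r``, column ``c`` has its cell *center* at::

    x = x_origin + (c + 0.5) * cell_size
    y = y_origin - (r + 0.5) * cell_size

so row indices increase southward and ``cell_id = r * n_cols + c``.  All
distances downstream (kernel weights, design spacing) are computed between
cell centers in map units.

Files are ESRI ASCII grids (``ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value`` header followed by whitespace-separated values); the
``NODATA_value`` sentinel marks missing cells.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class GridAlignmentError(ValueError):
    """Layers do not share a common grid."""


class EmptyDomainError(ValueError):
    """No valid cell remains after masking."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid."""

    n_rows: int
    n_cols: int
    cell_size: float
    x_origin: float
    y_origin: float
    crs_id: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self, cell_ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of cell centers for ``cell_ids`` (default: all)."""
        if cell_ids is None:
            cell_ids = np.arange(self.n_cells)
        cell_ids = np.asarray(cell_ids)
        r, c = np.divmod(cell_ids, self.n_cols)
        x = self.x_origin + (c + 0.5) * self.cell_size
        y = self.y_origin - (r + 0.5) * self.cell_size
        return x, y

    def matches(self, other: "GridSpec", tol_frac: float = 1e-6) -> bool:
        tol = tol_frac * self.cell_size
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
        )


@dataclass
class Layer:
    """One gridded covariate: a 2-D value array plus a per-cell missing flag.

    ``kind`` is ``"continuous"`` or ``"categorical"``; categorical values are
    non-negative integer codes stored as floats for a uniform array dtype.
    """

    name: str
    kind: str
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D (rows, cols)")
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"layer {self.name!r}: unknown kind {self.kind!r}")
        nan_mask = ~np.isfinite(self.values)
        if self.missing is None:
            self.missing = nan_mask
        else:
            self.missing = np.asarray(self.missing, dtype=bool) | nan_mask
        if self.missing.shape != self.values.shape:
            raise ValueError(f"layer {self.name!r}: missing mask shape mismatch")
        if self.kind == CATEGORICAL:
            valid = self.values[~self.missing]
            if valid.size and (np.any(valid < 0) or np.any(valid != np.round(valid))):
                raise ValueError(
                    f"layer {self.name!r}: categorical codes must be non-negative integers"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CovariateStack:
    """Co-registered layers sharing one grid and a joint validity mask.

    A cell is valid iff it is non-missing in *every* layer.
    """

    grid: GridSpec
    layers: list[Layer]
    joint_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for lyr in self.layers:
            if lyr.shape != shape:
                raise GridAlignmentError(
                    f"layer {lyr.name!r} has shape {lyr.shape}, grid expects {shape}"
                )
        if not any(l.kind == CONTINUOUS for l in self.layers):
            raise ValueError("stack needs at least one continuous layer")
        mask = np.ones(shape, dtype=bool)
        for lyr in self.layers:
            mask &= ~lyr.missing
        self.joint_mask = mask
        if not mask.any():
            raise EmptyDomainError("no cell is valid in every layer")

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def kinds(self) -> dict[str, str]:
        return {l.name: l.kind for l in self.layers}

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


@dataclass
class PixelTable:
    """Flat table of valid cells: one row per valid cell, ordered by cell_id.

    ``data`` columns: ``cell_id``, ``x``, ``y``, then one column per layer.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    grid: GridSpec

    @property
    def layer_names(self) -> list[str]:
        return list(self.kinds)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n, k in self.kinds.items() if k == CONTINUOUS]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n, k in self.kinds.items() if k == CATEGORICAL]

    @property
    def n(self) -> int:
        return len(self.data)

    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            names = self.continuous_names
        return self.data[list(names)].to_numpy(float)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; missing cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = body.reshape(n_rows, n_cols)
    if "nodata_value" in header:
        values = np.where(values == header["nodata_value"], np.nan, values)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
    )
    return values, grid


def write_ascii_grid(
    path: str | Path, values: np.ndarray, grid: GridSpec, nodata: float = -9999.0
) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise GridAlignmentError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_stack(sources: Iterable[tuple[str | Path, str]], crs_id: str = "") -> CovariateStack:
    """Assemble a stack from ``(path, kind)`` pairs of ASCII grids.

    Layer names are taken from file stems.  All grids must agree in shape,
    cell size and origin within ``1e-6 * cell_size``.
    """
    layers: list[Layer] = []
    grid: GridSpec | None = None
    for path, kind in sources:
        values, g = read_ascii_grid(path)
        if grid is None:
            grid = replace(g, crs_id=crs_id)
        elif not grid.matches(g):
            raise GridAlignmentError(f"layer {Path(path).stem!r} is not aligned with the stack grid")
        layers.append(Layer(name=Path(path).stem, kind=kind, values=values))
    if grid is None:
        raise ValueError("no sources given")
    return CovariateStack(grid=grid, layers=layers)


# ---------------------------------------------------------------------------
# Flattening and design export


def stack_to_table(stack: CovariateStack) -> PixelTable:
    """Flatten a stack to one row per valid cell, ordered by cell_id."""
    mask = stack.joint_mask.ravel()
    cell_ids = np.flatnonzero(mask)
    if cell_ids.size == 0:
        warnings.warn("all cells are masked; pixel table is empty")
    x, y = stack.grid.cell_centers(cell_ids)
    cols: dict[str, np.ndarray] = {"cell_id": cell_ids, "x": x, "y": y}
    for lyr in stack.layers:
        cols[lyr.name] = lyr.values.ravel()[cell_ids]
    return PixelTable(data=pd.DataFrame(cols), kinds=stack.kinds, grid=stack.grid)


def table_to_layer(table: PixelTable, name: str) -> Layer:
    """Re-grid one pixel-table column to a full Layer (inverse of flattening)."""
    values = np.full(table.grid.n_cells, np.nan)
    values[table.data["cell_id"].to_numpy(int)] = table.data[name].to_numpy(float)
    return Layer(
        name=name,
        kind=table.kinds.get(name, CONTINUOUS),
        values=values.reshape(table.grid.n_rows, table.grid.n_cols),
    )


def resample_nearest(layer: Layer, factor: int) -> Layer:
    """Coarsen a layer by integer ``factor`` using nearest-neighbor picks.

    Both continuous and categorical layers are resampled by selecting the
    original cell nearest each coarse-cell center; codes are never blended.
    Trailing rows/columns that do not fill a block are truncated.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    n_rows, n_cols = layer.shape
    out_r, out_c = n_rows // factor, n_cols // factor
    if out_r < 1 or out_c < 1:
        raise ValueError("factor larger than the grid")
    rr = np.arange(out_r) * factor + factor // 2
    cc = np.arange(out_c) * factor + factor // 2
    return Layer(
        name=layer.name,
        kind=layer.kind,
        values=layer.values[np.ix_(rr, cc)],
        missing=layer.missing[np.ix_(rr, cc)],
    )


def coarsen_grid(grid: GridSpec, factor: int) -> GridSpec:
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    return replace(
        grid,
        n_rows=grid.n_rows // factor,
        n_cols=grid.n_cols // factor,
        cell_size=grid.cell_size * factor,
    )


def write_design(design, stack: CovariateStack, out_dir: str | Path, basename: str = "design") -> dict[str, Path]:
    """Write a sample design as CSV (rank, cell_id, x, y, covariates, cost) + GeoJSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_ids = np.asarray(design.cell_ids, dtype=int)
    mask = stack.joint_mask.ravel()
    bad = cell_ids[(cell_ids < 0) | (cell_ids >= mask.size)]
    if bad.size or not mask[cell_ids].all():
        raise ValueError("design references cell_ids outside the stack's valid domain")
    x, y = stack.grid.cell_centers(cell_ids)
    rows: dict[str, np.ndarray] = {
        "rank": np.arange(1, cell_ids.size + 1),
        "cell_id": cell_ids,
        "x": x,
        "y": y,
    }
    for lyr in stack.layers:
        rows[lyr.name] = lyr.values.ravel()[cell_ids]
    rows["cost"] = np.asarray(design.cell_costs, dtype=float)
    df = pd.DataFrame(rows)
    csv_path = out_dir / f"{basename}.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(xi), float(yi)]},
            "properties": {"rank": int(k + 1), "cell_id": int(cid), "cost": float(ci)},
        }
        for k, (xi, yi, cid, ci) in enumerate(zip(x, y, cell_ids, rows["cost"]))
    ]
    geojson = {"type": "FeatureCollection", "crs_id": stack.grid.crs_id, "features": features}
    gj_path = out_dir / f"{basename}.geojson"
    gj_path.write_text(json.dumps(geojson, indent=1))
    return {"csv": csv_path, "geojson": gj_path}
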
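"""End-to-end sampling-design pipeline.

read stack -> (optional bandwidth CV) -> GWPCA -> Kaiser component
selection -> local score layers -> (optional DEM -> TWI -> cost) ->
cost-constrained cLHS annealing -> design files.  Every stage logs its
parameters and writes its intermediates; a MANIFEST records the config,
its hash and the outcome so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clhs, gwpca, terrain
from .grids import (
    CovariateStack,
    read_ascii_grid,
    read_stack,
    stack_to_table,
    table_to_layer,
    write_ascii_grid,
    write_design,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one design run (all paths are ASCII grids)."""

    rasters: list[tuple[str, str]]            # (path, continuous|categorical)
    out_dir: str
    dem_path: str | None = None               # enables the TWI cost stage
    bandwidth: float | None = None            # fixed bandwidth in map units
    bandwidth_candidates: list[float] = field(default_factory=list)
    subsample_frac: float = 0.10
    n_samples: int = 38
    iterations: int = 50_000
    cost_weight: float = 1.0
    use_cost: bool = True
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        for path, kind in self.rasters:
            if not Path(path).exists():
                raise FileNotFoundError(f"raster not found: {path}")
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"unknown layer kind {kind!r} for {path}")
        if self.dem_path is not None and not Path(self.dem_path).exists():
            raise FileNotFoundError(f"DEM not found: {self.dem_path}")
        if self.bandwidth is None and not self.bandwidth_candidates:
            raise ValueError("give a bandwidth or bandwidth candidates")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_design(config: RunConfig, stack: CovariateStack | None = None) -> dict:
    """Execute the full pipeline; returns the MANIFEST dictionary.

    ``stack`` may be passed directly (e.g. a synthetic stack) to skip the
    read stage.  On a stage failure the partial outputs are retained and
    the MANIFEST names the failed stage before the error is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.hash(),
                      "seed": config.seed, "stages": [], "status": "running"}

    def finish(stage: str, err: Exception) -> StageError:
        manifest["status"] = f"failed at {stage}"
        manifest["error"] = str(err)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, default=str))
        return StageError(stage, err)

    try:
        config.validate()
    except Exception as e:  # noqa: BLE001
        raise finish("validate", e) from e

    try:
        if stack is None:
            stack = read_stack(config.rasters)
        table = stack_to_table(stack)
        manifest["stages"].append({"stage": "read", "n_valid_cells": int(table.n)})
        logger.info("read stack: %d layers, %d valid cells", len(stack.layers), table.n)
    except Exception as e:  # noqa: BLE001
        raise finish("read", e) from e

    try:
        p = len(table.continuous_names)
        if config.bandwidth is not None:
            bandwidth = float(config.bandwidth)
        else:
            cv = gwpca.bandwidth_cv(
                table, k=min(2, p - 1) if p > 1 else 1,
                candidates=config.bandwidth_candidates,
                subsample_frac=config.subsample_frac, seed=config.seed,
            )
            cv.as_frame().to_csv(out / "bandwidth_cv.csv", index=False)
            bandwidth = cv.selected
        kernel = gwpca.KernelSpec(family=gwpca.BISQUARE, mode=gwpca.FIXED, bandwidth=bandwidth)
        result = gwpca.gwpca_fit(table, kernel)
        k = gwpca.select_components(result)
        gwpca.eigen_summary(result).to_csv(out / "eigen_summary.csv", index=False)
        s_table = gwpca.scores_table(result, table, k)
        for name in s_table.layer_names:
            write_ascii_grid(out / f"score_{name}.asc", table_to_layer(s_table, name).values, stack.grid)
        manifest["stages"].append({"stage": "gwpca", "bandwidth": bandwidth, "k": k})
        logger.info("gwpca: bandwidth=%g, retained k=%d components", bandwidth, k)
    except Exception as e:  # noqa: BLE001
        raise finish("gwpca", e) from e

    cost = None
    try:
        if config.use_cost and config.dem_path is not None:
            dem_values, dem_grid = read_ascii_grid(config.dem_path)
            from .grids import Layer

            dem = Layer(name="dem", kind="continuous", values=dem_values)
            twi_layer = terrain.twi(dem, dem_grid.cell_size)
            write_ascii_grid(out / "twi.asc", twi_layer.values, dem_grid)
            cost = terrain.twi_to_cost(twi_layer, dem_grid)
            write_ascii_grid(out / "cost.asc", cost.values, dem_grid)
            manifest["stages"].append({"stage": "cost", "provenance": cost.provenance})
    except Exception as e:  # noqa: BLE001
        raise finish("cost", e) from e

    try:
        cfg = clhs.AnnealConfig(
            n_samples=config.n_samples, iterations=config.iterations,
            weights=config.weights, cost_weight=config.cost_weight, seed=config.seed,
        )
        design = clhs.anneal(s_table, cfg, cost=cost)
        paths = write_design(design, stack, out)
        step = max(1, config.iterations // 1000)
        pd.DataFrame(
            {
                "iteration": np.arange(0, config.iterations, step),
                "best_objective": design.best_objective_trace[::step],
                "cost": design.cost_trace[::step],
            }
        ).to_csv(out / "trajectory.csv", index=False)
        manifest["stages"].append(
            {"stage": "clhs", "objective": design.objective, "total_cost": design.total_cost,
             "outputs": {k: str(v) for k, v in paths.items()}}
        )
        logger.info("clhs: objective=%.4f cost=%.4f", design.objective, design.total_cost)
    except Exception as e:  # noqa: BLE001
        raise finish("clhs", e) from e

    manifest["status"] = "ok"
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
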
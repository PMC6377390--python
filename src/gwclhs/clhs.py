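"""Conditioned Latin hypercube sampling by simulated annealing.

Given a population of cells with continuous (and optionally categorical)
covariates, select n cells whose covariate values form a Latin hypercube:
one sample per marginal quantile stratum of each continuous variable,
class frequencies matching the population for categorical variables, and
a sample correlation matrix close to the population's.  The objective is

    O = w1*O1 + w2*O2 + w3*O3
    O1 = sum_vars sum_strata |eta - 1|          (stratum occupancy)
    O2 = sum_vars sum_classes |eta_c/n - kappa_c|  (class proportions)
    O3 = sum_ij |c_ij - chat_ij|                (correlation match)

minimized by Metropolis annealing with geometric cooling T_j = T0 * f^j
and a single random swap per iteration.  A cost surface enters the
acceptance probability multiplicatively as exp(-cost_weight * max(Dcost,
0) / T): moves that raise the summed per-sample cost are throttled, which
suppresses sampling in high-cost (low-relevance) areas while leaving the
objective itself untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import PixelTable
from .terrain import CostSurface


class CollapsedStrataError(ValueError):
    """A variable is constant; quantile strata collapse."""


@dataclass(frozen=True)
class StrataSpec:
    """Population strata: quantile edges per continuous variable and class
    proportions per categorical variable."""

    edges: dict[str, np.ndarray]
    class_props: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, e in self.edges.items():
            if np.any(np.diff(e) < 0):
                raise ValueError(f"{name}: stratum edges must be non-decreasing")
        for name, kappa in self.class_props.items():
            if abs(float(np.sum(kappa)) - 1.0) > 1e-9:
                raise ValueError(f"{name}: class proportions must sum to 1")


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule and objective weights.

    n_samples    : design size (38 mirrors the original access-tube budget)
    iterations   : swap proposals; full optimization plateaus by ~5e4
    t0 / cooling : geometric schedule T_j = t0 * cooling**j
    weights      : (w1, w2, w3) on stratum, class and correlation terms
    cost_weight  : multiplier on the cost penalty in the acceptance rule;
                   0 recovers the unconstrained sampler exactly
    """

    n_samples: int = 38
    iterations: int = 50_000
    t0: float = 1.0
    cooling: float = 0.999
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cost_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0, 1)")
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            raise ValueError("objective weights must be nonnegative and not all zero")
        if self.cost_weight < 0:
            raise ValueError("cost_weight must be nonnegative")


@dataclass
class SampleDesign:
    """Result of one annealing run."""

    cell_ids: np.ndarray
    objective: float
    components: tuple[float, float, float]
    total_cost: float
    cell_costs: np.ndarray
    best_objective_trace: np.ndarray
    cost_trace: np.ndarray
    config: AnnealConfig


# ---------------------------------------------------------------------------
# strata and objective components


def quantile_strata(values: np.ndarray, n: int, name: str = "variable") -> np.ndarray:
    """n+1 stratum edges at empirical quantiles i/n (linear interpolation)."""
    if n < 1:
        raise ValueError("need at least one stratum")
    values = np.asarray(values, dtype=float)
    if np.nanmax(values) == np.nanmin(values):
        raise CollapsedStrataError(f"{name}: variable is constant, strata collapse")
    return np.quantile(values, np.linspace(0.0, 1.0, n + 1))


def stratum_counts(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Occupancy of each stratum; interior edges are low-inclusive, the last
    stratum includes its upper edge."""
    idx = np.searchsorted(edges[1:-1], values, side="right")
    return np.bincount(idx, minlength=edges.size - 1)


def build_strata(table: PixelTable, n_samples: int) -> StrataSpec:
    """Population strata for every covariate of a pixel table."""
    edges = {
        name: quantile_strata(table.data[name].to_numpy(float), n_samples, name)
        for name in table.continuous_names
    }
    props = {}
    for name in table.categorical_names:
        codes = table.data[name].to_numpy(int)
        counts = np.bincount(codes)
        props[name] = counts / counts.sum()
    return StrataSpec(edges=edges, class_props=props)


def objective_continuous(X_sel: np.ndarray, edges: Sequence[np.ndarray]) -> float:
    """O1: sum over variables and strata of |occupancy - 1|."""
    total = 0
    for j, e in enumerate(edges):
        eta = stratum_counts(X_sel[:, j], e)
        total += np.abs(eta - 1).sum()
    return float(total)


def objective_categorical(codes_sel: np.ndarray, class_props: Sequence[np.ndarray]) -> float:
    """O2: sum over variables and classes of |sample share - population share|."""
    n = codes_sel.shape[0]
    total = 0.0
    for j, kappa in enumerate(class_props):
        eta = np.bincount(codes_sel[:, j].astype(int), minlength=kappa.size)
        total += float(np.abs(eta / n - kappa).sum())
    return total


def objective_correlation(X_sel: np.ndarray, population_corr: np.ndarray) -> float:
    """O3: elementwise absolute difference between the design's and the
    population's correlation matrices (full matrix; diagonal contributes 0).

    A selected variable with zero variance leaves its correlations
    undefined; those entries are treated as 0 with a warning.
    """
    sd = X_sel.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chat = np.corrcoef(X_sel.T)
    if np.any(sd == 0):
        warnings.warn("constant variable in the design; its correlations set to 0")
        chat = np.where(np.isfinite(chat), chat, 0.0)
        np.fill_diagonal(chat, 1.0)
    return float(np.abs(population_corr - chat).sum())


def total_objective(
    o1: float, o2: float, o3: float, weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> float:
    return weights[0] * o1 + weights[1] * o2 + weights[2] * o3


# ---------------------------------------------------------------------------
# annealing moves


def perturb(design: np.ndarray, population_size: int, rng: np.random.Generator) -> np.ndarray:
    """Swap one uniformly chosen selected index for one unselected index."""
    n = design.size
    if population_size <= n:
        warnings.warn("population no larger than the design; nothing to swap")
        return design.copy()
    out = design.copy()
    pos = int(rng.integers(n))
    selected = set(design.tolist())
    while True:
        cand = int(rng.integers(population_size))
        if cand not in selected:
            break
    out[pos] = cand
    return out


def accept(
    delta_obj: float,
    delta_cost: float,
    temperature: float,
    cost_weight: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis rule with a multiplicative cost factor.

    Improving moves (delta_obj <= 0 and delta_cost <= 0) always pass;
    otherwise accept with probability
    exp(-max(delta_obj,0)/T) * exp(-cost_weight*max(delta_cost,0)/T),
    the second factor being the cost-acceptance term exp(-Dcost/T).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    penalty = cost_weight * max(delta_cost, 0.0)
    if delta_obj <= 0 and penalty == 0:
        return True
    p = np.exp(-max(delta_obj, 0.0) / temperature) * np.exp(-penalty / temperature)
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# the sampler


class _Population:
    """Numeric views of a pixel table for fast objective evaluation."""

    def __init__(self, table: PixelTable, n_samples: int, strata: StrataSpec | None = None):
        self.table = table
        self.cont_names = table.continuous_names
        self.cat_names = table.categorical_names
        self.X = table.matrix(self.cont_names)
        self.C = (
            table.data[self.cat_names].to_numpy(int)
            if self.cat_names
            else np.empty((table.n, 0), dtype=int)
        )
        if strata is None:
            strata = build_strata(table, n_samples)
        self.strata = strata
        self.edges = [strata.edges[n] for n in self.cont_names]
        self.props = [strata.class_props[n] for n in self.cat_names]
        if len(self.cont_names) >= 2:
            self.pop_corr = np.corrcoef(self.X.T)
        else:
            self.pop_corr = None

    def objective(self, idx: np.ndarray, weights) -> tuple[float, tuple[float, float, float]]:
        Xs = self.X[idx]
        o1 = objective_continuous(Xs, self.edges)
        o2 = objective_categorical(self.C[idx], self.props) if self.props else 0.0
        o3 = (
            objective_correlation(Xs, self.pop_corr)
            if self.pop_corr is not None and idx.size >= 3
            else 0.0
        )
        return total_objective(o1, o2, o3, weights), (o1, o2, o3)


def anneal(
    table: PixelTable,
    config: AnnealConfig,
    cost: CostSurface | None = None,
    strata: StrataSpec | None = None,
) -> SampleDesign:
    """Run the annealer and return the best-objective design visited.

    The best design is tracked by objective alone (costs steer acceptance,
    not the ranking), so a late uphill excursion cannot lose the optimum.
    Fully reproducible from ``config.seed``.
    """
    pop = _Population(table, config.n_samples, strata)
    N = table.n
    n = config.n_samples
    if N < n:
        raise ValueError(f"population of {N} cells cannot host {n} samples")
    cost_values = (
        cost.at_cells(table.data["cell_id"].to_numpy(int))
        if cost is not None
        else np.zeros(N)
    )
    if cost is not None and not np.all(np.isfinite(cost_values)):
        raise ValueError("cost surface is not finite on the population cells")
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(N, size=n, replace=False)
    obj, comps = pop.objective(idx, config.weights)
    cur_cost = float(cost_values[idx].sum())
    best_idx, best_obj, best_comps = idx.copy(), obj, comps
    best_trace = np.empty(config.iterations)
    cost_trace = np.empty(config.iterations)
    if N == n:
        best_trace[:] = obj
        cost_trace[:] = cur_cost
    else:
        temperature = config.t0
        for j in range(config.iterations):
            temperature *= config.cooling
            prop = perturb(idx, N, rng)
            prop_obj, prop_comps = pop.objective(prop, config.weights)
            prop_cost = float(cost_values[prop].sum())
            if accept(
                prop_obj - obj,
                prop_cost - cur_cost,
                temperature,
                config.cost_weight if cost is not None else 0.0,
                rng,
            ):
                idx, obj, comps, cur_cost = prop, prop_obj, prop_comps, prop_cost
                if obj < best_obj:
                    best_idx, best_obj, best_comps = idx.copy(), obj, comps
            best_trace[j] = best_obj
            cost_trace[j] = cur_cost
    best_cell_costs = cost_values[best_idx]
    return SampleDesign(
        cell_ids=table.data["cell_id"].to_numpy(int)[best_idx],
        objective=best_obj,
        components=best_comps,
        total_cost=float(best_cell_costs.sum()),
        cell_costs=best_cell_costs,
        best_objective_trace=best_trace,
        cost_trace=cost_trace,
        config=config,
    )
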
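"""Geographically weighted principal component analysis.

At every grid cell ``i`` a separate PCA is fitted with observation weights
that decay with geographic distance from ``i``:

    w_ij = (1 - (d_ij / b)^2)^2   for d_ij < b, else 0      (bi-square)

    Sigma(x_i, y_i) = local weighted covariance of the covariates,
    L V L' = its eigenstructure (eigenvalues L, loadings V).

The covariates are standardized globally (mean 0, sd 1, n-1 denominator)
and the local matrix is re-normalized to correlation scale, so every
location's eigenvalues sum to p and the Kaiser "eigenvalue >= 1" retention
rule is meaningful.  The bandwidth b is either a fixed distance in map
units or an adaptive neighbor count (converted to the distance of the k-th
nearest other point per location).

Bandwidth selection is a leave-one-out reconstruction cross-validation on
a seeded random subsample of cells: each held-out cell's standardized
covariate vector is reconstructed from the first k local components fitted
without it, and the bandwidth minimizing the summed squared reconstruction
error wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .grids import CATEGORICAL, CONTINUOUS, GridSpec, Layer, PixelTable

logger = logging.getLogger(__name__)

BISQUARE = "bisquare"
UNIFORM = "uniform"
FIXED = "fixed"
ADAPTIVE = "adaptive"


class BandwidthTooSmallError(ValueError):
    """Some location has fewer than p+1 neighbors with nonzero weight."""


@dataclass(frozen=True)
class KernelSpec:
    """Spatial weighting kernel.

    family    : "bisquare" (compact support) or "uniform" (every weight 1,
                the global-PCA limit, mainly for validation).
    mode      : "fixed" -> bandwidth is a distance in map units;
                "adaptive" -> bandwidth is a neighbor count and the local
                distance to that many nearest other points is used as b.
    bandwidth : distance or neighbor count, per mode.
    """

    family: str = BISQUARE
    mode: str = FIXED
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in (BISQUARE, UNIFORM):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.mode not in (FIXED, ADAPTIVE):
            raise ValueError(f"unknown kernel mode {self.mode!r}")
        if self.family == BISQUARE and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class StandardizationParams:
    """Global per-variable mean and standard deviation (n-1 denominator)."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class GWPCAResult:
    """Per-location eigenstructure of the local weighted correlation matrix.

    eigenvalues : (N, p) descending per row
    loadings    : (N, p, p); column m of loadings[i] is the m-th local
                  eigenvector, sign-fixed so its largest-|.| element is
                  positive.
    """

    cell_ids: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    kernel: KernelSpec
    standardization: StandardizationParams
    grid: GridSpec
    matrix_kind: str = "correlation"

    @property
    def n_locations(self) -> int:
        return self.cell_ids.size

    @property
    def n_vars(self) -> int:
        return self.eigenvalues.shape[1]

    @property
    def var_names(self) -> tuple[str, ...]:
        return self.standardization.names


@dataclass
class BandwidthCVResult:
    candidates: np.ndarray
    scores: np.ndarray
    selected: float
    k: int
    subsample_frac: float
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bandwidth": self.candidates, "cv_score": self.scores})


# ---------------------------------------------------------------------------
# kernel and moment primitives


def bisquare_weight(d, b: float):
    """Bi-square kernel weight ``(1 - (d/b)^2)^2`` for d < b, else 0."""
    if b <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    u = d / b
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w if w.ndim else float(w)


def standardize(table: PixelTable, names: Sequence[str] | None = None) -> tuple[np.ndarray, StandardizationParams]:
    """Globally standardize the continuous covariates (mean 0, sd 1, ddof=1)."""
    if names is None:
        names = table.continuous_names
    X = table.matrix(names)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s <= 0:
            raise ValueError(f"layer {list(names)[j]!r} is constant; cannot standardize")
    Z = (X - mean) / sd
    return Z, StandardizationParams(names=tuple(names), mean=mean, sd=sd)


def local_weighted_cov(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted covariance of rows of X about the weighted mean.

    Sigma = X_c' diag(w / sum w) X_c with X_c centered on the weighted mean;
    symmetric and positive semidefinite.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape[0] != X.shape[0]:
        raise ValueError("weight vector length must match the number of rows")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("empty neighborhood: all weights are zero")
    wn = w / sw
    mu = wn @ X
    Xc = X - mu
    cov = (Xc * wn[:, None]).T @ Xc
    return 0.5 * (cov + cov.T)


def gw_std(x: np.ndarray, w: np.ndarray, mean: float | None = None, normalized: bool = False) -> float:
    """Geographically weighted standard deviation of one covariate.

    As printed, sigma_i = [sum_j (x_j - xbar)^2 w_ij]^0.5 with the *global*
    mean xbar; with ``normalized=True`` the weighted sum of squares is
    divided by sum(w) first, making uniform weights reduce to the
    population standard deviation.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise ValueError("empty neighborhood: all weights are zero")
    xbar = x.mean() if mean is None else mean
    ss = float(np.sum((x - xbar) ** 2 * w))
    if normalized:
        ss /= sw
    return float(np.sqrt(ss))


def local_eigen(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with descending eigenvalues and fixed signs.

    Sign convention: in each eigenvector the element of largest magnitude
    is made positive (ties broken by the lowest index), so loadings are
    comparable across neighboring locations.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    vals[(vals < 0) & (vals > -1e-10)] = 0.0
    for m in range(vecs.shape[1]):
        idx = int(np.argmax(np.abs(vecs[:, m])))
        if vecs[idx, m] < 0:
            vecs[:, m] = -vecs[:, m]
    return vals, vecs


# ---------------------------------------------------------------------------
# fitting


def _weight_matrix_row(kernel: KernelSpec, d: np.ndarray) -> np.ndarray:
    if kernel.family == UNIFORM:
        return np.ones_like(d)
    b = kernel.bandwidth
    if kernel.mode == ADAPTIVE:
        k = int(kernel.bandwidth)
        # distance to the k-th nearest *other* point defines the local bandwidth
        others = np.sort(d[d > 0])
        if others.size < k:
            return np.zeros_like(d)
        b = others[k - 1] * (1 + 1e-12)  # include the k-th neighbor itself
    return bisquare_weight(d, b)


def _cov_to_corr(cov: np.ndarray, where: str) -> np.ndarray:
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        raise BandwidthTooSmallError(
            f"degenerate neighborhood at {where}: a covariate has zero local variance"
        )
    denom = np.sqrt(np.outer(diag, diag))
    corr = cov / denom
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def gwpca_fit(
    table: PixelTable,
    kernel: KernelSpec,
    one_hot_categorical: bool = False,
) -> GWPCAResult:
    """Fit a weighted PCA at every valid cell.

    Categorical layers are excluded unless ``one_hot_categorical`` is set,
    in which case each class indicator enters as a 0/1 column (standardized
    like any other variable).  Raises :class:`BandwidthTooSmallError` when
    any location has fewer than p+1 nonzero-weight neighbors.
    """
    names = list(table.continuous_names)
    work = table
    if one_hot_categorical and table.categorical_names:
        data = table.data.copy()
        kinds = dict(table.kinds)
        for cname in table.categorical_names:
            codes = data[cname].astype(int)
            for code in np.unique(codes):
                col = f"{cname}={code}"
                data[col] = (codes == code).astype(float)
                kinds[col] = CONTINUOUS
                names.append(col)
            del kinds[cname]
            data = data.drop(columns=[cname])
        work = PixelTable(data=data, kinds=kinds, grid=table.grid)
    Z, params = standardize(work, names)
    coords = work.coords()
    N, p = Z.shape
    eigenvalues = np.empty((N, p))
    loadings = np.empty((N, p, p))
    for i in range(N):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        w = _weight_matrix_row(kernel, d)
        nz = int(np.count_nonzero(w))
        if nz < p + 1:
            raise BandwidthTooSmallError(
                f"cell_id {int(table.data['cell_id'].iloc[i])}: only {nz} nonzero weights, "
                f"need at least p+1 = {p + 1}; increase the bandwidth"
            )
        cov = local_weighted_cov(Z, w)
        corr = _cov_to_corr(cov, f"cell_id {int(table.data['cell_id'].iloc[i])}")
        vals, vecs = local_eigen(corr)
        eigenvalues[i] = vals
        loadings[i] = vecs
    return GWPCAResult(
        cell_ids=work.data["cell_id"].to_numpy(int),
        eigenvalues=eigenvalues,
        loadings=loadings,
        kernel=kernel,
        standardization=params,
        grid=work.grid,
    )


def select_components(result: GWPCAResult) -> int:
    """Kaiser retention: components whose location-averaged eigenvalue >= 1."""
    mean_vals = result.eigenvalues.mean(axis=0)
    k = int(np.sum(mean_vals >= 1.0))
    if k == 0:
        warnings.warn("no component has mean eigenvalue >= 1; keeping the first")
        k = 1
    return k


def local_scores(result: GWPCAResult, table: PixelTable, k: int) -> np.ndarray:
    """Per-cell scores on the first k local components: s_m(i) = v_m(i)' z_i."""
    if k > result.n_vars:
        raise ValueError("k exceeds the number of variables")
    names = list(result.standardization.names)
    Z = (table.data[names].to_numpy(float) - result.standardization.mean) / result.standardization.sd
    scores = np.einsum("ipm,ip->im", result.loadings[:, :, :k], Z)
    return scores


def scores_table(result: GWPCAResult, table: PixelTable, k: int) -> PixelTable:
    """Package local scores as a continuous PixelTable for downstream sampling."""
    S = local_scores(result, table, k)
    data = {"cell_id": result.cell_ids}
    x, y = result.grid.cell_centers(result.cell_ids)
    data["x"], data["y"] = x, y
    kinds: dict[str, str] = {}
    for m in range(k):
        name = f"PC{m + 1}"
        data[name] = S[:, m]
        kinds[name] = CONTINUOUS
    return PixelTable(data=pd.DataFrame(data), kinds=kinds, grid=result.grid)


def winning_variable(result: GWPCAResult) -> Layer:
    """Map of the variable dominating the local leading component.

    Per cell: the index (into the standardized variable list) of the
    largest-|loading| entry of the first local eigenvector; ties go to the
    lowest index.  This is the standard summary of locally dominant
    variability, replacing multivariate glyph plots.
    """
    lead = result.loadings[:, :, 0]
    winners = np.argmax(np.abs(lead), axis=1).astype(float)
    values = np.full(result.grid.n_cells, np.nan)
    values[result.cell_ids] = winners
    return Layer(
        name="winning_variable",
        kind=CATEGORICAL,
        values=values.reshape(result.grid.n_rows, result.grid.n_cols),
    )


# ---------------------------------------------------------------------------
# bandwidth cross-validation


def bandwidth_cv(
    table: PixelTable,
    k: int,
    candidates: Sequence[float],
    subsample_frac: float = 0.10,
    seed: int = 0,
    kernel_mode: str = FIXED,
) -> BandwidthCVResult:
    """Choose the bandwidth by leave-one-out reconstruction error.

    For each candidate b and each cell i of a seeded random subsample, the
    local PCA at i is fitted with w_ii = 0 and i's standardized covariate
    vector is reconstructed from the first k components; score(b) is the
    summed squared reconstruction error.  Candidates that starve any
    neighborhood below p+1 points score +inf (with a warning).  The
    minimizing candidate wins; ties go to the smallest bandwidth.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate bandwidths")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    Z, _ = standardize(table)
    N, p = Z.shape
    if not 0 < k < p + 1:
        raise ValueError("k must satisfy 1 <= k <= p")
    coords = table.coords()
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(round(subsample_frac * N)))
    subsample = np.sort(rng.choice(N, size=n_sub, replace=False))
    cand = np.sort(np.asarray(list(candidates), dtype=float))
    D = cdist(coords[subsample], coords)
    scores = np.empty(cand.size)
    for ci, b in enumerate(cand):
        kernel = KernelSpec(family=BISQUARE, mode=kernel_mode, bandwidth=b)
        total = 0.0
        for row, i in enumerate(subsample):
            w = _weight_matrix_row(kernel, D[row])
            w[i] = 0.0  # leave the reconstructed cell out
            if np.count_nonzero(w) < p + 1:
                warnings.warn(
                    f"bandwidth {b:g}: neighborhood of cell {i} too small; score set to inf"
                )
                total = np.inf
                break
            cov = local_weighted_cov(Z, w)
            vals, vecs = local_eigen(cov)
            Vk = vecs[:, :k]
            mu = (w / w.sum()) @ Z
            resid = (Z[i] - mu) - Vk @ (Vk.T @ (Z[i] - mu))
            total += float(resid @ resid)
        scores[ci] = total
    best = int(np.argmin(scores))  # argmin takes the first (smallest b) on ties
    if not np.isfinite(scores[best]):
        raise BandwidthTooSmallError("every candidate bandwidth starves some neighborhood")
    return BandwidthCVResult(
        candidates=cand,
        scores=scores,
        selected=float(cand[best]),
        k=k,
        subsample_frac=subsample_frac,
        seed=seed,
    )


def eigen_summary(result: GWPCAResult) -> pd.DataFrame:
    """Location-averaged eigenvalues and percent variance per component."""
    mean_vals = result.eigenvalues.mean(axis=0)
    p = result.n_vars
    return pd.DataFrame(
        {
            "component": [f"PC{m + 1}" for m in range(p)],
            "mean_eigenvalue": mean_vals,
            "pct_variance": 100 * mean_vals / p,
            "cum_pct_variance": 100 * np.cumsum(mean_vals) / p,
        }
    )
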
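"""Synthetic covariate stacks, DEMs and two-regime scenarios.

Real auxiliary rasters (terrain, climate, radar backscatter, legacy soil
maps) are spatially autocorrelated continuous fields mixed with blocky
categorical class maps.  The generators here emulate that structure with
known ground truth so that every downstream stage — weighted PCA, terrain
derivatives, annealed sampling — can be tested end to end without any
external data.  All generators are pure functions of their parameters and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import CATEGORICAL, CONTINUOUS, CovariateStack, GridSpec, Layer


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one Gaussian-random-field layer.

    range   : correlation length in map units (0 = white noise)
    sill    : marginal variance of the field
    nugget  : fraction of the sill contributed by iid noise, in [0, 1]
    """

    grid: GridSpec
    range: float = 0.0
    sill: float = 1.0
    nugget: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.range < 0:
            raise ValueError("range must be >= 0")
        if self.sill <= 0:
            raise ValueError("sill must be > 0")
        if not 0.0 <= self.nugget <= 1.0:
            raise ValueError("nugget fraction must lie in [0, 1]")


def gaussian_random_field(spec: FieldSpec, name: str = "grf") -> Layer:
    """Stationary Gaussian random field by kernel-convolution synthesis.

    White noise is convolved with a Gaussian kernel whose length-scale is
    ``range`` expressed in cells, rescaled to variance ``(1 - nugget) * sill``,
    and iid nugget noise of variance ``nugget * sill`` is added.  Edge
    effects are avoided by synthesising a padded field and cropping.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.grid
    sigma_cells = spec.range / g.cell_size
    pad = int(np.ceil(4 * sigma_cells))
    noise = rng.standard_normal((g.n_rows + 2 * pad, g.n_cols + 2 * pad))
    if sigma_cells > 0:
        smooth = gaussian_filter(noise, sigma=sigma_cells, mode="constant")
    else:
        smooth = noise
    core = smooth[pad : pad + g.n_rows, pad : pad + g.n_cols]
    sd = core.std()
    if sd > 0:
        core = (core - core.mean()) / sd
    structured_var = (1.0 - spec.nugget) * spec.sill
    field = core * np.sqrt(structured_var)
    if spec.nugget > 0:
        field = field + rng.standard_normal(core.shape) * np.sqrt(spec.nugget * spec.sill)
    return Layer(name=name, kind=CONTINUOUS, values=field)


def make_categorical_layer(
    grid: GridSpec,
    n_classes: int,
    seed: int = 0,
    range_: float | None = None,
    name: str = "classes",
) -> Layer:
    """Blocky class map: quantile thresholds of a smooth random field.

    Codes are contiguous integers ``0..n_classes-1``; quantile thresholds
    guarantee every class occupies roughly ``1/n_classes`` of the grid.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if range_ is None:
        range_ = 8 * grid.cell_size
    base = gaussian_random_field(FieldSpec(grid=grid, range=range_, sill=1.0, seed=seed))
    v = base.values
    edges = np.quantile(v, np.linspace(0, 1, n_classes + 1)[1:-1])
    codes = np.searchsorted(edges, v, side="right").astype(float)
    return Layer(name=name, kind=CATEGORICAL, values=codes)


def make_dem_plane(
    grid: GridSpec, gx: float = 0.0, gy: float = 0.0, z0: float = 0.0, name: str = "dem"
) -> Layer:
    """Analytic inclined plane ``z(x, y) = z0 + gx*x + gy*y`` at cell centers.

    ``gx`` is the elevation gradient per map unit eastward, ``gy`` per map
    unit northward (y decreases with row index).
    """
    x, y = grid.cell_centers()
    z = z0 + gx * x + gy * y
    return Layer(name=name, kind=CONTINUOUS, values=z.reshape(grid.n_rows, grid.n_cols))


@dataclass(frozen=True)
class TwoRegimeTruth:
    """Known local structure of a two-regime stack.

    The leading local principal direction (on correlation scale) is
    ``west_direction`` for columns < split_col and ``east_direction`` for
    columns >= split_col; the hub variable (largest |loading|) is layer 0
    in the west, layer 1 in the east.
    """

    split_col: int
    west_direction: np.ndarray
    east_direction: np.ndarray


def _hub_truth(p: int, hub: int, partners: tuple[int, int], c: float) -> np.ndarray:
    """Leading eigenvector of the analytic regime correlation matrix."""
    R = np.eye(p)
    a, b = partners
    R[hub, a] = R[a, hub] = c
    R[hub, b] = R[b, hub] = c
    R[a, b] = R[b, a] = c * c
    vals, vecs = np.linalg.eigh(R)
    v = vecs[:, -1]
    return v if v[hub] > 0 else -v


def make_two_regime_stack(
    grid: GridSpec,
    p: int = 4,
    seed: int = 0,
    hub_corr: float = 0.9,
    hub_sd: float = 3.0,
) -> tuple[CovariateStack, TwoRegimeTruth]:
    """Stack whose leading local component flips between two sub-regions.

    Each half of the domain (hard split at the middle column) has its own
    latent factor.  In the west half layer 0 is the factor itself ("hub",
    amplified to ``hub_sd`` times the noise scale) and layers 1 and 2 are
    partners correlated ``hub_corr`` with it; in the east half layer 1 is
    the hub with partners 0 and 2.  On correlation scale the hub carries
    the largest loading of the local leading component, so the regime's
    dominant variable and leading direction are known exactly, while a
    global PCA mixes the two hubs.  Fields are spatially white so local
    correlation estimates carry maximal effective sample size.
    """
    if p < 3:
        raise ValueError("two-regime stack needs at least 3 layers")
    if not 0 < hub_corr < 1:
        raise ValueError("hub_corr must lie in (0, 1)")
    split = grid.n_cols // 2
    west = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    west[:, :split] = True
    u = [
        gaussian_random_field(FieldSpec(grid=grid, seed=seed * 1009 + j)).values
        for j in range(p)
    ]
    s_w = gaussian_random_field(FieldSpec(grid=grid, seed=seed * 1009 + p)).values
    s_e = gaussian_random_field(FieldSpec(grid=grid, seed=seed * 1009 + p + 1)).values
    c = hub_corr
    d = np.sqrt(1 - c * c)
    vals = [
        np.where(west, hub_sd * s_w, c * s_e + d * u[0]),
        np.where(west, c * s_w + d * u[1], hub_sd * s_e),
        np.where(west, c * s_w + d * u[2], c * s_e + d * u[2]),
    ] + [u[j] for j in range(3, p)]
    layers = [Layer(name=f"var{j}", kind=CONTINUOUS, values=v) for j, v in enumerate(vals)]
    truth = TwoRegimeTruth(
        split_col=split,
        west_direction=_hub_truth(p, 0, (1, 2), c),
        east_direction=_hub_truth(p, 1, (0, 2), c),
    )
    return CovariateStack(grid=grid, layers=layers), truth


def make_stack(
    grid: GridSpec,
    n_continuous: int = 5,
    n_categorical: int = 0,
    range_: float | None = None,
    common: float = 0.0,
    seed: int = 0,
) -> CovariateStack:
    """Homogeneous test stack: GRF layers + optional class maps.

    ``common`` in [0, 1) adds a shared latent factor so every pair of
    continuous layers has correlation ``common`` — a single *global*
    covariance structure, the same everywhere on the grid.
    """
    if range_ is None:
        range_ = 4 * grid.cell_size
    if not 0 <= common < 1:
        raise ValueError("common correlation must lie in [0, 1)")
    shared = (
        gaussian_random_field(
            FieldSpec(grid=grid, range=range_, sill=1.0, seed=seed * 7919 + 7817)
        ).values
        if common > 0
        else None
    )
    layers = []
    for j in range(n_continuous):
        base = gaussian_random_field(
            FieldSpec(grid=grid, range=range_, sill=1.0, seed=seed * 7919 + j),
            name=f"cov{j}",
        )
        if shared is not None:
            mixed = np.sqrt(common) * shared + np.sqrt(1 - common) * base.values
            base = Layer(name=f"cov{j}", kind=CONTINUOUS, values=mixed)
        layers.append(base)
    for j in range(n_categorical):
        layers.append(
            make_categorical_layer(grid, n_classes=3, seed=seed * 104729 + j, name=f"class{j}")
        )
    return CovariateStack(grid=grid, layers=layers)
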
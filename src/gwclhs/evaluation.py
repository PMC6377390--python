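"""Scoring of model-selected sampling locations against field outcomes.

Three checks: a positional RMSE between predicted and confirmed locations
(paired by id, Euclidean map distance), a squared Pearson correlation
between the stacked coordinate vectors of the two point sets, and a
binary suitability form — six field criteria per location, each scored
0 (unsuitable) or 1 (suitable), averaged and expressed as a percentage.
A design-comparison summary contrasts constrained and unconstrained
designs on mean cost and spacing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .terrain import CostSurface

CRITERIA = (
    "soil_type",
    "geology",
    "landform",
    "access_tube",
    "drainage",
    "effective_depth_gt_100cm",
)


def _paired_arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    req = {"pred_x", "pred_y", "act_x", "act_y"}
    if not req.issubset(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(req)}")
    P = pairs[["pred_x", "pred_y"]].to_numpy(float)
    A = pairs[["act_x", "act_y"]].to_numpy(float)
    if not (np.isfinite(P).all() and np.isfinite(A).all()):
        raise ValueError("coordinates must be finite")
    return P, A


def rmse_locations(pairs: pd.DataFrame) -> float:
    """Root mean square Euclidean distance between paired locations.

    RMSE = sqrt( (1/n) * sum_i ||P_i - A_i||^2 ), in map units.
    """
    if len(pairs) == 0:
        raise ValueError("no location pairs")
    P, A = _paired_arrays(pairs)
    d2 = ((P - A) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def correlation_locations(pairs: pd.DataFrame) -> float:
    """Squared Pearson correlation between stacked coordinate vectors.

    Predicted (x's then y's) against actual; one defensible reading of a
    location-agreement correlation, isolated here so alternates can be
    swapped in.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    P, A = _paired_arrays(pairs)
    u = np.concatenate([P[:, 0], P[:, 1]])
    v = np.concatenate([A[:, 0], A[:, 1]])
    if u.std() == 0 or v.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = np.corrcoef(u, v)[0, 1]
    return float(r**2)


def suitability_scores(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Score the binary field-suitability form.

    ``records``: one row per location, an id column (``location`` or the
    index) and one 0/1 column per criterion.  Returns the per-location
    table with ``mean_score`` and ``percentage`` appended, plus the
    fraction of locations at each distinct percentage level.
    """
    crit_cols = [c for c in records.columns if c != "location"]
    if not crit_cols:
        raise ValueError("no criteria columns")
    vals = records[crit_cols]
    for col in crit_cols:
        bad = ~vals[col].isin([0, 1])
        if bad.any():
            loc = records.index[bad][0] if "location" not in records else records.loc[bad, "location"].iloc[0]
            raise ValueError(f"criterion {col!r} at location {loc!r} is not binary")
    out = records.copy()
    out["mean_score"] = vals.mean(axis=1)
    out["percentage"] = out["mean_score"] * 100
    summary = out["percentage"].round(2).value_counts(normalize=True).sort_index()
    return out, summary


def compare_designs(
    design_a, design_b, cost: CostSurface
) -> pd.DataFrame:
    """Contrast two designs on the same cost grid.

    Reports per-design mean cost and mean nearest-neighbor spacing, plus
    the mean-cost difference (A - B).  Hypothesis testing is left to the
    caller.
    """
    rows = {}
    for label, design in (("A", design_a), ("B", design_b)):
        ids = np.asarray(design.cell_ids, dtype=int)
        if ids.max() >= cost.grid.n_cells or ids.min() < 0:
            raise ValueError(f"design {label} does not fit the cost grid")
        c = cost.at_cells(ids)
        x, y = cost.grid.cell_centers(ids)
        pts = np.column_stack([x, y])
        if ids.size >= 2:
            from scipy.spatial.distance import squareform

            D = squareform(pdist(pts))
            np.fill_diagonal(D, np.inf)
            nn = float(D.min(axis=1).mean())
        else:
            nn = np.nan
        rows[label] = {"mean_cost": float(c.mean()), "mean_nn_spacing": nn, "n": ids.size}
    summary = pd.DataFrame(rows).T
    summary.attrs["mean_cost_difference"] = rows["A"]["mean_cost"] - rows["B"]["mean_cost"]
    return summary
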
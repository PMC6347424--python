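"""Model-matrix assembly: standardization, collinearity screen, Box-Cox, weights.

The pre-modeling chain is: divide each predictor by its maximum (so the
maximum maps to exactly 1), drop one member of every predictor pair whose
|Pearson r| exceeds the collinearity threshold (a priority list decides which
member survives), Box-Cox-transform the beta_w response by profile maximum
likelihood, and attach per-cell weights derived from species richness.

Weight semantics: the model variance of cell i is proportional to
``1 / weight_i``.  ``weight_mode="intent"`` (default) uses weight = gamma, so
species-poor cells are down-weighted; ``"paper-literal"`` uses weight =
1/gamma, reproducing the reciprocal-of-richness phrasing verbatim.  With
constant richness the two differ only by a scale absorbed into sigma^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .grid import NeighborGraph
from .hetero import PREDICTOR_COLUMNS

__all__ = [
    "ModelMatrix",
    "standardize",
    "collinearity_filter",
    "boxcox_transform",
    "boxcox_fit",
    "assemble",
    "DEFAULT_PRIORITY",
]

# Higher-priority predictors survive a collinear pair.  The default order
# keeps CV_Tm over ROV_Elev and ROV_Pp over CV_Pp, reproducing the published
# drop choices when the data exhibit those correlations.
DEFAULT_PRIORITY = ["CV_Tm", "ROV_Pp", "CV_Pp", "ROV_Tm", "CV_Elev", "Veg_H", "Soil_H", "ROV_Elev"]


@dataclass
class ModelMatrix:
    """Aligned response / predictors / weights / graph for one taxon and scale."""

    response: np.ndarray
    boxcox_power: float
    predictors: pd.DataFrame
    weights: np.ndarray
    graph: NeighborGraph
    cell_ids: list[tuple[int, int]]
    beta_w: np.ndarray
    dropped_variables: list[dict] = field(default_factory=list)
    taxon: str = ""
    scale: float = float("nan")

    @property
    def n(self) -> int:
        return len(self.response)

    def design(self) -> tuple[np.ndarray, list[str]]:
        """Design matrix with a leading intercept column and its column names."""
        X = np.column_stack([np.ones(self.n), self.predictors.to_numpy(dtype=float)])
        return X, ["Intercept", *self.predictors.columns]


def standardize(values: np.ndarray) -> np.ndarray:
    """Divide by the column maximum so values are proportional on (0, 1]."""
    values = np.asarray(values, dtype=float)
    vmax = np.nanmax(values)
    if not vmax > 0:
        raise ValueError("cannot standardize a predictor with non-positive maximum")
    return values / vmax


def collinearity_filter(
    predictors: pd.DataFrame,
    threshold: float = 0.8,
    priority: list[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop the lower-priority member of every |r| > threshold pair.

    Pairs are visited in priority order, so the retained set depends only on
    the priority list, never on input column order.  Returns the filtered
    table and a drop log of ``{dropped, against, r}`` records.
    """
    if predictors.shape[1] < 2:
        return predictors, []
    priority = [c for c in (priority or DEFAULT_PRIORITY) if c in predictors.columns]
    priority += [c for c in predictors.columns if c not in priority]

    corr = predictors[priority].corr()
    kept: list[str] = []
    log: list[dict] = []
    for col in priority:
        clash = next(
            (k for k in kept if abs(corr.loc[col, k]) > threshold), None
        )
        if clash is None:
            kept.append(col)
        else:
            log.append({"dropped": col, "against": clash, "r": float(corr.loc[col, clash])})
    if not kept:
        raise ValueError("collinearity filter dropped every predictor")
    return predictors[kept], log


def boxcox_transform(y: np.ndarray, power: float) -> np.ndarray:
    """(y^p - 1)/p for p != 0; ln y at p = 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if power == 0:
        return np.log(y)
    return (y**power - 1.0) / power


def _boxcox_loglik(power: float, y: np.ndarray, logy_sum: float) -> float:
    t = boxcox_transform(y, power)
    var = t.var()
    if var <= 0:
        return -np.inf
    n = y.size
    return -0.5 * n * np.log(var) + (power - 1.0) * logy_sum


def boxcox_fit(y: np.ndarray, bounds: tuple[float, float] = (-2.0, 2.0)) -> tuple[float, np.ndarray]:
    """Estimate the Box-Cox power by profile Gaussian likelihood.

    Dense grid over ``bounds`` followed by bounded local refinement
    (tolerance 1e-4).  A constant input degenerates; the power is fixed at 1
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("Box-Cox requires finite, strictly positive values")
    if np.ptp(y) == 0:
        warnings.warn("constant response; Box-Cox power fixed at 1", stacklevel=2)
        return 1.0, boxcox_transform(y, 1.0)
    logy_sum = float(np.log(y).sum())
    grid = np.linspace(bounds[0], bounds[1], 81)
    ll = np.array([_boxcox_loglik(p, y, logy_sum) for p in grid])
    k = int(np.argmax(ll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda p: -_boxcox_loglik(p, y, logy_sum),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    power = float(res.x)
    return power, boxcox_transform(y, power)


def assemble(
    diversity: pd.DataFrame,
    heterogeneity: pd.DataFrame,
    graph: NeighborGraph,
    weight_mode: str = "intent",
    collinearity_threshold: float = 0.8,
    priority: list[str] | None = None,
    standardize_scope: str = "all",
) -> ModelMatrix:
    """Join records, clean, transform, and align everything on one cell order.

    Rows are restricted to unflagged cells with complete data; the graph is
    subset to the same cells in the same order.  ``standardize_scope`` is
    ``"all"`` (default) or ``"rov"`` (only the ROV_* columns are rescaled).
    """
    if weight_mode not in ("intent", "paper-literal"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    merged = diversity.merge(heterogeneity, on=["cell_id", "scale"], how="inner")
    merged = merged[~merged["flagged"]]
    pred_cols = [c for c in PREDICTOR_COLUMNS if c in merged.columns]
    complete = merged.dropna(subset=["beta_w", *pred_cols])
    n_dropped = len(merged) - len(complete)
    if n_dropped:
        warnings.warn(f"{n_dropped} cell(s) dropped for missing values", stacklevel=2)
    # order rows by the graph's node order (tuples make poor pandas indexes)
    pos = {cid: i for i, cid in enumerate(complete["cell_id"])}
    order = [pos[c] for c in graph.nodes if c in pos]
    complete = complete.iloc[order]

    preds = complete[pred_cols].astype(float).copy()
    dropped: list[dict] = []
    for col in pred_cols:
        scoped = standardize_scope == "all" or col.startswith("ROV_")
        colmax = np.nanmax(preds[col].to_numpy())
        if np.ptp(preds[col].to_numpy()) == 0:
            dropped.append({"dropped": col, "against": None, "r": None, "reason": "constant"})
            preds = preds.drop(columns=[col])
        elif scoped:
            if not colmax > 0:
                raise ValueError(f"predictor {col} has non-positive maximum")
            preds[col] = standardize(preds[col].to_numpy())
    preds, colin_log = collinearity_filter(preds, collinearity_threshold, priority)
    dropped.extend(colin_log)

    if len(complete) < preds.shape[1] + 2:
        raise ValueError(
            f"too few cells ({len(complete)}) for {preds.shape[1]} predictors"
        )

    beta_w = complete["beta_w"].to_numpy(dtype=float)
    power, response = boxcox_fit(beta_w)
    gamma = complete["gamma"].to_numpy(dtype=float)
    weights = gamma if weight_mode == "intent" else 1.0 / gamma

    cell_ids = list(complete["cell_id"])
    return ModelMatrix(
        response=response,
        boxcox_power=power,
        predictors=preds,
        weights=weights,
        graph=graph.subgraph(cell_ids),
        cell_ids=cell_ids,
        beta_w=beta_w,
        dropped_variables=dropped,
        taxon=str(complete["taxon"].iloc[0]) if "taxon" in complete else "",
        scale=float(complete["scale"].iloc[0]),
    )
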
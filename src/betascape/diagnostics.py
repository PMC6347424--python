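"""Residual diagnostics: Moran's I (analytic + Monte-Carlo) and normality.

Moran's I uses the binary Queen adjacency by default, matching the CAR
neighborhood; a row-standardized option is available.  The Monte-Carlo test
permutes values over cells and reports the one-sided (greater)
p-value ``(#{I_perm >= I_obs} + 1) / (n_perm + 1)`` by default — the
conventional alternative for "remaining positive spatial autocorrelation" —
with a two-sided option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import NeighborGraph

__all__ = ["MoranResult", "morans_i", "morans_mc", "residual_normality"]


@dataclass(frozen=True)
class MoranResult:
    I_observed: float
    I_expected: float  # -1/(n-1)
    p_value: float
    n_permutations: int
    seed: int
    alternative: str = "greater"


def _weight_matrix(graph: NeighborGraph, row_standardize: bool) -> np.ndarray:
    W = graph.W
    if row_standardize:
        deg = W.sum(axis=1, keepdims=True)
        W = np.divide(W, deg, out=np.zeros_like(W), where=deg > 0)
    return W


def morans_i(values: np.ndarray, graph: NeighborGraph, row_standardize: bool = False) -> float:
    """I = (n/S0) * (z' W z)/(z' z) with z the mean-centered values."""
    values = np.asarray(values, dtype=float)
    n = graph.n
    if values.shape != (n,):
        raise ValueError("values length must equal graph size")
    if n < 3:
        raise ValueError("Moran's I needs at least 3 cells")
    W = _weight_matrix(graph, row_standardize)
    S0 = W.sum()
    if S0 <= 0:
        raise ValueError("graph has no links (S0 = 0)")
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    return float((n / S0) * (z @ W @ z) / denom)


def morans_mc(
    values: np.ndarray,
    graph: NeighborGraph,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    row_standardize: bool = False,
) -> MoranResult:
    """Monte-Carlo Moran's I test by random permutation of values over cells."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    values = np.asarray(values, dtype=float)
    i_obs = morans_i(values, graph, row_standardize)
    rng = np.random.default_rng(seed)
    n = graph.n
    W = _weight_matrix(graph, row_standardize)
    S0 = W.sum()
    z = values - values.mean()
    denom = float(z @ z)
    scale = n / (S0 * denom)

    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        zp = z[rng.permutation(n)]
        perms[k] = scale * (zp @ W @ zp)
    if alternative == "greater":
        extreme = np.count_nonzero(perms >= i_obs)
    else:
        center = -1.0 / (n - 1)
        extreme = np.count_nonzero(np.abs(perms - center) >= abs(i_obs - center))
    p = (extreme + 1) / (n_permutations + 1)
    return MoranResult(
        I_observed=i_obs,
        I_expected=-1.0 / (n - 1),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
    )


def residual_normality(residuals: np.ndarray, n_quantiles: int = 100) -> dict:
    """Moment summaries plus sorted-residual vs normal-quantile pairs.

    Returns skewness, excess kurtosis, mean, sd, and a QQ table suitable for
    plotting; no formal hypothesis test is applied.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n < 8:
        raise ValueError("need at least 8 residuals")
    srt = np.sort(residuals)
    probs = (np.arange(n) + 0.5) / n
    theo = stats.norm.ppf(probs, loc=residuals.mean(), scale=residuals.std(ddof=1))
    step = max(n // n_quantiles, 1)
    return {
        "n": int(n),
        "mean": float(residuals.mean()),
        "sd": float(residuals.std(ddof=1)),
        "skewness": float(stats.skew(residuals)),
        "excess_kurtosis": float(stats.kurtosis(residuals)),
        "qq": [
            {"theoretical": float(t), "observed": float(o)}
            for t, o in zip(theo[::step], srt[::step])
        ],
    }
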
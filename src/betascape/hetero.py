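"""Per-cell environmental-heterogeneity predictors.

Eight quantities per cell: range of values (ROV) and coefficient of variation
(CV) for elevation, precipitation and temperature, plus Shannon-Wiener H of
the vegetation and soil class maps.  Conventions:

* ``ROV_Tm = max(Tmax) - min(Tmin)`` (cross-layer range);
* ``CV_Tm`` is computed on per-pixel mean annual temperature (tmax+tmin)/2;
* CV uses the sample (n-1) standard deviation; a single-pixel cell has CV 0;
  a non-positive mean makes CV undefined (NaN, reason logged by the caller);
* class areas for H are pixel counts (equal-area approximation at ~1 km
  grain).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import CellSet
from .synth import Landscape

__all__ = ["rov", "cv", "shannon_h", "heterogeneity_table", "PREDICTOR_COLUMNS"]

PREDICTOR_COLUMNS = [
    "ROV_Elev", "ROV_Pp", "ROV_Tm", "CV_Elev", "CV_Pp", "CV_Tm", "Veg_H", "Soil_H",
]


def rov(values: np.ndarray) -> float:
    """Range of values: max - min over the valid pixels of a cell."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    return float(values.max() - values.min())


def cv(values: np.ndarray) -> float:
    """Coefficient of variation: sample std (n-1) / mean.

    Returns NaN when the mean is non-positive (undefined; can happen for
    temperature in degC) and 0 for single-pixel cells.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    mean = values.mean()
    if mean <= 0:
        return float("nan")
    if values.size == 1:
        return 0.0
    return float(values.std(ddof=1) / mean)


def shannon_h(class_areas: np.ndarray) -> float:
    """Shannon-Wiener index -sum(p_i ln p_i) in nats from per-class areas.

    0 when a single class covers the cell; ln(S) when S classes share it
    equally.  Zero total area is undefined (NaN).
    """
    areas = np.asarray(class_areas, dtype=float)
    areas = areas[areas > 0]
    total = areas.sum()
    if total <= 0:
        return float("nan")
    p = areas / total
    return float(-(p * np.log(p)).sum())


def _class_h(layer: np.ndarray) -> float:
    _, counts = np.unique(layer, return_counts=True)
    return shannon_h(counts)


def heterogeneity_table(landscape: Landscape, cells: CellSet) -> pd.DataFrame:
    """One row per retained cell with all eight predictors.

    Undefined components are recorded as NaN; downstream assembly drops such
    cells from modeling with a logged reason.
    """
    elev = landscape.elevation.ravel()
    pp = landscape.precipitation.ravel()
    tmax = landscape.tmax.ravel()
    tmin = landscape.tmin.ravel()
    mat = landscape.mat.ravel()
    veg = landscape.vegetation.ravel()
    soil = landscape.soil.ravel()

    rows = []
    for cell in sorted(cells.cell_ids):
        idx = cells.pixels[cell]
        rows.append(
            {
                "cell_id": cell,
                "scale": cells.grid.scale,
                "ROV_Elev": rov(elev[idx]),
                "ROV_Pp": rov(pp[idx]),
                "ROV_Tm": float(np.max(tmax[idx]) - np.min(tmin[idx])) if idx.size else np.nan,
                "CV_Elev": cv(elev[idx]),
                "CV_Pp": cv(pp[idx]),
                "CV_Tm": cv(mat[idx]),
                "Veg_H": _class_h(veg[idx]),
                "Soil_H": _class_h(soil[idx]),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "scale", *PREDICTOR_COLUMNS])
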
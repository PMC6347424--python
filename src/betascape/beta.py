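"""Whittaker multiplicative beta-diversity per grid cell.

For each retained cell (one *region*), gamma is the number of species with at
least one presence pixel in the cell, mean alpha is the average per-pixel
species count over the cell's in-mask pixels (the *sites*), and
``beta_w = gamma / mean alpha``.  beta_w runs from 1 (every species in every
pixel) up to gamma (every species confined to a single pixel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import CellSet
from .synth import PresenceStack

__all__ = ["cell_diversity", "beta_summary"]

DIVERSITY_COLUMNS = [
    "cell_id", "taxon", "scale", "n_pixels", "alpha_mean", "gamma", "beta_w", "flagged",
]


def cell_diversity(
    presences: PresenceStack,
    cells: CellSet,
    include_empty_pixels: bool = True,
) -> pd.DataFrame:
    """Per-cell gamma, mean alpha and beta_w for one taxon.

    Empty (zero-richness) in-mask pixels enter the mean-alpha denominator by
    default; ``include_empty_pixels=False`` restricts sites to occupied pixels
    for sensitivity checks.  Cells with gamma = 0 are kept but ``flagged``
    (beta_w is NaN there) so they can be excluded from modeling explicitly.
    """
    n_sp = presences.n_species
    flat = presences.occupancy.reshape(n_sp, -1) if n_sp else np.zeros((0, 0), dtype=np.uint8)
    pixel_richness = (
        flat.sum(axis=0)
        if n_sp
        else np.zeros(np.prod(presences.occupancy.shape[1:] or (0,)), dtype=int)
    )

    rows = []
    for cell in sorted(cells.cell_ids):
        idx = cells.pixels[cell]
        gamma = int((flat[:, idx].max(axis=1) > 0).sum()) if (n_sp and idx.size) else 0
        rich = pixel_richness[idx]
        if not include_empty_pixels:
            rich = rich[rich > 0]
        n_sites = int(rich.size)
        alpha_mean = float(rich.mean()) if n_sites else 0.0
        if gamma > 0:
            assert alpha_mean > 0, "gamma > 0 with zero mean alpha is impossible"
            beta_w = gamma / alpha_mean
            flagged = False
        else:
            beta_w = np.nan
            flagged = True
        rows.append(
            {
                "cell_id": cell,
                "taxon": presences.taxon,
                "scale": cells.grid.scale,
                "n_pixels": int(idx.size),
                "alpha_mean": alpha_mean,
                "gamma": gamma,
                "beta_w": beta_w,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows, columns=DIVERSITY_COLUMNS)


def beta_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Count / min / median / max of beta_w per taxon and scale."""
    if records.empty:
        return pd.DataFrame(columns=["taxon", "scale", "n_cells", "min", "median", "max"])
    ok = records[~records["flagged"]]
    out = (
        ok.groupby(["taxon", "scale"], as_index=False)["beta_w"]
        .agg(n_cells="count", min="min", median="median", max="max")
    )
    return out
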
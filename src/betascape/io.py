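"""Text-format readers/writers: ESRI ASCII grids, GeoJSON cells, edge lists.

Rasters travel as ESRI ASCII grids (plain text, universally readable by GIS
stacks) rather than GeoTIFF so that every artifact in a run directory stays
text.  Grid cells and their attributes are exported as GeoJSON polygons;
neighbor graphs as edge-list CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CellSet, GeoTransform, NeighborGraph

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "cells_to_geojson",
    "graph_to_edgelist",
    "cell_id_str",
]


def cell_id_str(cell: tuple[int, int]) -> str:
    return f"r{cell[0]}c{cell[1]}"


def write_ascii_grid(path, array: np.ndarray, transform: GeoTransform, nodata=-9999) -> None:
    array = np.asarray(array)
    nrow, ncol = array.shape
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {transform.lon_min}\n"
        f"yllcorner {transform.lat_max - nrow * transform.pixel_size}\n"
        f"cellsize {transform.pixel_size}\nNODATA_value {nodata}\n"
    )
    body = array.astype(float)
    body = np.where(np.isfinite(body), body, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, GeoTransform]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = hdr.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    tr = GeoTransform(
        lon_min=hdr["xllcorner"],
        lat_max=hdr["yllcorner"] + hdr["nrows"] * hdr["cellsize"],
        pixel_size=hdr["cellsize"],
    )
    return data, tr


def cells_to_geojson(cells: CellSet, attributes: pd.DataFrame | None = None, path=None) -> dict:
    """GeoJSON FeatureCollection of cell polygons, optionally joined to a
    cell-keyed attribute table (column ``cell_id`` holding (row, col) tuples)."""
    attr_map: dict = {}
    if attributes is not None:
        for _, row in attributes.iterrows():
            attr_map[tuple(row["cell_id"])] = {
                k: (None if pd.isna(v) else v)
                for k, v in row.drop(labels=["cell_id"]).items()
            }
    features = []
    for cell in sorted(cells.cell_ids):
        lon0, lat0, lon1, lat1 = cells.grid.cell_bounds(cell)
        props = {
            "cell_id": cell_id_str(cell),
            "row": cell[0],
            "col": cell[1],
            "inside_fraction": cells.inside_fraction[cell],
            **attr_map.get(cell, {}),
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[lon0, lat0], [lon1, lat0], [lon1, lat1], [lon0, lat1], [lon0, lat0]]
                    ],
                },
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc, indent=1, default=float))
    return fc


def graph_to_edgelist(graph: NeighborGraph, path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"source": cell_id_str(a), "target": cell_id_str(b)}
            for a, b in graph.edge_list()
        ]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
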
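"""Degree-aligned analysis grids, mask-based cell retention, and Queen-contiguity graphs.

Grid cells are half-open boxes ``[lon0 + j*s, lon0 + (j+1)*s) x [lat0 + i*s,
lat0 + (i+1)*s)`` aligned to an integer-degree anchor (default 0E/0N) so that
the 2/1/0.5/0.25-degree grids nest.  Pixels are assigned to cells by their
center coordinate, which makes the assignment a true partition.  Cell ids are
0-based ``(row, col)`` pairs increasing north-to-south and west-to-east.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeoTransform",
    "GridSpec",
    "CellSet",
    "NeighborGraph",
    "build_grid",
    "apply_mask",
    "queen_graph",
]


@dataclass(frozen=True)
class GeoTransform:
    """Geographic registration of a pixel raster.

    ``lon_min``/``lat_max`` locate the outer corner of the upper-left pixel;
    ``pixel_size`` is the square pixel edge in degrees.  Row 0 is the
    northernmost pixel row.
    """

    lon_min: float
    lat_max: float
    pixel_size: float

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) center coordinate arrays for a raster of ``shape``."""
        nrow, ncol = shape
        lon = self.lon_min + (np.arange(ncol) + 0.5) * self.pixel_size
        lat = self.lat_max - (np.arange(nrow) + 0.5) * self.pixel_size
        return lon, lat


@dataclass(frozen=True)
class GridSpec:
    """A single-scale analysis grid over a geographic extent.

    The grid covers every cell that intersects ``extent``; rows count from the
    northernmost intersecting cell, columns from the westernmost.
    """

    scale: float
    extent: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max
    origin: tuple[float, float] = (0.0, 0.0)
    # index (in cell steps from origin) of column 0 / the *top* row
    col0: int = field(init=False)
    row_top: int = field(init=False)
    n_rows: int = field(init=False)
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("cell scale must be positive")
        lon_min, lat_min, lon_max, lat_max = self.extent
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ValueError("degenerate extent: zero area")
        s, (olon, olat) = self.scale, self.origin
        c0 = int(np.floor((lon_min - olon) / s))
        c1 = int(np.ceil((lon_max - olon) / s))
        r0 = int(np.floor((lat_min - olat) / s))
        r1 = int(np.ceil((lat_max - olat) / s))
        object.__setattr__(self, "col0", c0)
        object.__setattr__(self, "row_top", r1 - 1)  # northernmost cell step
        object.__setattr__(self, "n_cols", max(c1 - c0, 1))
        object.__setattr__(self, "n_rows", max(r1 - r0, 1))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) cell ids (half-open convention)."""
        s, (olon, olat) = self.scale, self.origin
        col = np.floor((np.asarray(lon) - olon) / s).astype(int) - self.col0
        row = self.row_top - np.floor((np.asarray(lat) - olat) / s).astype(int)
        return row, col

    def cell_bounds(self, cell: tuple[int, int]) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell's box."""
        row, col = cell
        s, (olon, olat) = self.scale, self.origin
        lon0 = olon + (self.col0 + col) * s
        lat1 = olat + (self.row_top - row + 1) * s
        return lon0, lat1 - s, lon0 + s, lat1


@dataclass
class CellSet:
    """Retained cells of one grid with their in-mask pixel index lists.

    ``pixels`` maps cell id to the flat indices of *in-mask* pixels whose
    centers fall in the cell; ``inside_fraction`` is (in-mask pixels)/(all
    pixels of the cell inside the raster extent).
    """

    grid: GridSpec
    pixels: dict[tuple[int, int], np.ndarray]
    inside_fraction: dict[tuple[int, int], float]
    total_pixels: dict[tuple[int, int], int]

    @property
    def cell_ids(self) -> list[tuple[int, int]]:
        return list(self.pixels)

    @property
    def n_cells(self) -> int:
        return len(self.pixels)


class NeighborGraph:
    """Symmetric binary adjacency over an ordered set of cells.

    Also provides the (possibly row-standardized-and-symmetrized) weight
    matrix used by the CAR model and caches its eigenvalues per style.
    """

    def __init__(self, nodes: list[tuple[int, int]], adjacency: np.ndarray):
        adjacency = np.asarray(adjacency, dtype=float)
        n = len(nodes)
        if adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if np.any(np.diag(adjacency) != 0):
            raise ValueError("self-links are not allowed")
        if not np.array_equal(adjacency, adjacency.T):
            raise ValueError("adjacency must be symmetric")
        self.nodes = list(nodes)
        self.W = adjacency
        self._eig_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_cells(cls, cells: list[tuple[int, int]]) -> "NeighborGraph":
        """Queen adjacency: link cells whose (row, col) ids differ by <= 1 in both axes."""
        n = len(cells)
        idx = np.asarray(cells, dtype=int) if n else np.empty((0, 2), dtype=int)
        W = np.zeros((n, n))
        if n:
            dr = np.abs(idx[:, 0][:, None] - idx[:, 0][None, :])
            dc = np.abs(idx[:, 1][:, None] - idx[:, 1][None, :])
            W = ((dr <= 1) & (dc <= 1)).astype(float)
            np.fill_diagonal(W, 0.0)
        return cls(cells, W)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def S0(self) -> float:
        return float(self.W.sum())

    @property
    def n_links(self) -> int:
        return int(round(self.S0 / 2))

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def neighbors(self, node: tuple[int, int]) -> list[tuple[int, int]]:
        i = self.nodes.index(node)
        return [self.nodes[j] for j in np.nonzero(self.W[i])[0]]

    def car_matrix(self, style: str = "W") -> np.ndarray:
        """CAR weight matrix: 'B' = binary; 'W' = symmetric similar of the
        row-standardized adjacency, D^{-1/2} A D^{-1/2} (isolates keep zero rows)."""
        if style == "B":
            return self.W
        if style == "W":
            deg = self.degrees()
            with np.errstate(divide="ignore"):
                dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
            return dinv[:, None] * self.W * dinv[None, :]
        raise ValueError(f"unknown weight style {style!r}")

    def car_eigenvalues(self, style: str = "W") -> np.ndarray:
        if style not in self._eig_cache:
            self._eig_cache[style] = np.linalg.eigvalsh(self.car_matrix(style))
        return self._eig_cache[style]

    def subgraph(self, keep: list[tuple[int, int]]) -> "NeighborGraph":
        pos = {node: i for i, node in enumerate(self.nodes)}
        idx = [pos[c] for c in keep]
        return NeighborGraph(list(keep), self.W[np.ix_(idx, idx)])

    def edge_list(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        ii, jj = np.nonzero(np.triu(self.W))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj)]


def build_grid(
    extent: tuple[float, float, float, float],
    scale_degrees: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> GridSpec:
    """Tile ``extent`` with half-open square cells of edge ``scale_degrees``."""
    return GridSpec(scale=scale_degrees, extent=extent, origin=origin)


def apply_mask(
    grid: GridSpec,
    mask: np.ndarray,
    transform: GeoTransform,
    min_inside_fraction: float = 0.5,
) -> CellSet:
    """Assign pixels to cells and retain cells with inside-fraction >= threshold.

    A cell is eliminated when *more than* 50% of its pixels fall outside the
    mask, so the exact-50% tie is retained.  Fractions are pixel counts, not
    polygon areas.
    """
    mask = np.asarray(mask, dtype=bool)
    nrow, ncol = mask.shape
    lon, lat = transform.pixel_centers(mask.shape)
    LON, LAT = np.meshgrid(lon, lat)
    row, col = grid.cell_of(LON.ravel(), LAT.ravel())
    flat_mask = mask.ravel()

    key = row * (grid.n_cols + 1) + col  # unique per (row, col) within the grid
    order = np.argsort(key, kind="stable")
    key_s, in_s, flat_s = key[order], flat_mask[order], order
    boundaries = np.flatnonzero(np.diff(key_s)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [key.size]])

    pixels: dict[tuple[int, int], np.ndarray] = {}
    fraction: dict[tuple[int, int], float] = {}
    totals: dict[tuple[int, int], int] = {}
    for a, b in zip(starts, ends):
        k = int(key_s[a])
        cell = (k // (grid.n_cols + 1), k % (grid.n_cols + 1))
        total = b - a
        inside = flat_s[a:b][in_s[a:b]]
        frac = inside.size / total
        if frac >= min_inside_fraction and inside.size > 0:
            pixels[cell] = np.sort(inside)
            fraction[cell] = frac
            totals[cell] = total
    if not pixels:
        warnings.warn("mask retains no cells", stacklevel=2)
    return CellSet(grid=grid, pixels=pixels, inside_fraction=fraction, total_pixels=totals)


def queen_graph(cells: CellSet) -> NeighborGraph:
    """Queen-contiguity graph over the retained cells (edge or corner adjacency)."""
    g = NeighborGraph.from_cells(sorted(cells.cell_ids))
    if g.n >= 2 and g.S0 == 0:
        warnings.warn("neighbor graph has no links; CAR fitting will reject it", stacklevel=2)
    return g
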
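"""Synthetic landscapes, virtual species, and direct draws from the CAR model.

Everything is seeded and deterministic: the same :class:`ScenarioConfig`
always produces bit-identical rasters.  Continuous surfaces are sums of a
linear gradient and a low-frequency random harmonic basis whose correlation
length is set (approximately) by ``surface_smoothness``; categorical maps are
quantile bins of auxiliary smooth surfaces, so class patches are spatially
coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .grid import GeoTransform, NeighborGraph

__all__ = [
    "ScenarioConfig",
    "Landscape",
    "PresenceStack",
    "generate_landscape",
    "generate_species",
    "sample_car_response",
]

_DEFAULT_GRADIENTS = {"elevation": 1500.0, "tmax": 6.0, "precipitation": 800.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic scenario."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (-4.0, 0.0, 4.0, 4.0)
    pixel_size: float = 0.05
    n_species: int = 40
    niche_breadth: float = 1.0
    range_occupancy_threshold: float = 0.5
    n_veg_classes: int = 5
    n_soil_classes: int = 7
    surface_smoothness: float = 1.5
    gradient_strengths: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GRADIENTS))
    noise_amplitude: float = 1.0
    mask_shape: str = "full"  # "full" or "ellipse"
    taxon: str = "synthetic"

    def __post_init__(self) -> None:
        lon_min, lat_min, lon_max, lat_max = self.extent
        w, h = lon_max - lon_min, lat_max - lat_min
        if w <= 0 or h <= 0:
            raise ValueError("degenerate extent: zero pixels")
        for span in (w, h):
            ncell = span / self.pixel_size
            if abs(ncell - round(ncell)) > 1e-9:
                raise ValueError("pixel_size must divide the extent evenly")
        if self.n_veg_classes < 1 or self.n_soil_classes < 1:
            raise ValueError("class counts must be >= 1")
        if not 0 < self.range_occupancy_threshold < 1:
            raise ValueError("range_occupancy_threshold must be in (0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        lon_min, lat_min, lon_max, lat_max = self.extent
        return (
            round((lat_max - lat_min) / self.pixel_size),
            round((lon_max - lon_min) / self.pixel_size),
        )

    @property
    def transform(self) -> GeoTransform:
        return GeoTransform(self.extent[0], self.extent[3], self.pixel_size)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["extent"] = list(d["extent"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["extent"] = tuple(d["extent"])
        return cls(**d)


@dataclass
class Landscape:
    """Co-registered environmental pixel layers on one geographic grid."""

    elevation: np.ndarray  # m
    tmax: np.ndarray  # degC
    tmin: np.ndarray  # degC
    mat: np.ndarray  # degC, (tmax + tmin) / 2
    precipitation: np.ndarray  # mm/yr
    vegetation: np.ndarray  # class id, 1..k
    soil: np.ndarray  # class id, 1..m
    mask: np.ndarray  # bool, True inside the study area
    transform: GeoTransform

    def __post_init__(self) -> None:
        shapes = {
            layer.shape
            for layer in (
                self.elevation, self.tmax, self.tmin, self.mat,
                self.precipitation, self.vegetation, self.soil, self.mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError("all layers must share one shape")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax must be >= tmin at every pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def continuous_layers(self) -> dict[str, np.ndarray]:
        return {
            "elevation": self.elevation,
            "tmax": self.tmax,
            "tmin": self.tmin,
            "mat": self.mat,
            "precipitation": self.precipitation,
        }


@dataclass
class PresenceStack:
    """Binary occupancy rasters for the species of one taxon group."""

    taxon: str
    species_ids: list[str]
    occupancy: np.ndarray  # (n_species, nrow, ncol), values in {0, 1}
    transform: GeoTransform

    def __post_init__(self) -> None:
        vals = np.unique(self.occupancy)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("occupancy must be binary")

    @property
    def n_species(self) -> int:
        return self.occupancy.shape[0]

    @property
    def empty_species(self) -> list[str]:
        """Species retained in the stack but occupying zero pixels."""
        sizes = self.occupancy.reshape(self.n_species, -1).sum(axis=1)
        return [sid for sid, s in zip(self.species_ids, sizes) if s == 0]

    def range_sizes(self) -> np.ndarray:
        return self.occupancy.reshape(self.n_species, -1).sum(axis=1)


def _harmonic_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    transform: GeoTransform,
    smoothness: float,
    n_harmonics: int = 24,
) -> np.ndarray:
    """Zero-mean, unit-ish variance smooth random surface.

    Sum of random-phase cosines with frequencies ~ 1/smoothness, so the
    correlation length tracks ``smoothness`` approximately (documented, not
    asserted).
    """
    lon, lat = transform.pixel_centers(shape)
    LON, LAT = np.meshgrid(lon, lat)
    f0 = 1.0 / max(smoothness, 1e-6)
    freqs = rng.uniform(0.1 * f0, f0, size=(n_harmonics, 2))
    signs = rng.choice([-1.0, 1.0], size=(n_harmonics, 2))
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    amps = rng.normal(0, 1, size=n_harmonics)
    out = np.zeros(shape)
    for (fx, fy), (sx, sy), ph, a in zip(freqs, signs, phases, amps):
        out += a * np.cos(2 * np.pi * (sx * fx * LON + sy * fy * LAT) + ph)
    out /= np.sqrt(n_harmonics / 2)
    return out


def _class_map(rng, shape, transform, smoothness, n_classes: int) -> np.ndarray:
    """Quantile-bin a smooth auxiliary surface into 1..n_classes patches."""
    if n_classes == 1:
        return np.ones(shape, dtype=int)
    aux = _harmonic_field(rng, shape, transform, smoothness)
    edges = np.quantile(aux, np.linspace(0, 1, n_classes + 1)[1:-1])
    return (np.digitize(aux, edges) + 1).astype(int)


def generate_landscape(config: ScenarioConfig) -> Landscape:
    """Build seeded, spatially structured environmental layers.

    Temperature decreases with elevation (fixed lapse rate of 6.5 degC/km);
    MAT is derived as (tmax + tmin) / 2.
    """
    rng = np.random.default_rng(config.seed)
    shape, transform = config.shape, config.transform
    lon, lat = transform.pixel_centers(shape)
    LON, LAT = np.meshgrid(lon, lat)
    lon_min, lat_min, lon_max, lat_max = config.extent
    u = (LON - lon_min) / (lon_max - lon_min)  # west->east in [0, 1]
    v = (LAT - lat_min) / (lat_max - lat_min)  # south->north in [0, 1]
    g = config.gradient_strengths
    amp = config.noise_amplitude

    elev_noise = _harmonic_field(rng, shape, transform, config.surface_smoothness)
    elevation = g.get("elevation", 0.0) * u + 600.0 * amp * elev_noise
    elevation = np.maximum(elevation - elevation.min(), 0.0)

    lapse = 6.5 / 1000.0  # degC per m
    t_noise = _harmonic_field(rng, shape, transform, config.surface_smoothness)
    tmax = 32.0 + g.get("tmax", 0.0) * (0.5 - v) - lapse * elevation + 1.5 * amp * t_noise
    spread = 12.0 + 3.0 * amp * np.abs(
        _harmonic_field(rng, shape, transform, config.surface_smoothness)
    )
    tmin = tmax - spread
    mat = 0.5 * (tmax + tmin)

    p_noise = _harmonic_field(rng, shape, transform, config.surface_smoothness)
    precipitation = 900.0 + g.get("precipitation", 0.0) * (v - 0.5) + 300.0 * amp * p_noise
    precipitation = np.maximum(precipitation, 10.0)

    vegetation = _class_map(rng, shape, transform, config.surface_smoothness, config.n_veg_classes)
    soil = _class_map(rng, shape, transform, config.surface_smoothness, config.n_soil_classes)

    if config.mask_shape == "ellipse":
        cx, cy = 0.5 * (lon_min + lon_max), 0.5 * (lat_min + lat_max)
        rx, ry = 0.48 * (lon_max - lon_min), 0.48 * (lat_max - lat_min)
        mask = ((LON - cx) / rx) ** 2 + ((LAT - cy) / ry) ** 2 <= 1.0
    else:
        mask = np.ones(shape, dtype=bool)

    return Landscape(
        elevation=elevation, tmax=tmax, tmin=tmin, mat=mat,
        precipitation=precipitation, vegetation=vegetation, soil=soil,
        mask=mask, transform=transform,
    )


def generate_species(config: ScenarioConfig, landscape: Landscape) -> PresenceStack:
    """Virtual species from Gaussian niche suitability on (MAT, precipitation).

    Each species draws a niche optimum from the environment values observed at
    in-mask pixels; it is present wherever
    ``exp(-d^2 / 2)`` >= ``range_occupancy_threshold``, with ``d`` the
    Euclidean distance to the optimum in z-scored environment space divided by
    ``niche_breadth``.  Smaller breadth means smaller ranges.  Species whose
    range is empty are retained and flagged via ``empty_species``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    env = np.stack([landscape.mat, landscape.precipitation])  # (2, H, W)
    inmask = landscape.mask
    flat = env[:, inmask]  # (2, n_pixels)
    mu, sd = flat.mean(axis=1), flat.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (env - mu[:, None, None]) / sd[:, None, None]

    n = config.n_species
    occ = np.zeros((n, *landscape.shape), dtype=np.uint8)
    ids = [f"sp{i:04d}" for i in range(n)]
    if n:
        picks = rng.integers(0, flat.shape[1], size=n)
        optima = (flat[:, picks] - mu[:, None]) / sd[:, None]  # z-scored optima
        for i in range(n):
            d2 = ((z - optima[:, i][:, None, None]) ** 2).sum(axis=0)
            suit = np.exp(-d2 / (2.0 * config.niche_breadth**2))
            occ[i] = (suit >= config.range_occupancy_threshold) & inmask
    return PresenceStack(
        taxon=config.taxon, species_ids=ids, occupancy=occ, transform=landscape.transform
    )


def sample_car_response(
    graph: NeighborGraph,
    X: np.ndarray,
    beta: np.ndarray,
    lam: float,
    sigma2: float,
    weights: np.ndarray | float = 1.0,
    seed: int = 0,
    style: str = "W",
) -> np.ndarray:
    """Draw y ~ Normal(X beta, sigma2 * D^{-1/2} (I - lam*M)^{-1} D^{-1/2}).

    ``M`` is the graph's CAR weight matrix in the requested ``style`` and
    ``D = diag(weights)``.  With ``lam = 0`` and unit weights this is an
    i.i.d. Gaussian draw.  Raises if ``lam`` leaves ``I - lam*M`` outside its
    positive-definite interval, naming the admissible bounds.
    """
    n = graph.n
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise ValueError("X row count must equal the number of graph nodes")
    beta = np.asarray(beta, dtype=float)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (n,))
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    M = graph.car_matrix(style)
    eig = graph.car_eigenvalues(style)
    lo = -np.inf if eig.min() >= 0 else 1.0 / eig.min()
    hi = np.inf if eig.max() <= 0 else 1.0 / eig.max()
    if not lo < lam < hi:
        raise ValueError(
            f"lambda={lam} outside the positive-definite interval ({lo:.6g}, {hi:.6g})"
        )

    P = np.eye(n) - lam * M
    L = np.linalg.cholesky(P)  # P = L L^T
    rng = np.random.default_rng(seed)
    zdraw = rng.standard_normal(n)
    u = np.linalg.solve(L.T, zdraw)  # cov(u) = P^{-1}
    return X @ beta + np.sqrt(sigma2) * u / np.sqrt(weights)
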
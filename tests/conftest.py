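import numpy as np
import pytest

from betascape import (
    GeoTransform,
    PresenceStack,
    ScenarioConfig,
    apply_mask,
    build_grid,
    generate_landscape,
    generate_species,
)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        seed=7,
        extent=(-2.0, 0.0, 2.0, 2.0),
        pixel_size=0.05,
        n_species=25,
        niche_breadth=1.0,
        surface_smoothness=1.2,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_stack(small_config, small_landscape):
    return generate_species(small_config, small_landscape)


def make_cellset(shape, scale=1.0, pixel_size=None, lon_min=0.0, mask=None):
    """CellSet over a raster of ``shape`` whose extent starts at (lon_min, 0)."""
    nrow, ncol = shape
    if pixel_size is None:
        pixel_size = 1.0
    tr = GeoTransform(lon_min, nrow * pixel_size, pixel_size)
    extent = (lon_min, 0.0, lon_min + ncol * pixel_size, nrow * pixel_size)
    grid = build_grid(extent, scale)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return apply_mask(grid, mask, tr), tr


def make_stack(occupancy, taxon="toy", pixel_size=1.0):
    """PresenceStack from an (n_species, nrow, ncol) binary array."""
    occ = np.asarray(occupancy, dtype=np.uint8)
    nrow = occ.shape[1]
    tr = GeoTransform(0.0, nrow * pixel_size, pixel_size)
    ids = [f"sp{i}" for i in range(occ.shape[0])]
    return PresenceStack(taxon=taxon, species_ids=ids, occupancy=occ, transform=tr)
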
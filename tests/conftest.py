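import numpy as np
import pytest

from lfhsi.camera_model import FilterBank, LensletGeometry, SensorConfig, xenon_spd
from lfhsi.phantom_scenes import (
    ReflectanceScene,
    make_tile_palette,
    make_wavelength_grid,
    render_checker_scene,
)


@pytest.fixture(scope="session")
def band_grid():
    """Default 155-band spectral axis, 350-1000 nm."""
    return make_wavelength_grid(350.0, 1000.0, 155)


@pytest.fixture(scope="session")
def default_bank():
    return FilterBank.default()


@pytest.fixture(scope="session")
def geometry():
    return LensletGeometry()


@pytest.fixture(scope="session")
def quiet_sensor():
    return SensorConfig(shot_noise=False, read_noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def smooth_illuminant(band_grid):
    return xenon_spd(band_grid, ripple_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def rippled_illuminant(band_grid):
    return xenon_spd(band_grid, ripple_amplitude=0.5, seed=3)


@pytest.fixture(scope="session")
def small_checker_scene(band_grid):
    """4x6 chart at 8 px tiles: 32x48 px, 24 labels."""
    palette = make_tile_palette(18, 6, seed=7, grid=band_grid)
    return render_checker_scene(palette, 4, 6, tile_px=8)


def flat_scene(grid, level=0.5, shape=(12, 12), depth_cm=25.0):
    """Spatially flat scene at a constant reflectance level."""
    cube = np.full(shape + (grid.count,), float(level))
    return ReflectanceScene(
        cube=cube,
        wavelengths=grid,
        depth_map=np.full(shape, depth_cm),
        truth_mask=np.zeros(shape, dtype=int),
        palette={},
    )


def spectrum_scene(grid, reflectance, shape=(12, 12), depth_cm=25.0):
    """Spatially flat scene carrying one given spectrum everywhere."""
    cube = np.broadcast_to(
        np.asarray(reflectance, float), shape + (grid.count,)
    ).copy()
    return ReflectanceScene(
        cube=cube,
        wavelengths=grid,
        depth_map=np.full(shape, depth_cm),
        truth_mask=np.zeros(shape, dtype=int),
        palette={},
    )
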
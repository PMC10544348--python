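"""End-to-end convenience drivers: simulate -> reconstruct -> validate.

These wire the stage modules together exactly the way the validation
experiments do: image a known 24-patch chart, reconstruct the hypercube
through white/dark referencing and regularised spectral inversion, sample
each tile's central region, and score the mean tile spectra against the
ground-truth palette with CIEDE2000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera_model import simulate_capture, xenon_spd
from .config import PipelineConfig
from .phantom_scenes import (
    ReflectanceScene,
    ReflectanceSpectrum,
    make_tile_palette,
    make_wavelength_grid,
    render_checker_scene,
)
from .reconstruction import Hypercube, reconstruct
from .spectra_analysis import (
    DeltaEReport,
    LabelMask,
    RoiSpectraTable,
    extract_roi_spectra,
    reject_saturated,
    tile_center_regions,
    validate_against_reference,
)

__all__ = ["CheckerRun", "simulate_scene_capture", "run_checker_validation"]


@dataclass
class CheckerRun:
    """Products of one chart-validation run."""

    scene: ReflectanceScene
    cube: Hypercube
    table: RoiSpectraTable
    report: DeltaEReport


def simulate_scene_capture(config: PipelineConfig, seed: int | None = None):
    """Build the configured scene and capture it; returns (scene, capture)."""
    seed = config.seed if seed is None else seed
    grid = make_wavelength_grid(
        config.band_start, config.band_stop, config.scene_bands
    )
    if config.scene_kind == "checker":
        palette = make_tile_palette(
            config.n_chromatic, config.n_neutral, seed=seed, grid=grid
        )
        scene = render_checker_scene(
            palette, config.checker_rows, config.checker_cols,
            config.tile_px, depth_cm=config.depth_cm,
        )
    elif config.scene_kind == "tissue":
        from .phantom_scenes import render_tissue_scene

        palette = make_tile_palette(2, 0, seed=seed, grid=grid)
        scene = render_tissue_scene(
            palette, blob_count=config.blob_count,
            blood_fraction=config.blood_fraction, seed=seed,
            depth_cm=config.depth_cm,
        )
    else:
        raise ValueError(f"unknown scene kind {config.scene_kind!r}")
    illum = xenon_spd(grid, ripple_amplitude=config.ripple_amplitude, seed=seed)
    capture = simulate_capture(
        scene, illum, config.bank(), config.geometry(),
        config.sensor(seed=seed), rho_ref=config.rho_ref, noise=config.noise,
    )
    return scene, capture


def run_checker_validation(
    config: PipelineConfig | None = None, seed: int | None = None
) -> CheckerRun:
    """Full chart fidelity run; report.max_delta_e is the headline number."""
    config = config or PipelineConfig()
    scene, capture = simulate_scene_capture(config, seed=seed)
    cube = reconstruct(capture, config.reconstruction())
    valid = reject_saturated(capture, config.saturation_fraction)
    mask = tile_center_regions(
        LabelMask(scene.truth_mask), config.center_fraction
    )
    table = extract_roi_spectra(cube, mask, valid)
    reference = {
        lab: ReflectanceSpectrum(scene.wavelengths, np.clip(r, 0.0, 1.0))
        for lab, r in scene.palette.items()
    }
    report = validate_against_reference(table, reference)
    return CheckerRun(scene=scene, cube=cube, table=table, report=report)
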
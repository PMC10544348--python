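"""Tissue-phantom ROI spectroscopy and the blood-tint red shift.

Simulates two-class tissue-like scenes (background "cortex" plus
"vessel" blobs), runs the full capture -> reconstruct chain with default
noise, extracts per-structure mean +/- std spectra through the truth
mask (saturated pixels rejected), L1-normalises them, and sweeps the
blood-contamination fraction to show that surface blood monotonically
shifts the normalised spectrum toward the red: the ratio of summed
reflectance in 620-700 nm to 500-580 nm grows with the contamination
level.

Outputs: results/tissue_spectra_l1.csv, results/blood_tint_ratios.csv.

Run: python analysis/03_tissue_roi_spectra.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lfhsi.camera_model import (
    FilterBank,
    LensletGeometry,
    SensorConfig,
    simulate_capture,
    xenon_spd,
)
from lfhsi.phantom_scenes import make_tile_palette, make_wavelength_grid, render_tissue_scene
from lfhsi.reconstruction import reconstruct
from lfhsi.spectra_analysis import (
    LabelMask,
    extract_roi_spectra,
    l1_normalize,
    reject_saturated,
)

OUT = Path("results")
LEGEND = {1: "cortex", 2: "vessel"}


def run_once(blood_fraction: float, seed: int = 0):
    grid = make_wavelength_grid(350, 1000, 155)
    classes = make_tile_palette(2, 0, seed=21, grid=grid)
    scene = render_tissue_scene(
        classes, blob_count=5, blood_fraction=blood_fraction, seed=seed,
        shape=(64, 64),
    )
    capture = simulate_capture(
        scene, xenon_spd(grid, ripple_amplitude=0.3, seed=seed),
        FilterBank.default(), LensletGeometry(), SensorConfig(seed=seed),
    )
    cube = reconstruct(capture)
    table = extract_roi_spectra(
        cube, LabelMask(scene.truth_mask, legend=LEGEND),
        reject_saturated(capture),
    )
    return cube, table


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cube, table = run_once(blood_fraction=0.0)
    norm = table.l1_normalized()
    norm.to_csv(OUT / "tissue_spectra_l1.csv")
    for i, name in enumerate(norm.names):
        print(
            f"{name}: {norm.n_pixels_valid[i]} valid px, "
            f"L1 mean spectrum sums to {np.nansum(norm.mean[i]):.6f}"
        )

    lam = cube.wavelengths.values
    red = (lam >= 620) & (lam <= 700)
    green = (lam >= 500) & (lam <= 580)
    rows = []
    for f in (0.0, 0.25, 0.5, 0.75):
        _, t = run_once(blood_fraction=f)
        vessel = l1_normalize(np.clip(t.mean[1], 1e-9, None))
        rows.append(
            {"blood_fraction": f,
             "red_green_ratio": vessel[red].sum() / vessel[green].sum()}
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "blood_tint_ratios.csv", index=False)
    monotone = (df["red_green_ratio"].diff().dropna() > 0).all()
    print(
        "blood-tint sweep (vessel class): red/green ratio "
        + " -> ".join(f"{v:.2f}" for v in df["red_green_ratio"])
        + ("  [strictly increasing]" if monotone else "  [NOT monotone]")
    )


if __name__ == "__main__":
    main()
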
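"""Simulate the chart-validation acquisition.

Builds the 24-patch synthetic reference chart (18 chromatic + 6 neutral
tiles on the default 155-band grid), images it with the simulated
66-lenslet camera under a rippled xenon-like illuminant — once noiseless
and once with default shot + read noise — and stores the scene, truth
mask, palette and raw capture sets under results/checker/.

Run: python analysis/01_simulate_checker.py
"""

import sys
from pathlib import Path

import numpy as np

from lfhsi import envi_io
from lfhsi.config import PipelineConfig
from lfhsi.phantom_scenes import ReflectanceSpectrum, save_palette_csv
from lfhsi.pipeline import simulate_scene_capture

OUT = Path("results/checker")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for tag, noise in (("noiseless", False), ("noisy", True)):
        cfg = PipelineConfig(noise=noise, seed=seed)
        scene, capture = simulate_scene_capture(cfg)
        envi_io.write_capture(capture, OUT / f"capture_{tag}")
        cfg.save(OUT / f"config_{tag}.yaml")
        if tag == "noiseless":
            envi_io.write_envi(
                scene.cube, OUT / "scene.hdr",
                wavelengths=scene.wavelengths.values,
            )
            envi_io.write_mask_png(scene.truth_mask, OUT / "truth_mask.png")
            save_palette_csv(
                {
                    lab: ReflectanceSpectrum(scene.wavelengths, np.clip(r, 0, 1))
                    for lab, r in scene.palette.items()
                },
                OUT / "palette.csv",
            )
        occupancy = capture.sample.max() / capture.sensor.full_scale_dn
        print(
            f"{tag:>9}: {capture.n_lenslets} lenslet sub-images of "
            f"{capture.sample.shape[1]}x{capture.sample.shape[2]} px, "
            f"peak DN at {100 * occupancy:.0f}% of full scale"
        )
    print(f"wrote scene, palette and capture sets to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
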
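"""Why NIR spectra look spiky without a matched white reference.

Xenon-arc surgical illuminants carry narrow emission ripple above
~750 nm. This experiment reconstructs the same smooth-spectrum scene
from a rippled-illuminant capture twice: once with the matched white
reference taken under the same illuminant (the intended workflow), and
once with a mismatched white reference taken under a smooth illuminant.
With the matched reference the 750-900 nm region reconstructs cleanly;
with the mismatched one the source ripple leaks into the recovered
spectra as spurious NIR peaks.

Output: results/ripple_cancellation.csv.

Run: python analysis/04_ripple_cancellation.py
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
from lfhsi.phantom_scenes import ReflectanceScene, make_wavelength_grid
from lfhsi.reconstruction import CaptureSet, reconstruct

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = make_wavelength_grid(350, 1000, 326)  # ~2 nm: resolves the ripple
    lam = grid.values
    r = 0.2 + 0.5 * np.exp(-0.5 * ((lam - 650) / 40.0) ** 2)
    scene = ReflectanceScene(
        cube=np.broadcast_to(r, (16, 16, lam.size)).copy(),
        wavelengths=grid,
        depth_map=np.full((16, 16), 25.0),
        truth_mask=np.zeros((16, 16), int),
        palette={},
    )
    sensor = SensorConfig(shot_noise=False, read_noise_sigma=0.0, seed=0)
    bank, geom = FilterBank.default(), LensletGeometry()
    rippled = xenon_spd(grid, ripple_amplitude=0.5, seed=3)
    smooth = xenon_spd(grid, ripple_amplitude=0.0)

    cap_matched = simulate_capture(scene, rippled, bank, geom, sensor,
                                   noise=False)
    cap_smooth_ref = simulate_capture(scene, smooth, bank, geom, sensor,
                                      noise=False)
    # mismatched: rippled sample stack, smooth-illuminant white reference
    cap_mismatched = CaptureSet(
        sample=cap_matched.sample, white=cap_smooth_ref.white,
        dark=cap_matched.dark, geometry=cap_matched.geometry,
        bank=bank, rho_ref=cap_matched.rho_ref, sensor=sensor,
        provenance={"white_reference": "mismatched illuminant"},
    )

    rows = []
    for tag, cap in (("matched", cap_matched), ("mismatched", cap_mismatched)):
        cube = reconstruct(cap)
        truth = np.interp(cube.wavelengths.values, lam, r)
        nir = (cube.wavelengths.values >= 750) & (cube.wavelengths.values <= 900)
        err = np.abs(cube.values[..., nir] - truth[nir]).max()
        rows.append({"white_reference": tag, "max_abs_error_750_900nm": err})
        print(f"{tag:>11} white reference: max |error| in 750-900 nm = {err:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "ripple_cancellation.csv", index=False)
    ratio = rows[1]["max_abs_error_750_900nm"] / rows[0]["max_abs_error_750_900nm"]
    print(
        f"a matched white reference suppresses the illuminant ripple "
        f"{ratio:.0f}-fold in this configuration"
    )


if __name__ == "__main__":
    main()
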
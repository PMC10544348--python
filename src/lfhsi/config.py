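"""Pipeline configuration and run logging.

One serialisable config object covers every stage (scene, illuminant,
filter bank, lenslet geometry, sensor, reconstruction, colorimetry); a
run's config and seed are embedded in output provenance so any product
can be regenerated. The run log is an append-only, machine-parseable
record of stage events (clip counts, residual disparities, warnings).
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .camera_model import FilterBank, LensletGeometry, SensorConfig
from .reconstruction import ReconstructionConfig

__all__ = ["PipelineConfig", "RunLog"]


@dataclass
class PipelineConfig:
    """Everything a full simulate -> reconstruct -> validate run needs."""

    # scene
    scene_kind: str = "checker"  # "checker" | "tissue"
    checker_rows: int = 4
    checker_cols: int = 6
    tile_px: int = 24
    n_chromatic: int = 18
    n_neutral: int = 6
    depth_cm: float = 25.0
    scene_bands: int = 155
    blob_count: int = 6
    blood_fraction: float = 0.0
    # illuminant
    ripple_amplitude: float = 0.3
    # filter bank
    n_lenslets: int = 66
    band_start: float = 350.0
    band_stop: float = 1000.0
    fwhm_nm: float = 10.0
    # lenslet geometry
    grid_rows: int = 6
    grid_cols: int = 11
    pitch_mm: float = 4.0
    disparity_scale: float = 3.354
    # sensor
    bit_depth: int = 12
    exposure_gain: float | None = None
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    rho_ref: float = 0.95
    noise: bool = True
    # reconstruction
    ridge: float = 1e-3
    smooth_order: int = 2
    nonneg: bool = False
    epsilon_dn: float = 1.0
    n_bands: int = 155
    max_shift: int = 4
    # colorimetry / analysis
    center_fraction: float = 0.5
    saturation_fraction: float = 1.0
    # randomness
    seed: int = 0

    def bank(self) -> FilterBank:
        return FilterBank.default(
            self.n_lenslets, self.band_start, self.band_stop, self.fwhm_nm
        )

    def geometry(self) -> LensletGeometry:
        return LensletGeometry(
            grid_rows=self.grid_rows, grid_cols=self.grid_cols,
            pitch_mm=self.pitch_mm, disparity_scale=self.disparity_scale,
        )

    def sensor(self, seed: int | None = None) -> SensorConfig:
        return SensorConfig(
            bit_depth=self.bit_depth, exposure_gain=self.exposure_gain,
            shot_noise=self.shot_noise, read_noise_sigma=self.read_noise_sigma,
            seed=self.seed if seed is None else seed,
        )

    def reconstruction(self) -> ReconstructionConfig:
        return ReconstructionConfig(
            ridge=self.ridge, smooth_order=self.smooth_order,
            nonneg=self.nonneg, epsilon_dn=self.epsilon_dn,
            n_bands=self.n_bands, band_start=self.band_start,
            band_stop=self.band_stop, max_shift=self.max_shift,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


class RunLog:
    """Append-only, tab-separated stage log (timestamp, stage, key, value)."""

    def __init__(self, path=None) -> None:
        self.path = Path(path) if path else None
        self.records: list[tuple[str, str, str, str]] = []

    def record(self, stage: str, key: str, value) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        rec = (stamp, stage, key, str(value))
        self.records.append(rec)
        if self.path:
            with open(self.path, "a") as f:
                f.write("\t".join(rec) + "\n")

    def __len__(self) -> int:
        return len(self.records)
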
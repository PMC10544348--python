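"""Forward model of a lenslet-array snapshot HSI camera.

A 66-lenslet lightfield camera sees the same scene through 66 narrow
Gaussian band-pass filters (FWHM 10 nm, centres spanning 350-1000 nm),
each lenslet from a slightly different viewpoint. A capture therefore
consists of 66 band-integrated sub-images with per-lenslet parallax,
digitised by a 12-bit sensor. This module simulates sample, white-reference
and dark-reference stacks, plus the small frame-geometry and optics
utilities of the acquisition chain (2x2 binning, frame memory footprint,
Brewster mount angle for the drape window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom_scenes import ReflectanceScene, WavelengthGrid, make_wavelength_grid

__all__ = [
    "Illuminant",
    "FilterBank",
    "LensletGeometry",
    "SensorConfig",
    "CaptureSet",
    "gaussian_filter_curve",
    "measure_fwhm",
    "xenon_spd",
    "simulate_capture",
    "bin2x2",
    "frame_memory_bytes",
    "brewster_angle",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_filter_curve(
    center: float, fwhm: float, grid: WavelengthGrid | np.ndarray
) -> np.ndarray:
    """Unit-peak Gaussian transmission with the given FWHM, sampled on `grid`."""
    lam = grid.values if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    if not lam[0] <= center <= lam[-1]:
        raise ValueError(f"filter centre {center} nm outside grid [{lam[0]}, {lam[-1]}]")
    sigma = fwhm * FWHM_TO_SIGMA
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def measure_fwhm(center: float, fwhm: float, resolution: float = 0.1) -> float:
    """Numerically measure a filter's FWHM by half-maximum crossing interpolation.

    Samples the curve on a `resolution`-nm grid around the centre and
    linearly interpolates the two 0.5 crossings; independent of the
    closed-form sigma relation, so it checks the generated curves.
    """
    span = 5.0 * fwhm
    lam = np.arange(center - span, center + span + resolution / 2, resolution)
    t = np.exp(-0.5 * ((lam - center) / (fwhm * FWHM_TO_SIGMA)) ** 2)
    above = t >= 0.5
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]

    def _cross(ia: int, ib: int) -> float:
        ta, tb = t[ia], t[ib]
        return lam[ia] + (0.5 - ta) / (tb - ta) * (lam[ib] - lam[ia])

    left = _cross(i0 - 1, i0)
    right = _cross(i1, i1 + 1)
    return float(right - left)


@dataclass(frozen=True)
class FilterBank:
    """The per-lenslet band-pass filters: Gaussian, equal spacing, FWHM 10 nm.

    The commercial device's exact band responses are proprietary; evenly
    spaced unit-peak Gaussians over 350-1000 nm are the explicit model here.
    """

    centers: np.ndarray
    fwhm: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        if self.centers.ndim != 1 or self.centers.size < 1:
            raise ValueError("need at least one filter centre")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    @classmethod
    def default(
        cls, n_lenslets: int = 66, start: float = 350.0, stop: float = 1000.0,
        fwhm: float = 10.0,
    ) -> "FilterBank":
        return cls(centers=np.linspace(start, stop, n_lenslets), fwhm=fwhm)

    @property
    def n_lenslets(self) -> int:
        return int(self.centers.size)

    def transmission_on(self, grid: WavelengthGrid | np.ndarray) -> np.ndarray:
        """n_lenslets x len(grid) matrix of transmission curves."""
        return np.stack(
            [gaussian_filter_curve(c, self.fwhm, grid) for c in self.centers]
        )


@dataclass(frozen=True)
class LensletGeometry:
    """Lenslet layout and the parallax it induces.

    Baselines sit on a centred regular lattice (default 6x11 = 66 lenslets
    at 4 mm pitch). A scene point at depth Z cm appears shifted by
    delta_i = disparity_scale * b_i / Z pixels in lenslet i, where b_i is
    its 2-vector baseline in mm. The default disparity_scale gives a
    maximum disparity of ~3 px at 25 cm.
    """

    grid_rows: int = 6
    grid_cols: int = 11
    pitch_mm: float = 4.0
    disparity_scale: float = 3.354  # px*cm/mm
    depth_cm: float | None = None

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("lenslet grid dims must be positive")

    @property
    def n_lenslets(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def baselines(self) -> np.ndarray:
        """n_lenslets x 2 (row, col) offsets in mm, symmetric about centre."""
        ry = (np.arange(self.grid_rows) - (self.grid_rows - 1) / 2.0) * self.pitch_mm
        rx = (np.arange(self.grid_cols) - (self.grid_cols - 1) / 2.0) * self.pitch_mm
        by, bx = np.meshgrid(ry, rx, indexing="ij")
        return np.stack([by.ravel(), bx.ravel()], axis=1)

    def disparities(self, depth_cm: float) -> np.ndarray:
        """Per-lenslet (dy, dx) pixel shift at the given depth."""
        if depth_cm <= 0:
            raise ValueError("depth must be positive")
        return self.disparity_scale * self.baselines / float(depth_cm)


@dataclass(frozen=True)
class SensorConfig:
    """12-bit monochrome sensor model (mono12 full scale 4095).

    exposure_gain converts band radiance to DN; None auto-exposes so the
    white reference peaks at 80% of full scale. Shot noise is Poisson on
    the expected DN; read noise is additive Gaussian in DN.
    """

    bit_depth: int = 12
    exposure_gain: float | None = None
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    seed: int = 0

    @property
    def full_scale_dn(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class Illuminant:
    """Relative spectral power of the surgical light source.

    Xenon-like: a broad smooth hump across 350-1000 nm, with narrow
    emission peaks confined to the ripple band (default 750-900 nm) —
    the structure that makes uncorrected NIR spectra look spiky and
    that white referencing must cancel.
    """

    wavelengths: WavelengthGrid
    spd: np.ndarray
    ripple_amplitude: float = 0.0
    ripple_band: tuple[float, float] = (750.0, 900.0)

    def __post_init__(self) -> None:
        self.spd = np.asarray(self.spd, dtype=float)
        if self.spd.shape != (len(self.wavelengths),):
            raise ValueError("spd length must match wavelength grid")
        if np.any(self.spd < 0):
            raise ValueError("spd must be non-negative")

    def sampled_on(self, grid: WavelengthGrid) -> np.ndarray:
        return np.interp(grid.values, self.wavelengths.values, self.spd)


def xenon_spd(
    grid: WavelengthGrid,
    ripple_amplitude: float = 0.3,
    seed: int = 0,
    n_peaks: int = 6,
    ripple_band: tuple[float, float] = (750.0, 900.0),
) -> Illuminant:
    """Xenon-arc-like illuminant: smooth visible hump + seeded NIR ripple.

    ripple_amplitude scales narrow (sigma 2-5 nm) additive peaks placed at
    seeded random positions inside ripple_band; 0 gives a perfectly smooth
    source. Strictly positive everywhere.
    """
    if not 0.0 <= ripple_amplitude < 1.0:
        raise ValueError("ripple_amplitude must lie in [0, 1)")
    lam = grid.values
    base = 0.25 + np.exp(-0.5 * ((lam - 580.0) / 230.0) ** 2)
    spd = base.copy()
    if ripple_amplitude > 0:
        rng = np.random.default_rng(seed)
        lo, hi = ripple_band
        for _ in range(n_peaks):
            c = rng.uniform(lo + 8.0, hi - 8.0)
            s = rng.uniform(2.0, 5.0)
            a = ripple_amplitude * rng.uniform(0.4, 1.0)
            spd = spd + a * base * np.exp(-0.5 * ((lam - c) / s) ** 2)
    return Illuminant(
        wavelengths=grid,
        spd=spd,
        ripple_amplitude=float(ripple_amplitude),
        ripple_band=ripple_band,
    )


@dataclass
class CaptureSet:
    """One raw acquisition: sample, white and dark lenslet stacks.

    Stacks are (n_lenslets, H, W) integer DN in [0, full_scale]. The
    white stack images a uniform reflector of reflectance rho_ref at the
    same depth; the dark stack is taken with the light path blocked.
    Geometry (with the true depth and disparity scale) and the filter
    bank travel with the data so reconstruction can undo the parallax.
    """

    sample: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    geometry: LensletGeometry
    bank: FilterBank
    rho_ref: float = 0.95
    sensor: SensorConfig = field(default_factory=SensorConfig)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.sample.shape, self.white.shape, self.dark.shape}
        if len(shapes) != 1:
            raise ValueError("sample/white/dark stacks must share one shape")
        fs = self.sensor.full_scale_dn
        for name in ("sample", "white", "dark"):
            stack = getattr(self, name)
            if stack.min() < 0 or stack.max() > fs:
                raise ValueError(f"{name} DN outside [0, {fs}]")

    @property
    def n_lenslets(self) -> int:
        return self.sample.shape[0]


def _digitise(expected: np.ndarray, sensor: SensorConfig, rng) -> np.ndarray:
    fs = sensor.full_scale_dn
    vals = expected
    if rng is not None:
        if sensor.shot_noise:
            vals = rng.poisson(np.maximum(vals, 0.0)).astype(float)
        if sensor.read_noise_sigma > 0:
            vals = vals + rng.normal(0.0, sensor.read_noise_sigma, vals.shape)
    return np.clip(np.rint(vals), 0, fs).astype(np.uint16)


def simulate_capture(
    scene: ReflectanceScene,
    illuminant: Illuminant,
    bank: FilterBank,
    geometry: LensletGeometry,
    sensor: SensorConfig,
    rho_ref: float = 0.95,
    noise: bool = True,
) -> CaptureSet:
    """Forward-simulate sample, white and dark stacks for a scene.

    Per lenslet i the band radiance is m_i(x) = sum_lambda L * F_i * r * dl
    on the scene's grid; the sub-image is then shifted by the lenslet's
    disparity at the scene depth (bilinear), digitised to 12-bit DN with
    optional shot + read noise. The white stack views a uniform reflector
    rho_ref at the same depth (flat field, so parallax is immaterial);
    the dark stack has zero expected signal.
    """
    lam = scene.wavelengths
    lo, hi = bank.centers.min(), bank.centers.max()
    if lo < lam.start or hi > lam.stop:
        raise ValueError(
            f"filter centres [{lo}, {hi}] exceed scene grid [{lam.start}, {lam.stop}]"
        )
    L = illuminant.sampled_on(lam)
    F = bank.transmission_on(lam)  # (n, B)
    weights = F * L * lam.step  # (n, B)

    depth = float(np.median(scene.depth_map))
    geometry = LensletGeometry(
        grid_rows=geometry.grid_rows,
        grid_cols=geometry.grid_cols,
        pitch_mm=geometry.pitch_mm,
        disparity_scale=geometry.disparity_scale,
        depth_cm=depth,
    )
    if geometry.n_lenslets != bank.n_lenslets:
        raise ValueError("geometry lenslet count must match filter bank")
    disps = geometry.disparities(depth)

    radiance = np.tensordot(scene.cube, weights, axes=([2], [1]))  # (H, W, n)
    white_levels = float(rho_ref) * weights.sum(axis=1)  # (n,)

    gain = sensor.exposure_gain
    if gain is None:
        gain = 0.8 * sensor.full_scale_dn / white_levels.max()

    h, w = scene.cube.shape[:2]
    n = bank.n_lenslets
    exp_sample = np.empty((n, h, w))
    for i in range(n):
        exp_sample[i] = ndimage.shift(
            gain * radiance[:, :, i], shift=disps[i], order=1, mode="nearest"
        )
    exp_white = np.broadcast_to(
        (gain * white_levels)[:, None, None], (n, h, w)
    ).copy()
    exp_dark = np.zeros((n, h, w))

    rng = np.random.default_rng(sensor.seed) if noise else None
    return CaptureSet(
        sample=_digitise(exp_sample, sensor, rng),
        white=_digitise(exp_white, sensor, rng),
        dark=_digitise(exp_dark, sensor, rng),
        geometry=geometry,
        bank=bank,
        rho_ref=float(rho_ref),
        sensor=sensor,
        provenance={
            "gain": float(gain),
            "depth_cm": depth,
            "noise": bool(noise),
            "seed": int(sensor.seed),
            "illuminant_ripple": float(illuminant.ripple_amplitude),
        },
    )


def bin2x2(frame: np.ndarray) -> np.ndarray:
    """Viewfinder-mode 2x2 binning: each output pixel is the rounded block mean."""
    frame = np.asarray(frame)
    h, w = frame.shape
    if h % 2 or w % 2:
        raise ValueError("frame dims must be even for 2x2 binning")
    blocks = frame.reshape(h // 2, 2, w // 2, 2).astype(float).mean(axis=(1, 3))
    return np.rint(blocks).astype(frame.dtype)


def frame_memory_bytes(width: int, height: int, bit_depth: int) -> int:
    """Memory of one packed frame: width*height*bit_depth/8, no padding."""
    if width <= 0 or height <= 0 or bit_depth <= 0:
        raise ValueError("all frame dimensions must be positive")
    if bit_depth % 4:
        raise ValueError("bit depth must be a multiple of 4 for packing")
    return width * height * bit_depth // 8


def brewster_angle(relative_index: float) -> float:
    """Incidence angle (degrees) of zero p-polarised reflection: arctan(n)."""
    if relative_index <= 0:
        raise ValueError("relative refractive index must be positive")
    return float(np.degrees(np.arctan(relative_index)))
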
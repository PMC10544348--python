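"""Synthetic reflectance scenes with known ground truth.

Desk-scale stand-ins for the physical targets used to validate an
intra-operative lightfield HSI system: a ColorChecker-like tiled chart
(colorimetric fidelity) and a two-class tissue-like phantom (ROI
spectroscopy), both defined as per-pixel diffuse reflectance r(x, y, λ)
on an explicit wavelength grid, with a depth map and an integer
ground-truth label mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ReflectanceSpectrum",
    "ReflectanceScene",
    "make_wavelength_grid",
    "make_tile_palette",
    "render_checker_scene",
    "render_tissue_scene",
    "blood_spectrum",
    "load_palette_csv",
    "save_palette_csv",
]

_GRID_MIN_NM = 300.0
_GRID_MAX_NM = 1100.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, strictly increasing spectral axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 values")
        d = np.diff(v)
        if not np.all(d > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ValueError("wavelength grid must be uniform to 1e-9 nm")
        if v[0] < _GRID_MIN_NM or v[-1] > _GRID_MAX_NM:
            raise ValueError(
                f"wavelengths must lie in [{_GRID_MIN_NM:g}, {_GRID_MAX_NM:g}] nm"
            )

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def count(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.count


def make_wavelength_grid(start: float, stop: float, count: int) -> WavelengthGrid:
    """Uniform grid of `count` wavelengths from `start` to `stop` nm inclusive."""
    if count < 2:
        raise ValueError("count must be >= 2")
    if not stop > start:
        raise ValueError("stop must exceed start")
    return WavelengthGrid(np.linspace(float(start), float(stop), int(count)))


#: Default spectral axis: 155 bands spanning 350-1000 nm.
def default_band_grid() -> WavelengthGrid:
    return make_wavelength_grid(350.0, 1000.0, 155)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Diffuse reflectance fractions on a wavelength grid."""

    wavelengths: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", r)
        if r.shape != (len(self.wavelengths),):
            raise ValueError("reflectance length must match wavelength grid")
        if r.min() < 0.0 or r.max() > 1.0:
            raise ValueError("reflectance must lie in [0, 1]")


@dataclass
class ReflectanceScene:
    """Ground-truth spatial-spectral phantom.

    cube:       H x W x B per-pixel reflectance in [0, 1]
    wavelengths: the B-point spectral axis
    depth_map:  H x W working distance in cm (strictly positive)
    truth_mask: H x W non-negative integer labels (0 = background/unlabelled)
    palette:    label -> B-vector ground-truth spectrum for that label
    """

    cube: np.ndarray
    wavelengths: WavelengthGrid
    depth_map: np.ndarray
    truth_mask: np.ndarray
    palette: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.depth_map = np.asarray(self.depth_map, dtype=float)
        self.truth_mask = np.asarray(self.truth_mask)
        if self.cube.ndim != 3 or self.cube.shape[2] != len(self.wavelengths):
            raise ValueError("cube must be H x W x B with B matching the grid")
        if self.cube.min() < 0.0 or self.cube.max() > 1.0:
            raise ValueError("scene reflectance must lie in [0, 1]")
        if self.depth_map.shape != self.cube.shape[:2]:
            raise ValueError("depth map shape must match the cube spatially")
        if np.any(self.depth_map <= 0):
            raise ValueError("depths must be strictly positive")
        if self.truth_mask.shape != self.cube.shape[:2]:
            raise ValueError("truth mask shape must match the cube spatially")
        if self.truth_mask.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.truth_mask).tolist()) - {0}
        missing = present - set(self.palette)
        if missing:
            raise ValueError(f"labels without palette entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape


def make_tile_palette(
    n_chromatic: int,
    n_neutral: int,
    seed: int,
    grid: WavelengthGrid | None = None,
) -> dict[int, ReflectanceSpectrum]:
    """Parametric stand-in for a 24-patch reference chart.

    Chromatic patches are smooth mixtures of 1-3 Gaussian bumps on a low
    base level, clipped to [0.02, 0.95]; neutral patches are flat greys at
    evenly spaced levels. Deterministic for a fixed seed. Labels run
    1..n_chromatic+n_neutral, chromatic first.
    """
    if n_chromatic < 0 or n_neutral < 0:
        raise ValueError("patch counts must be non-negative")
    if grid is None:
        grid = default_band_grid()
    rng = np.random.default_rng(seed)
    lam = grid.values
    palette: dict[int, ReflectanceSpectrum] = {}
    label = 1
    for _ in range(n_chromatic):
        r = np.full_like(lam, rng.uniform(0.03, 0.25))
        for _ in range(rng.integers(1, 4)):
            center = rng.uniform(380.0, 950.0)
            sigma = rng.uniform(30.0, 90.0)
            amp = rng.uniform(0.15, 0.7)
            r = r + amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
        r = np.clip(r, 0.02, 0.95)
        palette[label] = ReflectanceSpectrum(grid, r)
        label += 1
    if n_neutral:
        levels = np.linspace(0.05, 0.95, n_neutral + 2)[1:-1]
        for lev in levels:
            palette[label] = ReflectanceSpectrum(grid, np.full_like(lam, lev))
            label += 1
    return palette


def render_checker_scene(
    palette: dict[int, ReflectanceSpectrum],
    rows: int,
    cols: int,
    tile_px: int,
    depth_cm: float = 25.0,
) -> ReflectanceScene:
    """Tile the palette into a rows x cols chart of constant-spectrum patches.

    Labels fill 1..rows*cols in row-major order; the default working
    distance of 25 cm matches a desk acquisition of a reference chart.
    """
    if rows * cols != len(palette):
        raise ValueError(
            f"palette has {len(palette)} entries but layout needs {rows * cols}"
        )
    if tile_px < 4:
        raise ValueError("tile_px must be >= 4")
    grids = {s.wavelengths.count for s in palette.values()}
    if len(grids) != 1:
        raise ValueError("palette spectra must share one wavelength grid")
    grid = next(iter(palette.values())).wavelengths
    h, w = rows * tile_px, cols * tile_px
    cube = np.empty((h, w, grid.count), dtype=float)
    mask = np.zeros((h, w), dtype=np.int32)
    labels = sorted(palette)
    for idx, lab in enumerate(labels):
        r, c = divmod(idx, cols)
        sl = (slice(r * tile_px, (r + 1) * tile_px), slice(c * tile_px, (c + 1) * tile_px))
        cube[sl] = palette[lab].reflectance
        mask[sl] = lab
    return ReflectanceScene(
        cube=cube,
        wavelengths=grid,
        depth_map=np.full((h, w), float(depth_cm)),
        truth_mask=mask,
        palette={lab: palette[lab].reflectance.copy() for lab in labels},
    )


def blood_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Fixed blood-like tint: low reflectance 400-600 nm, high above 620 nm.

    A piecewise-smooth logistic step, illustrative rather than
    physiological; mixing any tissue spectrum toward it skews the result
    toward the red/NIR end, emulating surface blood contamination.
    """
    lam = grid.values
    return 0.02 + 0.53 / (1.0 + np.exp(-(lam - 610.0) / 5.0))


def render_tissue_scene(
    class_spectra: dict[int, ReflectanceSpectrum],
    blob_count: int = 6,
    blood_fraction: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    depth_cm: float = 25.0,
) -> ReflectanceScene:
    """Two-or-more-class tissue-like phantom with optional blood tint.

    The lowest label is the background; elliptical blobs of the other
    classes are placed at seeded random positions. Every pixel spectrum is
    then mixed as r' = (1 - f) * r + f * r_blood with f = blood_fraction,
    and the palette records the same mixed spectra so mask-driven
    extraction remains exact ground truth.
    """
    if len(class_spectra) < 2:
        raise ValueError("need at least two tissue classes")
    if not 0.0 <= blood_fraction <= 1.0:
        raise ValueError("blood_fraction must lie in [0, 1]")
    grids = {s.wavelengths.count for s in class_spectra.values()}
    if len(grids) != 1:
        raise ValueError("class spectra must share one wavelength grid")
    labels = sorted(class_spectra)
    grid = class_spectra[labels[0]].wavelengths
    h, w = shape
    rng = np.random.default_rng(seed)
    mask = np.full((h, w), labels[0], dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(blob_count):
        lab = labels[1 + rng.integers(0, len(labels) - 1)]
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ay, ax = rng.uniform(h / 16, h / 5), rng.uniform(w / 16, w / 5)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask[(u / ay) ** 2 + (v / ax) ** 2 <= 1.0] = lab
    f = float(blood_fraction)
    r_blood = blood_spectrum(grid)
    mixed = {
        lab: (1.0 - f) * class_spectra[lab].reflectance + f * r_blood
        for lab in labels
    }
    cube = np.empty((h, w, grid.count), dtype=float)
    for lab in labels:
        cube[mask == lab] = mixed[lab]
    return ReflectanceScene(
        cube=cube,
        wavelengths=grid,
        depth_map=np.full((h, w), float(depth_cm)),
        truth_mask=mask,
        palette=mixed,
    )


def save_palette_csv(palette: dict[int, ReflectanceSpectrum], path) -> None:
    """Write a palette as CSV columns (label, wavelength_nm, reflectance)."""
    import pandas as pd

    rows = []
    for lab in sorted(palette):
        s = palette[lab]
        for lam, r in zip(s.wavelengths.values, s.reflectance):
            rows.append((lab, lam, r))
    pd.DataFrame(rows, columns=["label", "wavelength_nm", "reflectance"]).to_csv(
        path, index=False
    )


def load_palette_csv(path) -> dict[int, ReflectanceSpectrum]:
    """Read user-supplied reference spectra (label, wavelength_nm, reflectance)."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"label", "wavelength_nm", "reflectance"}
    if not need.issubset(df.columns):
        raise ValueError(f"palette CSV must have columns {sorted(need)}")
    out: dict[int, ReflectanceSpectrum] = {}
    for lab, sub in df.groupby("label"):
        sub = sub.sort_values("wavelength_nm")
        grid = WavelengthGrid(sub["wavelength_nm"].to_numpy())
        out[int(lab)] = ReflectanceSpectrum(grid, sub["reflectance"].to_numpy())
    return out
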
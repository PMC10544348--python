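"""From raw lenslet captures to a calibrated reflectance hypercube.

Three stages mirror the acquisition chain in reverse:

1. reference correction - per pixel R = (S - D) / (W - D), which divides
   out the illuminant spectrum, filter throughput and sensor gain in one
   step (the point of taking an intra-operative white reference);
2. parallax registration - each lenslet views the scene from a different
   baseline, so its sub-image is shifted back onto a common pixel frame,
   either from known geometry or by cross-correlation;
3. spectral inversion - 66 band-integrated measurements per pixel are
   inverted to a 155-band spectrum. The 66 -> 155 oversampling is
   under-determined, so the solver is Tikhonov-regularised least squares
   with a second-difference smoothness penalty; the vendor's own
   algorithm is undisclosed and this is an explicit reimplementation
   choice, not a reproduction of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import cho_factor, cho_solve

from .camera_model import CaptureSet, FilterBank, LensletGeometry
from .phantom_scenes import WavelengthGrid, make_wavelength_grid

__all__ = [
    "CorrectedStack",
    "AlignedStack",
    "SystemMatrix",
    "Hypercube",
    "ReconstructionConfig",
    "correct_references",
    "register_known",
    "register_estimate",
    "build_system_matrix",
    "invert_spectra",
    "reconstruct",
]

CLIP_CEILING = 1.5  # super-unity reflectance kept visible for specular diagnostics


@dataclass
class CorrectedStack:
    """White/dark-referenced lenslet stack: values relative to the reference.

    values are fractions of the white reflector's signal (S = W maps to 1);
    valid flags pixels whose reference difference W - D fell below epsilon.
    """

    values: np.ndarray  # (n, H, W) float
    valid: np.ndarray  # (n, H, W) bool
    geometry: LensletGeometry | None = None


@dataclass
class AlignedStack:
    """Lenslet stack resampled onto the reference lenslet's pixel frame."""

    values: np.ndarray  # (n, H, W) float
    residual_disparity: np.ndarray  # (n, 2) px, reported not hidden
    applied_shift: np.ndarray | None = None  # (n, 2) px actually applied


@dataclass
class SystemMatrix:
    """Row-normalized filter responses on the output band grid.

    entries[i, k] = F_i(lambda_k) * dl, each row scaled so a flat unit
    reflectance maps to measurement 1 for every lenslet.
    """

    entries: np.ndarray  # (n_lenslets, n_bands)
    output_grid: WavelengthGrid


@dataclass
class Hypercube:
    """Reconstructed reflectance cube: H x W spatial x B spectral bands."""

    values: np.ndarray
    wavelengths: WavelengthGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.wavelengths):
            raise ValueError("hypercube must be H x W x B matching its grid")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ReconstructionConfig:
    """Tunables of the capture -> hypercube chain."""

    ridge: float = 1e-3
    smooth_order: int = 2
    nonneg: bool = False
    epsilon_dn: float = 1.0
    n_bands: int = 155
    band_start: float = 350.0
    band_stop: float = 1000.0
    max_shift: int = 4

    def output_grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.band_start, self.band_stop, self.n_bands)


def correct_references(
    sample: np.ndarray,
    white: np.ndarray,
    dark: np.ndarray,
    geometry: LensletGeometry | None = None,
    epsilon: float = 1.0,
) -> CorrectedStack:
    """Flat-field to reflectance fractions: R = (S - D) / max(W - D, epsilon).

    epsilon (in DN) guards dead reference pixels; where W - D < epsilon the
    pixel is flagged invalid rather than silently divided by a tiny number.
    """
    sample = np.asarray(sample, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if not sample.shape == white.shape == dark.shape:
        raise ValueError("sample, white and dark stacks must share one shape")
    denom = white - dark
    valid = denom >= epsilon
    values = (sample - dark) / np.maximum(denom, epsilon)
    return CorrectedStack(values=values, valid=valid, geometry=geometry)


def register_known(stack: CorrectedStack) -> AlignedStack:
    """Undo per-lenslet parallax from known geometry (subpixel bilinear).

    Each lenslet image is shifted by minus its disparity at the recorded
    depth; for planar scenes at that depth the residual disparity is ~0.
    """
    geom = stack.geometry
    if geom is None or geom.depth_cm is None:
        raise ValueError("register_known needs geometry with depth and scale")
    disps = geom.disparities(geom.depth_cm)
    out = np.empty_like(stack.values)
    for i in range(stack.values.shape[0]):
        out[i] = ndimage.shift(stack.values[i], -disps[i], order=1, mode="nearest")
    return AlignedStack(
        values=out,
        residual_disparity=np.zeros_like(disps),
        applied_shift=-disps,
    )


def register_estimate(
    stack: CorrectedStack,
    reference_lenslet: int | None = None,
    max_shift: int = 4,
) -> AlignedStack:
    """Estimate per-lenslet integer shifts by zero-mean normalized cross-correlation.

    Each lenslet is compared against the reference lenslet over all integer
    shifts within +/- max_shift; ties break toward the smaller shift. A
    texture-free (constant) lenslet falls back to zero shift with a warning.
    The subpixel remainder is unknown to this estimator, so the reported
    residual disparity is the half-pixel quantisation bound.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    vals = stack.values
    n = vals.shape[0]
    if reference_lenslet is None:
        reference_lenslet = n // 2
    ref = vals[reference_lenslet]
    ref_std = ref.std()

    shifts = np.zeros((n, 2))
    # candidates sorted by shift magnitude so ties resolve toward zero
    candidates = sorted(
        ((dy, dx) for dy in range(-max_shift, max_shift + 1)
         for dx in range(-max_shift, max_shift + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), abs(s[0]), abs(s[1])),
    )
    for i in range(n):
        img = vals[i]
        if img.std() == 0 or ref_std == 0:
            if i != reference_lenslet:
                warnings.warn(
                    f"lenslet {i}: constant image, falling back to zero shift",
                    stacklevel=2,
                )
            continue
        best, best_score = (0, 0), -np.inf
        for dy, dx in candidates:
            a = _overlap(ref, -dy, -dx)
            b = _overlap(img, dy, dx)
            za, zb = a - a.mean(), b - b.mean()
            denom = np.sqrt((za ** 2).sum() * (zb ** 2).sum())
            score = (za * zb).sum() / denom if denom > 0 else -np.inf
            if score > best_score + 1e-12:
                best, best_score = (dy, dx), score
        shifts[i] = best
    out = np.empty_like(vals)
    for i in range(n):
        out[i] = ndimage.shift(vals[i], -shifts[i], order=0, mode="nearest")
    return AlignedStack(
        values=out,
        residual_disparity=np.full((n, 2), 0.5),
        applied_shift=-shifts,
    )


def _overlap(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Crop `img` to the region that overlaps after an (dy, dx) shift."""
    h, w = img.shape
    y0, y1 = max(dy, 0), h + min(dy, 0)
    x0, x1 = max(dx, 0), w + min(dx, 0)
    return img[y0:y1, x0:x1]


def build_system_matrix(
    bank: FilterBank, output_grid: WavelengthGrid
) -> SystemMatrix:
    """Sample the filter bank onto the output band grid and row-normalize.

    A[i, k] = F_i(lambda_k) * dl, rows scaled to sum to 1 so that a flat
    unit reflectance maps to measurement 1 per lenslet. Every output band
    must receive support from at least one filter.
    """
    A = bank.transmission_on(output_grid) * output_grid.step
    row_sums = A.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = np.nonzero(row_sums <= 0)[0]
        raise ValueError(f"filters with no support on the output grid: {bad.tolist()}")
    A = A / row_sums[:, None]
    col = A.sum(axis=0)
    if np.any(col <= 1e-12):
        bad_bands = output_grid.values[col <= 1e-12]
        raise ValueError(
            f"output bands with zero filter support (nm): {bad_bands.tolist()}"
        )
    return SystemMatrix(entries=A, output_grid=output_grid)


def _second_difference(n: int, order: int) -> np.ndarray:
    D = np.eye(n)
    return np.diff(D, n=order, axis=0)


def invert_spectra(
    aligned: AlignedStack,
    A: SystemMatrix,
    ridge: float = 1e-3,
    smooth_order: int = 2,
    nonneg: bool = False,
    provenance: dict | None = None,
) -> Hypercube:
    """Per-pixel regularised inversion of the lenslet measurements.

    Solves min ||A r - m||^2 + ridge * ||D^k r||^2 with the k-th difference
    smoothness operator; the 66 -> 155 system is rank-deficient, so at
    ridge = 0 the solver refuses rather than return an arbitrary solution.
    Optional non-negativity by clipping-with-refit on offending pixels.
    Output clipped to [0, 1.5] with the clip count logged in provenance.
    """
    m = aligned.values
    n_lens, h, w = m.shape
    mat = A.entries
    if mat.shape[0] != n_lens:
        raise ValueError("aligned stack length must equal system-matrix rows")
    n_bands = mat.shape[1]
    if ridge <= 0:
        if n_lens < n_bands:
            raise ValueError(
                "normal equations are singular at ridge=0 for an oversampled "
                "band grid; set ridge > 0 to supply the smoothness prior"
            )
        ridge = 0.0
    D = _second_difference(n_bands, smooth_order)
    N = mat.T @ mat + ridge * (D.T @ D)
    try:
        factor = cho_factor(N)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("singular normal system; increase ridge") from exc

    M = m.reshape(n_lens, h * w)
    R = cho_solve(factor, mat.T @ M)  # (n_bands, n_px)

    refit = 0
    if nonneg:
        bad = np.nonzero((R < -1e-9).any(axis=0))[0]
        for j in bad:
            r = R[:, j]
            for _ in range(10):
                neg = r < 0
                if not neg.any():
                    break
                free = ~neg
                sub = mat[:, free]
                Df = D[:, free]
                Nf = sub.T @ sub + ridge * (Df.T @ Df)
                r_free = np.linalg.solve(Nf, sub.T @ M[:, j])
                r = np.zeros(n_bands)
                r[free] = r_free
            R[:, j] = np.maximum(r, 0.0)
        refit = int(bad.size)

    cube = R.T.reshape(h, w, n_bands)
    n_clip = int(np.count_nonzero((cube < 0) | (cube > CLIP_CEILING)))
    cube = np.clip(cube, 0.0, CLIP_CEILING)
    prov = dict(provenance or {})
    prov.update(
        ridge=float(ridge),
        smooth_order=int(smooth_order),
        nonneg=bool(nonneg),
        clipped_values=n_clip,
        nonneg_refit_pixels=refit,
    )
    return Hypercube(values=cube, wavelengths=A.output_grid, provenance=prov)


def reconstruct(
    capture: CaptureSet, config: ReconstructionConfig | None = None
) -> Hypercube:
    """Full chain: reference correction -> registration -> spectral inversion.

    Uses known-geometry registration when the capture records its depth and
    disparity scale, else falls back to cross-correlation estimation.
    Corrected values are rescaled by the white reflector's reflectance
    rho_ref so the hypercube is absolute reflectance rather than
    reflectance relative to the reference tile.
    """
    cfg = config or ReconstructionConfig()
    corrected = correct_references(
        capture.sample, capture.white, capture.dark,
        geometry=capture.geometry, epsilon=cfg.epsilon_dn,
    )
    geom = capture.geometry
    if geom is not None and geom.depth_cm is not None:
        aligned = register_known(corrected)
        reg_mode = "known"
    else:
        aligned = register_estimate(corrected, max_shift=cfg.max_shift)
        reg_mode = "estimated"
    aligned.values *= capture.rho_ref
    A = build_system_matrix(capture.bank, cfg.output_grid())
    prov = dict(capture.provenance)
    prov.update(
        registration=reg_mode,
        rho_ref=float(capture.rho_ref),
        epsilon_dn=float(cfg.epsilon_dn),
        invalid_reference_px=int(np.count_nonzero(~corrected.valid)),
    )
    return invert_spectra(
        aligned, A,
        ridge=cfg.ridge, smooth_order=cfg.smooth_order, nonneg=cfg.nonneg,
        provenance=prov,
    )
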
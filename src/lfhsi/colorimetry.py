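"""Spectra to CIEXYZ, sRGB and CIELAB, and the CIEDE2000 colour difference.

This is the validation mathematics for spectral fidelity: a reflectance
spectrum from the white-balanced hypercube is integrated against the CIE
1931 2-degree colour-matching functions under the equal-energy convention
(the illuminant is already divided out by white referencing), converted
to sRGB for display or to L*a*b* for perceptual comparison, and two
colours are compared with the full CIEDE2000 formula.

Because the hypercube is already white-balanced, its flat perfect
reflector is the scene's reference white; the XYZ integration therefore
applies a diagonal (von Kries style) scaling that maps that flat
reflector exactly onto the D65 white point, so neutral spectra render
neutral in sRGB and sit on the L* axis in CIELAB.

The CMF table shipped with the package is the Wyman-Sloan-Shirley
multi-Gaussian analytic fit to the CIE 1931 2-degree standard observer,
tabulated at 5 nm over 360-830 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ColorMatchingFunctions",
    "D65_WHITE",
    "spectrum_to_xyz",
    "xyz_to_srgb",
    "xyz_to_lab",
    "ciede2000",
    "srgb_render",
]

#: D65 white point tristimulus, Y normalised to 1 (sRGB's native white).
D65_WHITE = np.array([0.95047, 1.00000, 1.08883])

# IEC 61966-2-1 XYZ -> linear sRGB
_XYZ_TO_RGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


@dataclass(frozen=True)
class ColorMatchingFunctions:
    wavelengths: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, v)
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
        object.__setattr__(
            self, "wavelengths", np.asarray(self.wavelengths, float)
        )

    @classmethod
    def cie1931_2deg(cls) -> "ColorMatchingFunctions":
        """Load the packaged 5 nm standard-observer table."""
        path = resources.files("lfhsi.data") / "cie1931_cmf_5nm.csv"
        tab = np.genfromtxt(str(path), delimiter=",", names=True)
        return cls(
            wavelengths=tab["wavelength_nm"],
            xbar=tab["xbar"],
            ybar=tab["ybar"],
            zbar=tab["zbar"],
        )


_DEFAULT_CMF: ColorMatchingFunctions | None = None


def _default_cmf() -> ColorMatchingFunctions:
    global _DEFAULT_CMF
    if _DEFAULT_CMF is None:
        _DEFAULT_CMF = ColorMatchingFunctions.cie1931_2deg()
    return _DEFAULT_CMF


def spectrum_to_xyz(
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    cmf: ColorMatchingFunctions | None = None,
    adapt_white: np.ndarray | None = D65_WHITE,
) -> np.ndarray:
    """Integrate white-balanced reflectance against the CMFs.

    X = sum r(l) xbar(l) dl / N with N = sum ybar(l) dl over the overlap of
    the spectrum's range and the CMF support, so a flat perfect reflector
    maps to Y = 1 exactly. With the default adapt_white, a per-channel
    scaling then maps that flat reflector exactly onto the D65 white point
    (the reflectance is relative to the scene's white reference, so its
    flat spectrum IS the reference white). Pass adapt_white=None for the
    raw equal-energy integrals. `reflectance` may be any (..., L) stack;
    the spectrum is linearly resampled onto the CMF grid.
    """
    if cmf is None:
        cmf = _default_cmf()
    lam = np.asarray(wavelengths, float)
    r = np.asarray(reflectance, float)
    if r.shape[-1] != lam.size:
        raise ValueError("last axis of reflectance must match wavelengths")
    sel = (cmf.wavelengths >= lam[0]) & (cmf.wavelengths <= lam[-1])
    if not sel.any():
        raise ValueError(
            f"no spectral overlap: spectrum [{lam[0]}, {lam[-1]}] nm vs "
            f"CMF support [{cmf.wavelengths[0]}, {cmf.wavelengths[-1]}] nm"
        )
    grid = cmf.wavelengths[sel]
    flat = r.reshape(-1, lam.size)
    resampled = np.empty((flat.shape[0], grid.size))
    for i in range(flat.shape[0]):
        resampled[i] = np.interp(grid, lam, flat[i])
    norm = cmf.ybar[sel].sum()
    xyz = np.stack(
        [
            resampled @ cmf.xbar[sel] / norm,
            resampled @ cmf.ybar[sel] / norm,
            resampled @ cmf.zbar[sel] / norm,
        ],
        axis=-1,
    )
    if adapt_white is not None:
        flat_white = np.array(
            [cmf.xbar[sel].sum(), cmf.ybar[sel].sum(), cmf.zbar[sel].sum()]
        ) / norm
        xyz = xyz * (np.asarray(adapt_white, float) / flat_white)
    return xyz.reshape(r.shape[:-1] + (3,))


def xyz_to_srgb(
    xyz: np.ndarray, return_clipped: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """XYZ -> display sRGB: linear 3x3 matrix then piecewise gamma, clip to [0,1].

    Out-of-gamut or super-white values are clipped; set return_clipped to
    also get a boolean mask of where clipping occurred.
    """
    xyz = np.asarray(xyz, float)
    lin = xyz @ _XYZ_TO_RGB.T
    clipped = (lin < -1e-12) | (lin > 1.0 + 1e-12)
    lin = np.clip(lin, 0.0, 1.0)
    srgb = np.where(
        lin <= 0.0031308,
        12.92 * lin,
        1.055 * np.power(lin, 1.0 / 2.4) - 0.055,
    )
    if return_clipped:
        return srgb, clipped
    return srgb


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray | None = None) -> np.ndarray:
    """XYZ -> CIELAB with the cube-root function and its linear toe."""
    if white is None:
        white = D65_WHITE
    white = np.asarray(white, float)
    if np.any(white <= 0):
        raise ValueError("white point components must be positive")
    t = np.asarray(xyz, float) / white
    delta = 6.0 / 29.0
    f = np.where(t > delta ** 3, np.cbrt(t), t / (3 * delta ** 2) + 4.0 / 29.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack(
        [116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1
    )


def ciede2000(
    lab1: np.ndarray, lab2: np.ndarray, kL: float = 1.0, kC: float = 1.0,
    kH: float = 1.0,
) -> np.ndarray | float:
    """Full CIEDE2000 colour difference between Lab triplets (vectorised).

    Includes the chroma-dependent a* rescaling (G), the hue rotation term
    R_T and the S_L/S_C/S_H weighting functions. Symmetric, non-negative,
    zero iff the inputs are equal.
    """
    lab1 = np.asarray(lab1, float)
    lab2 = np.asarray(lab2, float)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = (C1 + C2) / 2.0
    G = 0.5 * (1.0 - np.sqrt(Cbar ** 7 / (Cbar ** 7 + 25.0 ** 7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = (L1 + L2) / 2.0
    Cbp = (C1p + C2p) / 2.0
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            habs <= 180.0,
            hsum / 2.0,
            np.where(hsum < 360.0, (hsum + 360.0) / 2.0, (hsum - 360.0) / 2.0),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp ** 7 / (Cbp ** 7 + 25.0 ** 7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / (kL * SL)) ** 2
        + (dCp / (kC * SC)) ** 2
        + (dHp / (kH * SH)) ** 2
        + RT * (dCp / (kC * SC)) * (dHp / (kH * SH))
    )
    if dE.ndim == 0:
        return float(dE)
    return dE


def srgb_render(cube, cmf: ColorMatchingFunctions | None = None) -> np.ndarray:
    """Render a hypercube to an 8-bit sRGB image (H x W x 3 uint8)."""
    xyz = spectrum_to_xyz(cube.wavelengths.values, cube.values, cmf=cmf)
    srgb = xyz_to_srgb(xyz)
    return np.rint(srgb * 255.0).astype(np.uint8)
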
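"""ENVI cube, PNG mask and CSV I/O.

ENVI (a plain-text header next to a raw binary cube) is the de facto
interchange container for hyperspectral data; reads accept BSQ, BIL and
BIP interleaves and honour byte order, writes default to BSQ float32
little-endian with the wavelength list (nm) in the header. Capture sets
are stored as one ENVI cube per stack (lenslet index as the band axis)
plus a sidecar CSV describing the filter bank, lenslet geometry and
sensor settings.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .camera_model import CaptureSet, FilterBank, LensletGeometry, SensorConfig
from .phantom_scenes import WavelengthGrid
from .reconstruction import Hypercube

__all__ = [
    "read_envi",
    "write_envi",
    "read_hypercube",
    "write_hypercube",
    "write_capture",
    "read_capture",
    "write_mask_png",
    "read_mask_png",
]

_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16,
}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            while i < len(lines):
                parts.append(lines[i])
                if "}" in lines[i]:
                    i += 1
                    break
                i += 1
            val = " ".join(parts)
        fields[key] = val
    return fields


def read_envi(header_path, data_path=None):
    """Read an ENVI cube -> (values H x W x B float array, wavelengths or None).

    Accepts BSQ/BIL/BIP; a truncated data file raises with the expected
    and actual byte counts; a missing wavelength list warns and yields
    band-index wavelengths of None.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    data_path = Path(data_path)
    fields = _parse_header(header_path.read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = np.dtype(_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").strip().lower()
    offset = int(fields.get("header offset", 0))

    expected = samples * lines * bands * dtype.itemsize + offset
    actual = data_path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"ENVI data size mismatch: header implies {expected} bytes, "
            f"file {data_path} has {actual} bytes"
        )
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    wavelengths = None
    if "wavelength" in fields:
        txt = fields["wavelength"].strip().strip("{}")
        wavelengths = np.array(
            [float(v) for v in txt.replace("\n", " ").split(",") if v.strip()]
        )
        if wavelengths.size != bands:
            raise ValueError("wavelength list length does not match band count")
    else:
        warnings.warn(
            "ENVI header has no wavelength list; using band indices", stacklevel=2
        )
    return np.ascontiguousarray(cube), wavelengths


def write_envi(
    values: np.ndarray,
    header_path,
    data_path=None,
    wavelengths: np.ndarray | None = None,
    interleave: str = "bsq",
    dtype=np.float32,
    provenance: dict | None = None,
) -> None:
    """Write an H x W x B cube as ENVI header + raw binary (default BSQ float32)."""
    values = np.asarray(values)
    if values.ndim != 3 or values.shape[2] == 0:
        raise ValueError("cube must be H x W x B with at least one band")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    data_path = Path(data_path)
    h, w, b = values.shape
    dtype = np.dtype(dtype)
    interleave = interleave.lower()
    if interleave == "bsq":
        arr = values.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = values.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = values
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    arr.astype(dtype.newbyteorder("<")).tofile(data_path)

    lines = [
        "ENVI",
        "description = {lfhsi hypercube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        # enough digits that a uniform grid survives the text round trip
        wl = ", ".join(f"{v:.10f}" for v in np.asarray(wavelengths, float))
        lines.append("wavelength units = nm")
        lines.append(f"wavelength = {{{wl}}}")
    header_path.write_text("\n".join(lines) + "\n")
    if provenance is not None:
        sidecar = header_path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(provenance, indent=2, default=str) + "\n")


def write_hypercube(cube: Hypercube, header_path, **kw) -> None:
    write_envi(
        cube.values, header_path,
        wavelengths=cube.wavelengths.values,
        provenance=cube.provenance, **kw,
    )


def read_hypercube(header_path, data_path=None) -> Hypercube:
    values, wl = read_envi(header_path, data_path)
    if wl is None:
        raise ValueError("hypercube header must carry a wavelength list")
    prov = {}
    sidecar = Path(header_path).with_suffix(".provenance.json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return Hypercube(values=values, wavelengths=WavelengthGrid(wl), provenance=prov)


def write_capture(capture: CaptureSet, directory) -> None:
    """One ENVI cube per stack (lenslet index as band axis) + sidecar CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("sample", "white", "dark"):
        stack = getattr(capture, name)  # (n, H, W) -> H x W x n
        write_envi(
            stack.transpose(1, 2, 0), directory / f"{name}.hdr", dtype=np.uint16
        )
    geom = capture.geometry
    meta = pd.DataFrame(
        {
            "lenslet": np.arange(capture.n_lenslets),
            "center_nm": capture.bank.centers,
            "fwhm_nm": capture.bank.fwhm,
            "baseline_y_mm": geom.baselines[:, 0],
            "baseline_x_mm": geom.baselines[:, 1],
        }
    )
    meta.to_csv(directory / "lenslets.csv", index=False)
    side = {
        "grid_rows": geom.grid_rows,
        "grid_cols": geom.grid_cols,
        "pitch_mm": geom.pitch_mm,
        "disparity_scale": geom.disparity_scale,
        "depth_cm": geom.depth_cm,
        "rho_ref": capture.rho_ref,
        "sensor": {
            "bit_depth": capture.sensor.bit_depth,
            "exposure_gain": capture.sensor.exposure_gain,
            "shot_noise": capture.sensor.shot_noise,
            "read_noise_sigma": capture.sensor.read_noise_sigma,
            "seed": capture.sensor.seed,
        },
        "provenance": capture.provenance,
    }
    (directory / "capture.json").write_text(json.dumps(side, indent=2) + "\n")


def read_capture(directory) -> CaptureSet:
    directory = Path(directory)
    stacks = {}
    for name in ("sample", "white", "dark"):
        with warnings.catch_warnings():
            # lenslet stacks index bands by lenslet, not wavelength
            warnings.simplefilter("ignore", UserWarning)
            values, _ = read_envi(directory / f"{name}.hdr")
        stacks[name] = np.ascontiguousarray(values.transpose(2, 0, 1))
    meta = pd.read_csv(directory / "lenslets.csv")
    side = json.loads((directory / "capture.json").read_text())
    bank = FilterBank(
        centers=meta["center_nm"].to_numpy(), fwhm=float(meta["fwhm_nm"].iloc[0])
    )
    geom = LensletGeometry(
        grid_rows=int(side["grid_rows"]),
        grid_cols=int(side["grid_cols"]),
        pitch_mm=float(side["pitch_mm"]),
        disparity_scale=float(side["disparity_scale"]),
        depth_cm=side["depth_cm"],
    )
    s = side["sensor"]
    sensor = SensorConfig(
        bit_depth=int(s["bit_depth"]),
        exposure_gain=s["exposure_gain"],
        shot_noise=bool(s["shot_noise"]),
        read_noise_sigma=float(s["read_noise_sigma"]),
        seed=int(s["seed"]),
    )
    return CaptureSet(
        sample=stacks["sample"], white=stacks["white"], dark=stacks["dark"],
        geometry=geom, bank=bank, rho_ref=float(side["rho_ref"]),
        sensor=sensor, provenance=side.get("provenance", {}),
    )


def write_mask_png(labels: np.ndarray, path) -> None:
    """Store an integer label mask as 16-bit PNG."""
    import imageio.v3 as iio

    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit in uint16")
    iio.imwrite(path, labels.astype(np.uint16))


def read_mask_png(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)).astype(np.int32)
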
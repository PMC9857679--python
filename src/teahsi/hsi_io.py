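"""Hyperspectral cube I/O, reflectance correction, ROI masking, spectra.

Supports two cube dialects: an ENVI-style text header + raw binary file
(BIL or BSQ interleave), the de-facto exchange format for line-scanning
NIR cameras, and a portable HDF5 container for fixtures and archives.
Radiometric processing follows the standard two-point correction
``R = (raw - dark) / (white - dark)`` against white/dark reference frames,
after which the tea sample ROI is isolated by thresholding the band-mean
reflectance at 0.1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from teahsi.errors import (
    DegenerateReferenceError,
    DimensionError,
    EmptyRoiError,
    FormatError,
)

_REFERENCE_TOL = 1e-9


@dataclass
class HyperspectralCube:
    """A rows x cols x bands reflectance (or raw-intensity) array."""

    data: np.ndarray
    wavelengths: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"cube must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise DimensionError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band axis {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise DimensionError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_mean_image(self) -> np.ndarray:
        """Spatial image of per-pixel mean reflectance across bands."""
        return self.data.mean(axis=2)


@dataclass
class RoiMask:
    """Boolean foreground mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float = 0.1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DimensionError("ROI mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def correct_reflectance(
    raw: HyperspectralCube, white: HyperspectralCube, dark: HyperspectralCube
) -> HyperspectralCube:
    """Two-point black/white radiometric correction.

    ``R = (raw - dark) / (white - dark)`` per pixel and band, clipped to
    [0, 1] (a sample cannot out-reflect the white tile).  All three cubes
    must share shape and wavelength axis.
    """
    for name, cube in (("white", white), ("dark", dark)):
        if cube.shape != raw.shape:
            raise DimensionError(f"{name} reference shape {cube.shape} != raw shape {raw.shape}")
        if not np.array_equal(cube.wavelengths, raw.wavelengths):
            raise DimensionError(f"{name} reference wavelength axis differs from raw")
    denom = white.data - dark.data
    bad = np.abs(denom) < _REFERENCE_TOL
    if np.any(bad):
        band = int(np.argwhere(bad)[0, 2])
        raise DegenerateReferenceError(
            f"white and dark references coincide (|white-dark| < {_REFERENCE_TOL:g}) "
            f"at band {band} ({raw.wavelengths[band]:.1f} nm)"
        )
    reflectance = np.clip((raw.data - dark.data) / denom, 0.0, 1.0)
    return HyperspectralCube(data=reflectance, wavelengths=raw.wavelengths.copy(), corrected=True)


def segment_roi(cube: HyperspectralCube, threshold: float = 0.1) -> RoiMask:
    """Threshold masking: foreground iff band-mean reflectance > threshold.

    The comparison is strict, so a pixel at exactly the threshold is
    background.  Raises :class:`EmptyRoiError` if nothing survives.
    """
    mask = cube.band_mean_image() > threshold
    if not mask.any():
        raise EmptyRoiError(
            f"no pixel has band-mean reflectance above {threshold}; empty ROI"
        )
    return RoiMask(mask=mask, threshold_used=threshold)


def extract_mean_spectrum(cube: HyperspectralCube, mask: RoiMask) -> np.ndarray:
    """Arithmetic mean spectrum over foreground pixels, per band."""
    if mask.mask.shape != cube.shape[:2]:
        raise DimensionError(
            f"mask shape {mask.mask.shape} does not match cube spatial dims {cube.shape[:2]}"
        )
    if mask.n_foreground == 0:
        raise EmptyRoiError("cannot average a spectrum over an empty ROI")
    return cube.data[mask.mask].mean(axis=0)


# ---------------------------------------------------------------------------
# ENVI-style header + binary dialect

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def write_cube(cube: HyperspectralCube, path: str | Path, interleave: str = "bil") -> None:
    """Write a cube to disk.

    ``.h5``/``.hdf5`` paths use the HDF5 container; anything else is
    written as ENVI-style raw binary (float64, ``interleave`` bil or bsq)
    with a companion ``<path>.hdr`` text header carrying the wavelength
    list bit-exactly.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_hdf5(cube, path)
        return
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise FormatError(f"unsupported interleave '{interleave}' (use 'bil' or 'bsq')")
    rows, cols, bands = cube.shape
    # BIL stores (lines, bands, samples); BSQ stores (bands, lines, samples).
    if interleave == "bil":
        arr = np.transpose(cube.data, (0, 2, 1))
    else:
        arr = np.transpose(cube.data, (2, 0, 1))
    arr.astype("<f8").tofile(path)
    wl_text = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "file type = ENVI Standard\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float64)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"corrected = {int(cube.corrected)}\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl_text} }}\n"
    )
    _header_path(path).write_text(header)


def _parse_envi_header(text: str, path: Path) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError(f"{path}: missing ENVI magic line")
    # Fold brace-delimited multi-line values onto one line before parsing.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    out: dict = {}
    for key in ("samples", "lines", "bands", "data type"):
        if key not in fields:
            raise FormatError(f"{path}: header missing required field '{key}'")
        try:
            out[key] = int(fields[key])
        except ValueError as exc:
            raise FormatError(f"{path}: header field '{key}' is not an integer") from exc
    for key in ("samples", "lines", "bands"):
        if out[key] <= 0:
            raise FormatError(f"{path}: header field '{key}' must be positive")
    if out["data type"] not in _ENVI_DTYPES:
        raise FormatError(f"{path}: unsupported data type code {out['data type']}")
    interleave = fields.get("interleave", "").lower()
    if interleave not in ("bil", "bsq"):
        raise FormatError(f"{path}: unsupported or missing interleave '{interleave}'")
    out["interleave"] = interleave
    if "wavelength" not in fields:
        raise FormatError(f"{path}: header missing field 'wavelength'")
    wl_body = fields["wavelength"].strip()
    if not (wl_body.startswith("{") and wl_body.endswith("}")):
        raise FormatError(f"{path}: malformed wavelength block")
    try:
        out["wavelengths"] = np.array(
            [float(tok) for tok in wl_body[1:-1].split(",") if tok.strip()], dtype=np.float64
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength entry") from exc
    if out["wavelengths"].size != out["bands"]:
        raise FormatError(
            f"{path}: wavelength list length {out['wavelengths'].size} != bands {out['bands']}"
        )
    out["corrected"] = fields.get("corrected", "0").strip() == "1"
    return out


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (either dialect).

    Accepts the binary path or its ``.hdr`` companion for the ENVI dialect.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path)
    if path.suffix.lower() == ".hdr":
        hdr_path, bin_path = path, path.with_suffix("")
    else:
        hdr_path, bin_path = _header_path(path), path
    if not hdr_path.exists():
        raise FormatError(f"header file not found: {hdr_path}")
    meta = _parse_envi_header(hdr_path.read_text(), hdr_path)
    dtype = np.dtype(_ENVI_DTYPES[meta["data type"]]).newbyteorder("<")
    expected = meta["samples"] * meta["lines"] * meta["bands"] * dtype.itemsize
    actual = bin_path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{bin_path}: binary size {actual} B does not match header "
            f"(samples x lines x bands -> {expected} B); truncated or mislabeled file"
        )
    flat = np.fromfile(bin_path, dtype=dtype)
    if meta["interleave"] == "bil":
        arr = flat.reshape(meta["lines"], meta["bands"], meta["samples"]).transpose(0, 2, 1)
    else:
        arr = flat.reshape(meta["bands"], meta["lines"], meta["samples"]).transpose(1, 2, 0)
    return HyperspectralCube(
        data=arr.astype(np.float64), wavelengths=meta["wavelengths"], corrected=meta["corrected"]
    )


# ---------------------------------------------------------------------------
# Portable HDF5 container

def _write_hdf5(cube: HyperspectralCube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.data)
        f.create_dataset("wavelengths_nm", data=cube.wavelengths)
        f.attrs["corrected"] = bool(cube.corrected)


def _read_hdf5(path: Path) -> HyperspectralCube:
    try:
        with h5py.File(path, "r") as f:
            for name in ("reflectance", "wavelengths_nm"):
                if name not in f:
                    raise FormatError(f"{path}: container missing dataset '{name}'")
            return HyperspectralCube(
                data=f["reflectance"][...],
                wavelengths=f["wavelengths_nm"][...],
                corrected=bool(f.attrs.get("corrected", False)),
            )
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 container ({exc})") from exc


def write_mask_png(mask: RoiMask, path: str | Path) -> None:
    """Write the mask as an 8-bit PNG (foreground 255, background 0)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))
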
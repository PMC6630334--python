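"""ENVI hyperspectral IO, reflectance calibration, and spectral trimming.

A line-scan NIR instrument records raw detector counts ``I_raw`` together with
a dark-current frame ``I_dark`` (lens capped) and a white-reference frame
``I_ref`` (near-perfect diffuse reflector).  Unitless reflectance is

    I_cal = (I_raw - I_dark) / (I_ref - I_dark)

computed per pixel and band.  Bands at the edges of the detector have poor
signal-to-noise; analysis is restricted to a fixed wavelength window
(default 941-1666 nm) by :func:`trim_spectral`.

Cubes are stored in memory as ``(lines, samples, bands)`` float arrays and on
disk as ENVI header/binary pairs (text ``.hdr`` + raw ``.img``).  BIL, BIP and
BSQ interleaves are read; BIL is written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CorruptFileError,
    DegenerateReferenceError,
    EmptyWindowError,
    FormatError,
)

# ENVI numeric data-type codes we support.
_DTYPE_TO_CODE = {np.dtype("uint16"): 12, np.dtype("float32"): 4, np.dtype("float64"): 5}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}


@dataclass
class RawScan:
    """Raw counts plus calibration frames sharing one wavelength axis.

    ``dark`` and ``white`` may be single ``(samples, bands)`` frames (the
    line-scan convention: one reference line broadcast along the scan axis)
    or full ``(lines, samples, bands)`` cubes.
    """

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.raw.ndim != 3:
            raise ValueError("raw must be a (lines, samples, bands) cube")
        n_bands = self.raw.shape[2]
        for name, frame in (("dark", self.dark), ("white", self.white)):
            if frame.shape[-1] != n_bands or frame.ndim not in (2, 3):
                raise ValueError(f"{name} frame incompatible with raw cube shape")
        if self.wavelengths.shape != (n_bands,):
            raise ValueError("wavelengths length must equal the band dimension")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class CalibratedCube:
    """Reflectance cube with its wavelength axis and processing provenance."""

    reflectance: np.ndarray
    wavelengths: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be a (lines, samples, bands) cube")
        if self.wavelengths.shape != (self.reflectance.shape[2],):
            raise ValueError("wavelengths length must equal the band dimension")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape


def calibrate(scan: RawScan) -> CalibratedCube:
    """Convert raw counts to reflectance: (raw - dark) / (white - dark).

    Dark/white frames given as ``(samples, bands)`` are broadcast along the
    scan (line) axis.  Any band where the white and dark references coincide
    somewhere makes the ratio undefined and raises
    :class:`DegenerateReferenceError` naming the band.
    """
    dark = scan.dark if scan.dark.ndim == 3 else scan.dark[np.newaxis, :, :]
    white = scan.white if scan.white.ndim == 3 else scan.white[np.newaxis, :, :]
    denom = white - dark
    bad = np.nonzero(np.any(denom <= 0, axis=(0, 1)))[0]
    if bad.size:
        b = int(bad[0])
        raise DegenerateReferenceError(
            f"white reference does not exceed dark current at band {b} "
            f"({scan.wavelengths[b]:.2f} nm); calibration undefined"
        )
    reflectance = (scan.raw - dark) / denom
    return CalibratedCube(
        reflectance=reflectance,
        wavelengths=scan.wavelengths.copy(),
        provenance=["calibrate: (raw - dark) / (white - dark)"],
    )


def trim_spectral(cube: CalibratedCube, low: float = 941.0, high: float = 1666.0) -> CalibratedCube:
    """Keep bands with ``low <= wavelength <= high`` (endpoints inclusive).

    On the instrument's native 256-band grid (874 nm start, 3.36 nm step) the
    default window retains exactly 216 bands.
    """
    if not low < high:
        raise ValueError(f"trim window must satisfy low < high, got [{low}, {high}]")
    keep = (cube.wavelengths >= low) & (cube.wavelengths <= high)
    if not keep.any():
        raise EmptyWindowError(
            f"no bands fall inside [{low}, {high}] nm "
            f"(grid spans {cube.wavelengths[0]:.2f}-{cube.wavelengths[-1]:.2f} nm)"
        )
    return CalibratedCube(
        reflectance=cube.reflectance[:, :, keep],
        wavelengths=cube.wavelengths[keep],
        provenance=cube.provenance + [f"trim_spectral: [{low}, {high}] nm"],
    )


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band closest to ``target_nm`` (lower index wins ties)."""
    return int(np.argmin(np.abs(np.asarray(wavelengths) - target_nm)))


# ---------------------------------------------------------------------------
# ENVI header/binary IO


def _header_path(path: Path) -> Path:
    return path.with_suffix(".hdr") if path.suffix != ".hdr" else path


def _data_path(path: Path) -> Path:
    return path.with_suffix(".img")


def _format_header(shape: tuple[int, int, int], dtype: np.dtype, interleave: str,
                   wavelengths: np.ndarray) -> str:
    lines, samples, bands = shape
    wl = ", ".join(f"{w:.6g}" for w in wavelengths)
    return (
        "ENVI\n"
        "description = {seedvigor hyperspectral cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    # Collapse brace-delimited multi-line values, then split key = value.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_envi(path: str | Path, data: np.ndarray, wavelengths: np.ndarray,
               interleave: str = "bil") -> Path:
    """Write a cube (or a single ``(samples, bands)`` frame) as an ENVI pair.

    Returns the header path.  Frames are stored as one-line cubes.  Supported
    dtypes: uint16, float32, float64; anything else is stored as float64.
    """
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    if data.ndim != 3:
        raise ValueError("data must be 2-D (samples, bands) or 3-D (lines, samples, bands)")
    if data.dtype not in _DTYPE_TO_CODE:
        data = data.astype(np.float64)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.shape != (data.shape[2],):
        raise ValueError("wavelengths length must equal the band dimension")
    interleave = interleave.lower()
    if interleave != "bil":
        raise ValueError("only BIL interleave is written")

    path = Path(path)
    hdr = _header_path(path)
    hdr.parent.mkdir(parents=True, exist_ok=True)
    hdr.write_text(_format_header(data.shape, data.dtype, "bil", wavelengths))
    # BIL: for each line, bands × samples.
    np.ascontiguousarray(data.transpose(0, 2, 1)).tofile(_data_path(path))
    return hdr


def read_envi(path: str | Path) -> CalibratedCube:
    """Read an ENVI header/binary pair into a :class:`CalibratedCube`.

    The cube is returned in ``(lines, samples, bands)`` order whatever the
    stored interleave (BIL/BIP/BSQ).  The header must carry a ``wavelength``
    field; a payload whose size disagrees with the header raises
    :class:`CorruptFileError`.
    """
    path = Path(path)
    hdr_path = _header_path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_header(hdr_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if code not in _CODE_TO_DTYPE:
        raise FormatError(f"unsupported ENVI data type code {code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) files are supported")
    interleave = fields.get("interleave", "bil").lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unknown interleave {interleave!r}")

    if "wavelength" not in fields:
        raise FormatError("ENVI header has no 'wavelength' field")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(tok) for tok in wl_text.replace(",", " ").split()])
    if wavelengths.size != bands:
        raise CorruptFileError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    dtype = _CODE_TO_DTYPE[code]
    flat = np.fromfile(_data_path(path), dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise CorruptFileError(
            f"binary payload holds {flat.size} values but header implies {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )
    if interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:  # bsq
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    return CalibratedCube(
        reflectance=np.ascontiguousarray(data).astype(dtype, copy=False),
        wavelengths=wavelengths,
        provenance=[f"read_envi: {path.name} ({interleave})"],
    )
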
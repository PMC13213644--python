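"""Hypercube I/O, black/white reflectance calibration, band trimming and ROI means.

Cubes are exchanged in the open ENVI dialect — a small text header (``.hdr``)
next to a raw binary cube — since that is the lingua franca of hyperspectral
tooling.  Only the fields this pipeline needs are honored: samples/lines/bands,
data type, interleave (BIL/BIP/BSQ), byte order, header offset and the
wavelength list.

Calibration converts raw detector counts to relative reflectance in percent
against dark (0 %) and white (100 %) reference frames:

    I = (I0 - D) / (W - D) * 100

No clipping is applied: specular pixels may legitimately exceed 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawCube",
    "ReflectanceCube",
    "ReferenceFrames",
    "calibrate_reflectance",
    "trim_bands",
    "extract_roi_mean",
    "threshold_mask",
    "read_envi",
    "write_envi",
    "save_mask_csv",
    "load_mask_csv",
    "save_mask_png",
    "load_mask_png",
]

_DTYPE_TO_ENVI = {"uint8": 1, "int16": 2, "int32": 3, "float32": 4, "float64": 5,
                  "uint16": 12, "uint32": 13}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


@dataclass
class RawCube:
    """Uncalibrated hypercube: (rows, cols, bands) detector counts."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.wavelengths.size:
            raise ValueError("cube must be (rows, cols, bands) matching wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReflectanceCube:
    """Calibrated hypercube in relative reflectance (%), optional background mask."""

    data: np.ndarray
    wavelengths: np.ndarray
    mask: np.ndarray | None = None     # True = foreground

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.wavelengths.size:
            raise ValueError("cube must be (rows, cols, bands) matching wavelengths")
        if self.mask is not None and self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match the pixel grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceFrames:
    """Dark (0 % reflectance) and white (100 %) reference frames.

    Frames are per-band vectors (spatially uniform references) or full frames
    broadcastable against the cube.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")


def calibrate_reflectance(raw: RawCube, refs: ReferenceFrames) -> ReflectanceCube:
    """Black/white calibration to relative reflectance in percent.

    Raises ``ValueError`` naming the first offending band where the white
    frame does not exceed the dark frame.
    """
    dark, white = refs.dark, refs.white
    if dark.shape[-1] != raw.wavelengths.size:
        raise ValueError("reference frames do not match the cube band axis")
    span = white - dark
    bad = np.where(~np.all(span > 0, axis=tuple(range(span.ndim - 1))))[0]
    if bad.size:
        raise ValueError(
            f"white <= dark at band {bad[0]} ({raw.wavelengths[bad[0]]:.1f} nm)"
        )
    refl = (raw.data - dark) / span * 100.0
    return ReflectanceCube(data=refl, wavelengths=raw.wavelengths.copy())


def trim_bands(obj, low_nm: float, high_nm: float):
    """Retain bands with ``low_nm <= lambda <= high_nm`` (inclusive, order kept).

    Accepts a RawCube, ReflectanceCube or SpectrumSet and returns the same
    kind.  Raises if the window selects no bands.
    """
    from .synthetic import SpectrumSet

    wl = obj.wavelengths
    keep = (wl >= low_nm) & (wl <= high_nm)
    if not keep.any():
        raise ValueError(f"no bands inside [{low_nm}, {high_nm}] nm")
    if isinstance(obj, RawCube):
        return RawCube(data=obj.data[:, :, keep], wavelengths=wl[keep])
    if isinstance(obj, ReflectanceCube):
        return ReflectanceCube(
            data=obj.data[:, :, keep], wavelengths=wl[keep], mask=obj.mask
        )
    if isinstance(obj, SpectrumSet):
        return SpectrumSet(
            wavelengths=wl[keep],
            spectra=obj.spectra[:, keep],
            labels=obj.labels,
            concentrations=obj.concentrations,
        )
    raise TypeError(f"cannot trim bands of {type(obj).__name__}")


def extract_roi_mean(cube: ReflectanceCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean spectrum over the masked (True) pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("ROI mask shape must match the pixel grid")
    if not mask.any():
        raise ValueError("ROI mask selects no pixels")
    return cube.data[mask].mean(axis=0)


def threshold_mask(
    cube: ReflectanceCube, reference_nm: float, threshold: float = 10.0
) -> np.ndarray:
    """Foreground mask: reflectance above ``threshold`` % at the band nearest
    ``reference_nm``.  Replaces the vendor software's manual background masking."""
    band = int(np.argmin(np.abs(cube.wavelengths - reference_nm)))
    return cube.data[:, :, band] > threshold


# --- ENVI header + raw binary -------------------------------------------------

def write_envi(path, cube, interleave: str = "bil", dtype: str = "float32") -> Path:
    """Write ``<path>.hdr`` and ``<path>.img``; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError("interleave must be bil, bip or bsq")
    if dtype not in _DTYPE_TO_ENVI:
        raise ValueError(f"unsupported dtype {dtype!r}")
    path = Path(path)
    data = np.asarray(cube.data, dtype=dtype)
    rows, cols, bands = data.shape
    if interleave == "bil":
        arranged = data.transpose(0, 2, 1)       # line, band, sample
    elif interleave == "bip":
        arranged = data                           # line, sample, band
    else:
        arranged = data.transpose(2, 0, 1)       # band, line, sample
    img_path = path.with_suffix(".img")
    arranged.tofile(img_path)
    wl_list = ",\n ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {hsichem reflectance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{\n {wl_list}}}\n"
    )
    hdr_path = path.with_suffix(".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if "=" not in line:
            i += 1
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{"):
            buf = val[1:]
            while "}" not in buf and i + 1 < len(lines):
                i += 1
                buf += " " + lines[i]
            val = buf[: buf.index("}")]
        fields[key] = val.strip()
        i += 1
    return fields


def read_envi(hdr_path) -> ReflectanceCube:
    """Read an ENVI header + binary cube written by :func:`write_envi` or
    compatible tools (BIL/BIP/BSQ, little-endian, supported data types)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    offset = int(fields.get("header offset", 0))
    dtype = np.dtype(_ENVI_TO_DTYPE[int(fields["data type"])])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bil").lower()
    img_path = hdr_path.with_suffix(".img")
    if not img_path.exists():
        img_path = hdr_path.with_suffix(".dat")
    flat = np.fromfile(img_path, dtype=dtype, offset=offset)
    if flat.size != rows * cols * bands:
        raise ValueError("binary cube size does not match header dimensions")
    if interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    elif interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl = np.array([float(v) for v in fields["wavelength"].replace("\n", " ").split(",")])
    return ReflectanceCube(data=np.ascontiguousarray(data, dtype=float), wavelengths=wl)


def save_mask_csv(path, mask: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter=",")


def load_mask_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", dtype=int).astype(bool)


def save_mask_png(path, mask: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def load_mask_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path)) > 127
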
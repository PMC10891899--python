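"""ENVI hypercube and binary-mask I/O.

Hypercubes are stored on disk as a raw Band-Interleaved-by-Line (BIL) binary
file accompanied by a plain-text ``key = value`` header (HDR).  In BIL layout
each image line stores, band by band, one row of samples::

    line 0: band 0 samples, band 1 samples, ..., band B-1 samples
    line 1: band 0 samples, ...

In memory a :class:`Hypercube` holds reflectance indexed ``[row, col, band]``
together with the band-center wavelength grid (nm) and the raw header map.
Only the minimal ENVI dialect the pipeline needs is supported: BIL interleave,
32-bit float or 16-bit unsigned data, little/big byte order.

Ground-truth masks are single-channel images with 1 marking vein pixels and 0
skin; on disk they are 0/255 PNG or PGM.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Hypercube",
    "RoiSpec",
    "EnviHeaderError",
    "EnviDialectError",
    "EnviSizeError",
    "MaskFormatError",
    "parse_envi_header",
    "read_envi",
    "write_envi",
    "crop_roi",
    "to_rgb",
    "read_mask",
    "write_mask",
]


class EnviHeaderError(ValueError):
    """Header file is missing, malformed, or lacks required fields."""


class EnviDialectError(ValueError):
    """Header declares a layout outside the supported dialect (e.g. BSQ)."""


class EnviSizeError(ValueError):
    """Binary file size disagrees with the dimensions the header declares."""


class MaskFormatError(ValueError):
    """Mask image is not a single-channel binary image."""


# ENVI "data type" codes for the supported numeric types.
_DTYPE_CODES = {4: np.float32, 12: np.uint16}
_CODE_FOR_DTYPE = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


@dataclass
class Hypercube:
    """A reflectance cube ``data[row, col, band]`` plus spectral metadata.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Reflectance-like intensities; must be finite.
    wavelengths : ndarray of shape (bands,), optional
        Band-center wavelengths in nm, strictly increasing.
    meta : dict
        Header key/value map (strings).  ``interleave`` is always ``"bil"``.
    """

    data: np.ndarray
    wavelengths: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"cube must be rows x cols x bands, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (self.data.shape[2],):
                raise ValueError("wavelengths length must equal band count")
            if np.any(np.diff(self.wavelengths) <= 0):
                raise ValueError("wavelengths must be strictly increasing")
        self.meta.setdefault("interleave", "bil")
        if self.meta["interleave"] != "bil":
            raise EnviDialectError("only BIL interleave is supported")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class RoiSpec:
    """Half-open region of interest ``[row0, row0+height) x [col0, col0+width)``."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI extent must be at least 1x1")


def parse_envi_header(header_path: str | os.PathLike) -> dict:
    """Parse a plain-text ENVI header into a key -> string map.

    Multi-line ``{ ... }`` blocks (e.g. wavelength lists) are joined.  Keys are
    lower-cased; values keep their raw text.
    """
    try:
        with open(header_path, "r") as fh:
            text = fh.read()
    except OSError as exc:
        raise EnviHeaderError(f"cannot read header: {exc}") from exc

    lines = text.splitlines()
    if lines and lines[0].strip().upper() == "ENVI":
        lines = lines[1:]
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith(";"):
            continue
        if "=" not in line:
            raise EnviHeaderError(f"malformed header line: {line!r}")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            # accumulate until closing brace
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            if "}" not in value:
                raise EnviHeaderError(f"unterminated {{...}} block for key {key!r}")
            value = value.strip("{} ").strip()
        meta[key] = value
    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in meta:
            raise EnviHeaderError(f"header missing required field {required!r}")
    return meta


def _header_dims(meta: dict) -> tuple[int, int, int]:
    try:
        lines = int(meta["lines"])
        samples = int(meta["samples"])
        bands = int(meta["bands"])
    except ValueError as exc:
        raise EnviHeaderError(f"non-integer dimensions in header: {exc}") from exc
    if min(lines, samples, bands) < 1:
        raise EnviHeaderError("header dimensions must be positive")
    return lines, samples, bands


def read_envi(header_path: str | os.PathLike, data_path: str | os.PathLike | None = None) -> Hypercube:
    """Read a BIL hypercube described by ``header_path``.

    ``data_path`` defaults to the header path with its extension dropped (the
    convention :func:`write_envi` uses, with a ``.bil`` suffix).
    """
    meta = parse_envi_header(header_path)
    if meta["interleave"].lower() != "bil":
        raise EnviDialectError(f"unsupported interleave {meta['interleave']!r} (only bil)")
    lines, samples, bands = _header_dims(meta)
    code = int(meta["data type"])
    if code not in _DTYPE_CODES:
        raise EnviDialectError(f"unsupported data type code {code} (only 4=float32, 12=uint16)")
    dtype = np.dtype(_DTYPE_CODES[code])
    byte_order = int(meta.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if data_path is None:
        base, _ = os.path.splitext(os.fspath(header_path))
        data_path = base + ".bil"
    expected = lines * samples * bands * dtype.itemsize
    actual = os.path.getsize(data_path)
    if actual != expected:
        raise EnviSizeError(
            f"data file holds {actual} bytes but header declares {expected} "
            f"({lines}x{samples}x{bands} @ {dtype.itemsize}B)"
        )
    flat = np.fromfile(data_path, dtype=dtype)
    # BIL: (lines, bands, samples) on disk -> (rows, cols, bands) in memory
    data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    data = np.ascontiguousarray(data.astype(dtype.newbyteorder("=")))

    wavelengths = None
    if "wavelength" in meta:
        wavelengths = np.array([float(w) for w in meta["wavelength"].replace(",", " ").split()])
        if wavelengths.size != bands:
            raise EnviHeaderError("wavelength list length disagrees with band count")
    return Hypercube(data=data, wavelengths=wavelengths, meta=dict(meta))


def write_envi(
    cube: Hypercube,
    header_path: str | os.PathLike,
    data_path: str | os.PathLike | None = None,
) -> None:
    """Write ``cube`` as raw BIL binary plus plain-text header.

    float32 and uint16 data are written bit-exactly; any other dtype is cast
    to float32 first.  Little-endian on disk.
    """
    if data_path is None:
        base, _ = os.path.splitext(os.fspath(header_path))
        data_path = base + ".bil"
    data = cube.data
    if data.dtype not in _CODE_FOR_DTYPE:
        data = data.astype(np.float32)
    code = _CODE_FOR_DTYPE[data.dtype]
    disk = data.transpose(0, 2, 1).astype(data.dtype.newbyteorder("<"))
    try:
        with open(data_path, "wb") as fh:
            fh.write(np.ascontiguousarray(disk).tobytes())
    except OSError as exc:
        raise OSError(f"cannot write BIL data: {exc}") from exc

    meta = dict(cube.meta)
    meta.update(
        {
            "samples": str(cube.cols),
            "lines": str(cube.rows),
            "bands": str(cube.bands),
            "interleave": "bil",
            "data type": str(code),
            "byte order": "0",
            "header offset": meta.get("header offset", "0"),
        }
    )
    with open(header_path, "w") as fh:
        fh.write("ENVI\n")
        for key in ("samples", "lines", "bands", "header offset", "data type", "interleave", "byte order"):
            fh.write(f"{key} = {meta.pop(key)}\n")
        if cube.wavelengths is not None:
            wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
            fh.write("wavelength = { " + wl + " }\n")
            meta.pop("wavelength", None)
        for key, value in meta.items():
            fh.write(f"{key} = {value}\n")


def crop_roi(cube: Hypercube, roi: RoiSpec) -> Hypercube:
    """Crop a spatial region of interest; wavelengths and metadata carry over.

    Raises
    ------
    ValueError
        If the ROI extends beyond the cube (no silent clamping).
    """
    if roi.row0 + roi.height > cube.rows or roi.col0 + roi.width > cube.cols:
        raise ValueError(
            f"ROI {roi} exceeds cube extent {cube.rows}x{cube.cols}"
        )
    data = cube.data[roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width, :].copy()
    meta = dict(cube.meta)
    meta["samples"] = str(roi.width)
    meta["lines"] = str(roi.height)
    wl = None if cube.wavelengths is None else cube.wavelengths.copy()
    return Hypercube(data=data, wavelengths=wl, meta=meta)


def to_rgb(cube: Hypercube, band_indices: tuple[int, int, int]) -> np.ndarray:
    """Render three chosen bands as an RGB image in [0, 1].

    Each channel is its band min-max rescaled independently; a constant band
    maps to all zeros.
    """
    if len(band_indices) != 3:
        raise ValueError("exactly three band indices are required")
    for b in band_indices:
        if not (0 <= b < cube.bands):
            raise IndexError(f"band index {b} out of range [0, {cube.bands})")
    out = np.zeros((cube.rows, cube.cols, 3), dtype=float)
    for ch, b in enumerate(band_indices):
        band = cube.data[:, :, b].astype(float)
        lo, hi = band.min(), band.max()
        if hi > lo:
            out[:, :, ch] = (band - lo) / (hi - lo)
    return out


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel mask image; nonzero pixels become 1."""
    img = iio.imread(path)
    if img.ndim == 3:
        # a palette/alpha expansion of a truly single-channel image is fine
        if img.shape[2] in (3, 4) and all(
            np.array_equal(img[:, :, 0], img[:, :, c]) for c in range(1, 3)
        ):
            img = img[:, :, 0]
        else:
            raise MaskFormatError(f"mask must be single-channel, got shape {img.shape}")
    elif img.ndim != 2:
        raise MaskFormatError(f"mask must be 2-D, got shape {img.shape}")
    return (np.asarray(img) != 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as a 0/255 single-channel PNG or PGM."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskFormatError("mask must be 2-D")
    if not np.isin(mask, (0, 1)).all():
        raise MaskFormatError("mask values must be in {0, 1}")
    iio.imwrite(path, (mask.astype(np.uint8) * 255))
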
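"""Reading and writing ENVI header/data pairs.

ENVI images are a flat binary payload described by a small text header
(`samples`, `lines`, `bands`, `data type`, `interleave`, `byte order`,
optional `wavelength = { ... }`).  The three interleaves lay the same values
out differently on disk:

    BSQ  band-sequential   (band, line, sample)
    BIL  band-interleaved-by-line   (line, band, sample)
    BIP  band-interleaved-by-pixel  (line, sample, band)

In memory the cube is always (line, sample, band); interleave only matters
here.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

from .hypercube import Hypercube, SignalKind

__all__ = ["read_envi", "write_envi", "EnviFormatError"]

# ENVI numeric codes for the dtypes this package emits/accepts
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


class EnviFormatError(ValueError):
    """Header missing/contradictory keys or payload size mismatch."""


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _parse_list(value: str) -> list[str]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:-1]
    return [tok.strip() for tok in inner.split(",") if tok.strip()]


def _data_path(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem.with_suffix(".dat"), stem.with_suffix(".img"), stem.with_suffix(".raw"), stem):
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no data file found next to {header_path}")


def read_envi(header_path: str | os.PathLike) -> Hypercube:
    """Read an ENVI header/data pair into a (line, sample, band) hypercube."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required key: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _DTYPES:
        raise EnviFormatError(f"unsupported data type code {dtype_code}")
    if "wavelength" not in fields:
        raise EnviFormatError("header lists no wavelengths")
    wavelengths = np.array([float(v) for v in _parse_list(fields["wavelength"])])
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", "0"))

    data_path = _data_path(header_path)
    expected = lines * samples * bands * dtype.itemsize
    actual = data_path.stat().st_size - offset
    if actual != expected:
        raise EnviFormatError(
            f"payload holds {actual} bytes, header implies {expected} "
            f"({lines}x{samples}x{bands} of {dtype.itemsize} bytes)"
        )
    flat = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = flat.reshape(lines, samples, bands)

    kind = fields.get("signal kind", SignalKind.RAW_COUNTS.value)
    try:
        signal_kind = SignalKind(kind)
    except ValueError:
        signal_kind = SignalKind.RAW_COUNTS
    meta = {"description": fields.get("description", "").strip("{} \n")}
    return Hypercube(np.ascontiguousarray(cube), wavelengths, signal_kind, meta)


def write_envi(
    cube: Hypercube,
    header_path: str | os.PathLike,
    interleave: str = "bsq",
) -> Path:
    """Write ``cube`` as an ENVI pair; returns the data-file path.

    Wavelengths are emitted with 8 significant digits so the grid survives a
    round trip to well under 1e-3 nm.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".dat")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype(np.float64)
    code = _DTYPE_CODES[dtype]

    ny, nx, nb = cube.shape
    arr = np.ascontiguousarray(cube.data, dtype=dtype.newbyteorder("<"))
    if interleave == "bsq":
        payload = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = arr.transpose(0, 2, 1)
    else:
        payload = arr
    np.ascontiguousarray(payload).tofile(data_path)

    wl = ", ".join(f"{w:.8g}" for w in cube.wavelengths_nm)
    desc = str(cube.meta.get("description", "hsiauth export"))
    header = (
        "ENVI\n"
        f"description = {{{desc}}}\n"
        f"samples = {nx}\n"
        f"lines = {ny}\n"
        f"bands = {nb}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"signal kind = {cube.signal_kind.value}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return data_path
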
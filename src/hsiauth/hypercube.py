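"""Hypercube data model, radiometric calibration and region bookkeeping.

A hypercube holds a full short-wave-infrared spectrum at every spatial pixel:
two spatial axes (line ``y``, sample ``x``) and one wavelength axis.  Raw
detector counts are converted to reflectance against internal dark/white
references and then to pseudo-absorbance ``A = log10(1/R)``, the scale on
which Beer–Lambert-style linear mixing of constituents is approximately valid
and on which all chemometric modelling in this package operates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalKind",
    "Hypercube",
    "ReferencePair",
    "Region",
    "RegionLayout",
    "CalibrationError",
    "calibrate_reflectance",
    "to_pseudo_absorbance",
    "extract_region_spectra",
]

#: reflectance ceiling tolerating specular pixels
DEFAULT_R_MAX = 1.5
#: reflectance floor preventing infinities in log10(1/R)
DEFAULT_R_EPS = 1e-6


class SignalKind(str, Enum):
    RAW_COUNTS = "raw_counts"
    REFLECTANCE = "reflectance"
    PSEUDO_ABSORBANCE = "pseudo_absorbance"


class CalibrationError(ValueError):
    """White/dark references unusable on at least one band."""


@dataclass
class Hypercube:
    """3-D spectral image in fixed ``(line, sample, band)`` memory order.

    Interleave (BIL/BIP/BSQ) is purely an I/O concern; see :mod:`hsiauth.envi`.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    signal_kind: SignalKind = SignalKind.RAW_COUNTS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.signal_kind = SignalKind(self.signal_kind)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D (line, sample, band) array, got ndim={self.data.ndim}")
        ny, nx, nb = self.data.shape
        if ny == 0 or nx == 0:
            raise ValueError("spatial dimensions must be positive")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != nb:
            raise ValueError(
                f"wavelength vector length {self.wavelengths_nm.size} != band count {nb}"
            )
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValueError("wavelengths must be finite")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (n_pixels, n_bands) view in row-major spatial order."""
        ny, nx, nb = self.data.shape
        return self.data.reshape(ny * nx, nb)


@dataclass
class ReferencePair:
    """Dark and white reference measurements on the scene's band grid.

    Each reference may be a full :class:`Hypercube` of raw counts or a
    per-band vector; cubes are averaged over their spatial extent to a
    per-band vector before use, which suppresses reference noise.
    """

    dark: "Hypercube | np.ndarray"
    white: "Hypercube | np.ndarray"

    def band_means(self) -> tuple[np.ndarray, np.ndarray]:
        dark = _reference_vector(self.dark)
        white = _reference_vector(self.white)
        if dark.shape != white.shape:
            raise ValueError("dark and white references disagree on band count")
        return dark, white


def _reference_vector(ref: "Hypercube | np.ndarray") -> np.ndarray:
    if isinstance(ref, Hypercube):
        return ref.pixels().mean(axis=0)
    arr = np.asarray(ref, dtype=float)
    if arr.ndim != 1:
        raise ValueError("vector reference must be 1-D")
    return arr


# ---------------------------------------------------------------------------
# regions


@dataclass(frozen=True)
class Region:
    """A labelled sample position: half-open rectangle or inclusive disk."""

    label: str
    shape: str  # "rect" | "disk"
    params: tuple[float, ...]  # rect: (y0, x0, y1, x1) half-open; disk: (cy, cx, r)
    class_hint: str | None = None

    def member_mask(self, spatial_shape: tuple[int, int]) -> np.ndarray:
        ny, nx = spatial_shape
        if self.shape == "rect":
            y0, x0, y1, x1 = (int(v) for v in self.params)
            m = np.zeros((ny, nx), dtype=bool)
            m[max(y0, 0) : max(min(y1, ny), 0), max(x0, 0) : max(min(x1, nx), 0)] = True
            return m
        if self.shape == "disk":
            cy, cx, r = self.params
            yy, xx = np.ogrid[:ny, :nx]
            return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass
class RegionLayout:
    regions: list[Region]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")

    def __iter__(self) -> Iterable[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def get(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_csv(self, path) -> None:
        rows = [
            {
                "label": r.label,
                "class_hint": "" if r.class_hint is None else r.class_hint,
                "shape": r.shape,
                "params": ";".join(repr(float(p)) for p in r.params),
            }
            for r in self.regions
        ]
        pd.DataFrame(rows, columns=["label", "class_hint", "shape", "params"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "RegionLayout":
        df = pd.read_csv(path, dtype={"label": str, "class_hint": str, "shape": str, "params": str})
        regions = []
        for row in df.itertuples(index=False):
            hint = None if pd.isna(row.class_hint) or row.class_hint == "" else str(row.class_hint)
            params = tuple(float(v) for v in str(row.params).split(";"))
            regions.append(Region(str(row.label), str(row.shape), params, hint))
        return cls(regions)


# ---------------------------------------------------------------------------
# calibration


def calibrate_reflectance(
    raw: Hypercube,
    refs: ReferencePair,
    r_eps: float = DEFAULT_R_EPS,
    r_max: float = DEFAULT_R_MAX,
) -> Hypercube:
    """Convert raw counts to reflectance against dark/white references.

    ``R = (raw - dark) / (white - dark)`` per band, with the references
    averaged over their spatial extent, then clipped to ``[r_eps, r_max]`` so
    that dead and specular pixels cannot produce infinities downstream.
    """
    if raw.signal_kind is not SignalKind.RAW_COUNTS:
        raise ValueError(f"expected raw_counts cube, got {raw.signal_kind.value}")
    dark, white = refs.band_means()
    if len(dark) != raw.n_bands:
        raise ValueError("reference band count does not match scene")
    span = white - dark
    bad = np.flatnonzero(span <= 0)
    if bad.size:
        raise CalibrationError(
            f"white <= dark on band(s) {bad.tolist()[:8]} "
            f"(wavelengths {raw.wavelengths_nm[bad[:8]].round(1).tolist()} nm)"
        )
    refl = (raw.data.astype(float) - dark) / span
    np.clip(refl, r_eps, r_max, out=refl)
    meta = dict(raw.meta)
    meta["calibration"] = {"r_eps": r_eps, "r_max": r_max}
    return Hypercube(refl, raw.wavelengths_nm, SignalKind.REFLECTANCE, meta)


def to_pseudo_absorbance(refl: Hypercube) -> Hypercube:
    """Pseudo-absorbance ``A = log10(1/R)``; finite by the calibration clip."""
    if refl.signal_kind is not SignalKind.REFLECTANCE:
        raise ValueError(f"expected reflectance cube, got {refl.signal_kind.value}")
    absb = -np.log10(refl.data)
    return Hypercube(absb, refl.wavelengths_nm, SignalKind.PSEUDO_ABSORBANCE, dict(refl.meta))


# ---------------------------------------------------------------------------
# pixel extraction


def extract_region_spectra(
    cube: Hypercube,
    layout: RegionLayout | Sequence[Region],
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Collect masked-in pixels of every region into one labelled pixel matrix.

    Returns a DataFrame with columns ``label``, ``y``, ``x`` and one column per
    band (named by wavelength).  Regions whose masked intersection is empty
    contribute zero rows and raise a warning, not an error.
    """
    ny, nx, nb = cube.shape
    keep = np.ones((ny, nx), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if keep.shape != (ny, nx):
        raise ValueError("mask shape does not match cube")
    regions = list(layout)
    blocks = []
    for region in regions:
        inside = region.member_mask((ny, nx)) & keep
        ys, xs = np.nonzero(inside)
        if ys.size == 0:
            warnings.warn(f"region {region.label!r} has no masked-in pixels", stacklevel=2)
        spectra = cube.data[ys, xs, :]
        block = pd.DataFrame(spectra, columns=[f"{w:.2f}" for w in cube.wavelengths_nm])
        block.insert(0, "x", xs)
        block.insert(0, "y", ys)
        block.insert(0, "label", region.label)
        blocks.append(block)
    if not blocks:
        raise ValueError("layout contains no regions")
    return pd.concat(blocks, ignore_index=True)


def spectra_matrix(df: pd.DataFrame) -> np.ndarray:
    """Band matrix (rows = pixels) from an extract_region_spectra frame."""
    return df.drop(columns=["label", "y", "x"]).to_numpy(dtype=float)
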
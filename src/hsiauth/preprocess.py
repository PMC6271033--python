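"""Spectral pretreatments for pixel matrices.

All operations act row-wise on a (pixels x bands) matrix.  The scatter
corrections (SNV, MSC) remove per-pixel multiplicative and additive
distortions caused by particle size and packing; Savitzky-Golay derivatives
suppress smooth baselines; mean centering is applied last, as part of the
model, and its column means are stored so prediction pixels receive exactly
the treatment the calibration pixels did.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "crop_wavelengths",
    "snv",
    "msc",
    "savgol_derivative",
    "mean_center",
    "PreprocessPlan",
]

_SD_FLOOR = 1e-12


def crop_wavelengths(
    matrix: np.ndarray, wavelengths_nm: np.ndarray, min_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drop all bands with wavelength <= ``min_nm`` (strictly greater kept).

    The short-wavelength end of SWIR spectra is dominated by detector noise
    and carries little constituent information; cropping it sharpens pixel
    classification.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    keep = wavelengths_nm > min_nm
    if not keep.any():
        raise ValueError(f"cropping at {min_nm} nm removes every band")
    return np.asarray(matrix)[:, keep], wavelengths_nm[keep]


def snv(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard normal variate: standardize each row to mean 0, sample SD 1.

    Returns ``(corrected, flags)`` where ``flags`` marks rows whose SD fell
    below 1e-12; those rows are zero-filled rather than divided by ~0.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands per row")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flags = (sd < _SD_FLOOR).ravel()
    safe = np.where(sd < _SD_FLOOR, 1.0, sd)
    out = (x - mu) / safe
    out[flags] = 0.0
    return out, flags


def msc(
    matrix: np.ndarray, reference: "np.ndarray | str" = "mean"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x ~ a + b*ref (ordinary least squares); the
    corrected row is (x - a)/b.  Rows with |b| < 1e-12 cannot be rescaled and
    pass through unchanged, flagged.  Returns (corrected, flags, reference).
    """
    x = np.asarray(matrix, dtype=float)
    ref = x.mean(axis=0) if isinstance(reference, str) else np.asarray(reference, dtype=float)
    if ref.shape != (x.shape[1],):
        raise ValueError("reference length must equal band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValueError("MSC reference is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * ref.mean()
    flags = np.abs(b) < _SD_FLOOR
    safe_b = np.where(flags, 1.0, b)
    out = (x - a[:, None]) / safe_b[:, None]
    out[flags] = x[flags]
    return out, flags, ref


def savgol_derivative(
    matrix: np.ndarray, window: int = 11, polyorder: int = 2, deriv: int = 1
) -> np.ndarray:
    """Row-wise Savitzky-Golay derivative with respect to band index.

    The band grid is near-uniform (~6.25 nm), so the index-spaced derivative
    differs from a per-nm derivative only by a constant factor that the
    bilinear models downstream absorb.
    """
    x = np.asarray(matrix, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if deriv not in (1, 2):
        raise ValueError("deriv must be 1 or 2")
    if window > x.shape[1]:
        raise ValueError(f"window {window} exceeds band count {x.shape[1]}")
    return savgol_filter(x, window_length=window, polyorder=polyorder, deriv=deriv, axis=1)


def mean_center(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column means; returns (centered, means) for later replay."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("mean centering needs at least 2 rows")
    means = x.mean(axis=0)
    return x - means, means


# ---------------------------------------------------------------------------


@dataclass
class PreprocessPlan:
    """Ordered pretreatment recipe with fit/replay semantics.

    ``steps`` is a list of ``(name, params)`` pairs drawn from
    ``crop_wavelengths``, ``snv``, ``msc``, ``savgol_derivative`` and
    ``mean_center``.  ``fit_transform`` records the state a second pass needs
    (crop mask via min_nm, MSC reference, column means) so ``transform``
    treats prediction pixels identically to calibration pixels.
    """

    steps: list[tuple[str, dict]] = field(
        default_factory=lambda: [
            ("crop_wavelengths", {"min_nm": 996.0}),
            ("snv", {}),
        ]
    )
    state_: dict[str, Any] = field(default_factory=dict, repr=False)

    _ORDER = ("crop_wavelengths", "snv", "msc", "savgol_derivative", "mean_center")

    def __post_init__(self) -> None:
        names = [n for n, _ in self.steps]
        unknown = set(names) - set(self._ORDER)
        if unknown:
            raise ValueError(f"unknown preprocess step(s): {sorted(unknown)}")
        if "crop_wavelengths" in names and names[0] != "crop_wavelengths":
            raise ValueError("crop_wavelengths must come first")
        if "mean_center" in names and names[-1] != "mean_center":
            raise ValueError("mean_center must come last")
        for name, params in self.steps:
            if name == "savgol_derivative":
                w = int(params.get("window", 11))
                p = int(params.get("polyorder", 2))
                if w % 2 == 0 or w <= p:
                    raise ValueError("savgol window must be odd and > polyorder")

    def fit_transform(
        self, matrix: np.ndarray, wavelengths_nm: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        self.state_ = {}
        return self._apply(matrix, wavelengths_nm, fitting=True)

    def transform(
        self, matrix: np.ndarray, wavelengths_nm: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        if not self.state_ and any(n in ("msc", "mean_center") for n, _ in self.steps):
            raise RuntimeError("plan has stateful steps but was never fitted")
        return self._apply(matrix, wavelengths_nm, fitting=False)

    def _apply(
        self, matrix: np.ndarray, wavelengths_nm: np.ndarray, fitting: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(matrix, dtype=float)
        wl = np.asarray(wavelengths_nm, dtype=float)
        for name, params in self.steps:
            if name == "crop_wavelengths":
                x, wl = crop_wavelengths(x, wl, float(params["min_nm"]))
            elif name == "snv":
                x, _ = snv(x)
            elif name == "msc":
                if fitting:
                    x, _, ref = msc(x, params.get("reference", "mean"))
                    self.state_["msc_reference"] = ref
                else:
                    x, _, _ = msc(x, self.state_["msc_reference"])
            elif name == "savgol_derivative":
                x = savgol_derivative(
                    x,
                    window=int(params.get("window", 11)),
                    polyorder=int(params.get("polyorder", 2)),
                    deriv=int(params.get("deriv", 1)),
                )
            elif name == "mean_center":
                if fitting:
                    x, means = mean_center(x)
                    self.state_["column_means"] = means
                else:
                    x = x - self.state_["column_means"]
        return x, wl

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        state = {
            k: v.tolist() if isinstance(v, np.ndarray) else v for k, v in self.state_.items()
        }
        return {"steps": [[n, p] for n, p in self.steps], "state": state}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessPlan":
        plan = cls(steps=[(n, dict(p)) for n, p in d["steps"]])
        plan.state_ = {
            k: np.asarray(v, dtype=float) if isinstance(v, list) else v
            for k, v in d.get("state", {}).items()
        }
        return plan
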
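"""Automated pixel masking: background, dead pixels and edge effects.

Interactive score-plot lassoing (the usual workflow in commercial imaging
software) is replaced by a deterministic, reproducible procedure: the first
principal component of the whole image separates sample from stage, an Otsu
threshold on the PC1 score histogram splits the two populations, and a binary
erosion trims mixed boundary pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .hypercube import Hypercube, SignalKind

__all__ = ["PixelMask", "flag_dead_pixels", "segment_background", "erode_edges", "build_mask"]

# provenance codes
KEPT, BACKGROUND, DEAD, EDGE = 0, 1, 2, 3
_PROVENANCE_NAMES = {KEPT: "kept", BACKGROUND: "background", DEAD: "dead", EDGE: "edge"}

_DEAD_VAR = 1e-10
_MIN_KEPT_FRACTION = 0.01


@dataclass
class PixelMask:
    """Boolean keep-grid plus a per-pixel removal reason."""

    keep: np.ndarray
    provenance: np.ndarray  # int codes, see _PROVENANCE_NAMES

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        if self.keep.shape != self.provenance.shape:
            raise ValueError("keep and provenance shapes differ")
        if not np.array_equal(self.keep, self.provenance == KEPT):
            raise ValueError("keep grid inconsistent with provenance")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def provenance_names(self) -> np.ndarray:
        out = np.empty(self.keep.shape, dtype=object)
        for code, name in _PROVENANCE_NAMES.items():
            out[self.provenance == code] = name
        return out

    def validate_coverage(self) -> None:
        if self.n_kept < _MIN_KEPT_FRACTION * self.keep.size:
            raise ValueError(
                f"mask keeps {self.n_kept}/{self.keep.size} pixels (<1%); "
                "masking parameters are likely wrong for this scene"
            )


def flag_dead_pixels(cube: Hypercube) -> np.ndarray:
    """Dead = spectrally constant (variance < 1e-10) or any non-finite value."""
    px = cube.data
    finite = np.isfinite(px).all(axis=2)
    var = np.nanvar(np.where(np.isfinite(px), px, np.nan), axis=2)
    return ~finite | (var < _DEAD_VAR)


def segment_background(cube: Hypercube, exclude: np.ndarray | None = None,
                       background: str = "low") -> np.ndarray:
    """Split sample from stage on the PC1 score histogram (Otsu threshold).

    The dominant variance direction of a whole-scene absorbance image is the
    sample-vs-stage contrast, so one mean-centered principal component plus a
    histogram threshold recovers the stage.  Of the two score groups, the one
    whose mean spectrum has the lower overall absorbance is called background
    when ``background="low"`` (a bare stage reflects more than powder beds);
    ``background="high"`` flips the orientation.

    Returns a boolean grid that is True on background pixels.  ``exclude``
    marks pixels (e.g. dead ones) left out of the PCA and threshold.
    """
    if cube.signal_kind is not SignalKind.PSEUDO_ABSORBANCE:
        raise ValueError("background segmentation expects a pseudo-absorbance cube")
    if background not in ("low", "high"):
        raise ValueError("background must be 'low' or 'high'")
    ny, nx, nb = cube.shape
    if ny * nx < 2:
        raise ValueError("need at least 2 spatial pixels")
    x = cube.pixels()
    use = np.ones(ny * nx, dtype=bool) if exclude is None else ~exclude.reshape(-1)
    xs = x[use]
    xc = xs - xs.mean(axis=0)
    total = float((xc * xc).sum())
    if total <= 0:
        raise ValueError("image is spatially uniform; cannot segment background")
    score = _pc1_scores(xc)
    try:
        thresh = threshold_otsu(score)
        lo = score <= thresh
    except ValueError:
        lo = score <= 0.0
    hi = ~lo
    if not lo.any() or not hi.any():
        lo = score <= 0.0
        hi = ~lo
        if not lo.any() or not hi.any():
            raise ValueError("degenerate score histogram; cannot segment background")
    mean_lo = float(xs[lo].mean())
    mean_hi = float(xs[hi].mean())
    bg_is_lo = mean_lo < mean_hi
    if background == "high":
        bg_is_lo = not bg_is_lo
    bg_used = lo if bg_is_lo else hi
    bg = np.zeros(ny * nx, dtype=bool)
    bg[np.flatnonzero(use)[bg_used]] = True
    return bg.reshape(ny, nx)


def _pc1_scores(xc: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """First NIPALS component scores of a pre-centered matrix (no RNG)."""
    t = xc[:, int(np.argmax((xc * xc).sum(axis=0)))].astype(float).copy()
    if not t.any():
        t = xc.sum(axis=1)
    for _ in range(max_iter):
        p = xc.T @ t
        p /= np.linalg.norm(p)
        t_new = xc @ p
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1.0):
            t = t_new
            break
        t = t_new
    return t


def erode_edges(mask: PixelMask, iterations: int = 1) -> PixelMask:
    """Trim the kept set by 4-connected binary erosion, `iterations` times."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return PixelMask(mask.keep.copy(), mask.provenance.copy())
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    eroded = ndimage.binary_erosion(mask.keep, structure=structure, iterations=iterations)
    provenance = mask.provenance.copy()
    provenance[mask.keep & ~eroded] = EDGE
    return PixelMask(eroded, provenance)


def build_mask(cube: Hypercube, edge_iterations: int = 1, background: str = "low") -> PixelMask:
    """Full masking pipeline: dead pixels, then background, then edge erosion."""
    dead = flag_dead_pixels(cube)
    bg = segment_background(cube, exclude=dead, background=background)
    provenance = np.full(cube.shape[:2], KEPT, dtype=np.uint8)
    provenance[bg] = BACKGROUND
    provenance[dead] = DEAD  # dead wins over background
    mask = PixelMask(provenance == KEPT, provenance)
    mask = erode_edges(mask, edge_iterations)
    mask.validate_coverage()
    return mask
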
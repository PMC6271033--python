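"""NIPALS principal component analysis for pixel matrices.

NIPALS extracts one component at a time by alternating least squares with
deflation — the chemometric convention, and cheap when only a handful of
components is needed from very many pixels.  Explained variance is tracked
per component (R2X) and cumulatively (R2X_cum).  A truncated SVD gives
identical answers up to sign and serves as the independent oracle in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .masking import PixelMask

__all__ = [
    "PCAModel",
    "ScoreImage",
    "fit_pca",
    "project_pixels",
    "make_score_image",
    "loadings_line_plot_data",
    "select_n_components",
]


@dataclass
class PCAModel:
    mean: np.ndarray  # band vector
    loadings: np.ndarray  # bands x A, columns unit norm
    scores: np.ndarray  # pixels x A
    r2x_per_component: np.ndarray
    r2x_cum: np.ndarray
    n_components: int
    meta: dict = field(default_factory=dict)


@dataclass
class ScoreImage:
    values: np.ndarray  # spatial grid, NaN outside kept pixels
    component: int
    vmin: float
    vmax: float


def _nipals_component(
    x: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One NIPALS iteration cycle on a centered/deflated matrix.

    Returns (scores t, unit loading p, converged).
    """
    start = int(np.argmax((x * x).sum(axis=0)))
    t = x[:, start].astype(float).copy()
    if not np.any(t):
        t = x.sum(axis=1)
    converged = False
    for _ in range(max_iter):
        p = x.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = x @ p
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1.0):
            t = t_new
            converged = True
            break
        t = t_new
    return t, p, converged


def fit_pca(
    matrix: np.ndarray,
    n_components: int,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PCAModel:
    """Fit a NIPALS PCA with internal mean centering.

    Sign convention: each loading column is flipped so its largest-magnitude
    element is positive, which makes repeated runs comparable.
    """
    x = np.asarray(matrix, dtype=float)
    n, p_dim = x.shape
    if not 1 <= n_components <= min(n, p_dim):
        raise ValueError(f"n_components must be in [1, {min(n, p_dim)}]")
    mean = x.mean(axis=0)
    resid = x - mean
    ss_total = float((resid * resid).sum())
    if ss_total <= 0:
        raise ValueError("matrix has zero variance")

    scores = np.empty((n, n_components))
    loadings = np.empty((p_dim, n_components))
    r2 = np.empty(n_components)
    extracted = 0
    for a in range(n_components):
        if float((resid * resid).sum()) <= 1e-12 * ss_total:
            break  # matrix exhausted below working precision
        t, p, converged = _nipals_component(resid, tol, max_iter)
        if not converged:
            warnings.warn(f"NIPALS component {a + 1} did not converge; accepting current vector",
                          stacklevel=2)
        if p[np.argmax(np.abs(p))] < 0:
            p = -p
            t = -t
        resid -= np.outer(t, p)
        scores[:, a] = t
        loadings[:, a] = p
        r2[a] = (t @ t) / ss_total
        extracted = a + 1
    return PCAModel(
        mean=mean,
        loadings=loadings[:, :extracted],
        scores=scores[:, :extracted],
        r2x_per_component=r2[:extracted],
        r2x_cum=np.cumsum(r2[:extracted]),
        n_components=extracted,
    )


def project_pixels(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Scores of new pixels: (X - mean) @ P."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"band count {x.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    return (x - model.mean) @ model.loadings


def make_score_image(model: PCAModel, mask: "PixelMask | np.ndarray", component: int) -> ScoreImage:
    """Scatter one component's scores back onto the spatial grid.

    Rows of the training matrix must correspond to kept pixels in row-major
    order, which is how extraction produces them.
    """
    keep = mask.keep if isinstance(mask, PixelMask) else np.asarray(mask, dtype=bool)
    if component >= model.n_components:
        raise ValueError(f"component {component} not in model (A={model.n_components})")
    if int(keep.sum()) != model.scores.shape[0]:
        raise ValueError("mask kept-pixel count does not match score rows")
    grid = np.full(keep.shape, np.nan)
    grid[keep] = model.scores[:, component]
    bound = float(np.nanmax(np.abs(grid))) if np.isfinite(grid).any() else 1.0
    return ScoreImage(values=grid, component=component, vmin=-bound, vmax=bound)


def loadings_line_plot_data(
    model: PCAModel,
    wavelengths_nm: np.ndarray,
    component: int = 0,
    window_nm: float = 300.0,
) -> dict:
    """Loading vector vs wavelength plus the most discriminating window.

    The window is the contiguous wavelength span (of width ``window_nm``)
    maximizing mean |loading| — the region a spectroscopist would inspect for
    constituent bands that drive the separation.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if component >= model.n_components:
        raise ValueError("component out of range")
    loading = model.loadings[:, component]
    if len(wl) != len(loading):
        raise ValueError("wavelength vector does not match loading length")
    abs_l = np.abs(loading)
    best_start, best_score = 0, -np.inf
    for i in range(len(wl)):
        j = int(np.searchsorted(wl, wl[i] + window_nm, side="right"))
        if j <= i:
            continue
        score = abs_l[i:j].mean()
        if score > best_score + 1e-15:
            best_score, best_start = score, i
    j = int(np.searchsorted(wl, wl[best_start] + window_nm, side="right"))
    flat = bool(np.ptp(abs_l) < 1e-12)
    return {
        "wavelengths_nm": wl,
        "loading": loading,
        "window_nm": (float(wl[best_start]), float(wl[j - 1])),
        "window_mean_abs_loading": float(best_score),
        "non_informative": flat,
    }


def select_n_components(
    matrix: np.ndarray,
    max_components: int,
    n_segments: int = 7,
    gain_threshold: float = 0.01,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> int:
    """Pick the component count by row-wise cross-validated reconstruction.

    Rows are split into ``n_segments`` random segments; for each left-out
    segment a PCA is fit on the rest and every element of a held-out row is
    predicted from the row's *other* bands (leave-one-band-out through the
    exact least-squares leverage identity, leverage h_j = sum_a P_ja^2), so a
    component only lowers PRESS when the loading structure generalizes —
    plain projection would flatter pure noise.  Q2X_cum(a) = 1 - PRESS(a)/SS,
    pooled over segments.  Components are accepted while the marginal gain is
    at least ``gain_threshold``; the floor is one component.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if n < n_segments:
        raise ValueError("fewer rows than CV segments")
    max_a = min(max_components, x.shape[1], n - (n // n_segments) - 1)
    max_a = max(max_a, 1)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % n_segments

    press = np.zeros(max_a)
    ss = 0.0
    for seg in range(n_segments):
        test = assignment == seg
        train = ~test
        model = fit_pca(x[train], max_a, tol=tol, max_iter=max_iter)
        xc = x[test] - model.mean
        ss += float((xc * xc).sum())
        resid = xc.copy()
        leverage = np.zeros(x.shape[1])
        last = 0.0
        for a in range(max_a):
            if a < model.n_components:
                p = model.loadings[:, a]
                resid -= np.outer(resid @ p, p)
                leverage += p * p
                loo = resid / np.maximum(1.0 - leverage, 1e-8)
                last = float((loo * loo).sum())
            press[a] += last
    q2 = 1.0 - press / ss
    chosen = 1
    for a in range(1, max_a):
        gain = q2[a] - q2[a - 1]
        if gain < gain_threshold:
            break
        chosen = a + 1
    return chosen
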
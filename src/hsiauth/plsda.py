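"""PLS2 discriminant analysis with dummy-Y coding and cut-off classification.

The classifier regresses a one-hot class matrix Y on the pixel spectra X with
NIPALS PLS2.  Model complexity is chosen from Q2Y_cum, the cross-validated
fraction of Y-variance predicted (1 - PRESS/SS, PRESS pooled over random
segments).  A pixel is assigned to a class when its predicted dummy value
falls inside a cut-off window (default [0.5, 1.5]); pixels matching no class
window are reported as "no class" — material unlike anything calibrated,
e.g. excipients or processed extracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube import Region, RegionLayout

__all__ = [
    "ClassCodebook",
    "PLSDAModel",
    "ClassPredictionImage",
    "encode_classes",
    "fit_plsda",
    "predict_continuous",
    "classify_pixels",
    "quantify_composition",
    "external_validation",
    "NO_CLASS",
    "MASKED",
]

NO_CLASS = "no_class"
MASKED = "masked"

DEFAULT_MIN_CUT = 0.5
DEFAULT_MAX_CUT = 1.5


@dataclass(frozen=True)
class ClassCodebook:
    """Ordered class labels with one-hot encoding."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least 2 classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("class labels must be unique")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    def __len__(self) -> int:
        return len(self.labels)


def encode_classes(labels, codebook: ClassCodebook) -> np.ndarray:
    """One-hot dummy matrix; rows sum to 1."""
    idx = np.array([codebook.index(l) for l in labels])
    y = np.zeros((len(idx), len(codebook)))
    y[np.arange(len(idx)), idx] = 1.0
    return y


@dataclass
class CVSpec:
    """Random-segment cross-validation: each segment left out once."""

    n_segments: int = 7
    seed: int = 0
    stratified: bool = True


@dataclass
class PLSDAModel:
    codebook: ClassCodebook
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # bands x A
    x_loadings: np.ndarray  # bands x A
    y_loadings: np.ndarray  # classes x A
    scores: np.ndarray  # training pixels x A
    coef: np.ndarray  # bands x classes, for the chosen A
    n_factors: int
    r2x_cum: np.ndarray
    r2y_cum: np.ndarray
    q2y_cum: np.ndarray
    cv_spec: CVSpec = field(default_factory=CVSpec)
    min_cut: float = DEFAULT_MIN_CUT
    max_cut: float = DEFAULT_MAX_CUT
    meta: dict = field(default_factory=dict)


@dataclass
class ClassPredictionImage:
    """Per-pixel hard labels plus the continuous dummy-Y predictions."""

    labels: np.ndarray  # object grid: class label, NO_CLASS or MASKED
    yhat: np.ndarray  # (ny, nx, n_classes), NaN at masked pixels
    codebook: ClassCodebook


# ---------------------------------------------------------------------------
# fitting


def _pls_nipals(
    x: np.ndarray, y: np.ndarray, n_factors: int, tol: float = 1e-10, max_iter: int = 500
) -> dict:
    """NIPALS PLS2 on pre-centered X, Y; deflates both blocks.

    Returns W, P (X-loadings), Q (Y-loadings), T and cumulative R2X/R2Y.
    """
    ex, ey = x.copy(), y.copy()
    n, p_dim = x.shape
    m = y.shape[1]
    ssx = float((x * x).sum())
    ssy = float((y * y).sum())
    W = np.zeros((p_dim, n_factors))
    P = np.zeros((p_dim, n_factors))
    Q = np.zeros((m, n_factors))
    T = np.zeros((n, n_factors))
    r2x = np.zeros(n_factors)
    r2y = np.zeros(n_factors)
    for a in range(n_factors):
        u = ey[:, int(np.argmax((ey * ey).sum(axis=0)))].copy()
        if not np.any(u):
            warnings.warn(f"Y block exhausted before factor {a + 1}", stacklevel=2)
            W, P, Q, T = W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
            r2x, r2y = r2x[:a], r2y[:a]
            break
        t = np.zeros(n)
        w = np.zeros(p_dim)
        q = np.zeros(m)
        converged = False
        for _ in range(max_iter):
            w = ex.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = ex @ w
            q = ey.T @ t_new / (t_new @ t_new)
            u = ey @ q / (q @ q)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            warnings.warn(f"PLS factor {a + 1} did not converge; accepting current vector",
                          stacklevel=2)
        if w[np.argmax(np.abs(w))] < 0:
            w, t, q = -w, -t, -q
        tt = t @ t
        p_vec = ex.T @ t / tt
        ex = ex - np.outer(t, p_vec)
        ey = ey - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t
        r2x[a] = 1.0 - float((ex * ex).sum()) / ssx
        r2y[a] = 1.0 - float((ey * ey).sum()) / ssy
    return {"W": W, "P": P, "Q": Q, "T": T, "r2x_cum": r2x, "r2y_cum": r2y}


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray, a: int) -> np.ndarray:
    """Regression coefficients B for the first ``a`` factors: X·B ≈ Y."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def _cv_assignment(y: np.ndarray, spec: CVSpec) -> np.ndarray:
    """Segment membership, drawn once; stratified by class to avoid empty-class folds."""
    n = y.shape[0]
    rng = np.random.default_rng(spec.seed)
    assignment = np.empty(n, dtype=int)
    if spec.stratified and y.shape[1] > 1:
        cls = y.argmax(axis=1)
        for c in np.unique(cls):
            idx = np.flatnonzero(cls == c)
            perm = rng.permutation(len(idx))
            assignment[idx[perm]] = np.arange(len(idx)) % spec.n_segments
    else:
        assignment = rng.permutation(n) % spec.n_segments
    return assignment


def cross_validated_q2y(
    x: np.ndarray, y: np.ndarray, max_factors: int, cv_spec: CVSpec
) -> np.ndarray:
    """Q2Y_cum(a) = 1 - PRESS(a)/SS(Y centered), PRESS pooled over segments."""
    n = x.shape[0]
    if n < cv_spec.n_segments:
        raise ValueError(f"{n} rows < {cv_spec.n_segments} CV segments")
    assignment = _cv_assignment(y, cv_spec)
    yc_full = y - y.mean(axis=0)
    ssy = float((yc_full * yc_full).sum())
    press = np.zeros(max_factors)
    for seg in range(cv_spec.n_segments):
        test = assignment == seg
        train = ~test
        xm, ym = x[train].mean(axis=0), y[train].mean(axis=0)
        fit = _pls_nipals(x[train] - xm, y[train] - ym, max_factors)
        n_avail = fit["W"].shape[1]
        xt = x[test] - xm
        for a in range(max_factors):
            aa = min(a + 1, n_avail)
            b = _coefficients(fit["W"], fit["P"], fit["Q"], aa)
            resid = y[test] - (xt @ b + ym)
            press[a] += float((resid * resid).sum())
    return 1.0 - press / ssy


def fit_plsda(
    x: np.ndarray,
    y: np.ndarray,
    codebook: ClassCodebook,
    max_factors: int = 10,
    cv_spec: CVSpec | None = None,
    gain_threshold: float = 0.01,
    min_cut: float = DEFAULT_MIN_CUT,
    max_cut: float = DEFAULT_MAX_CUT,
) -> PLSDAModel:
    """Fit PLS-DA, choosing the factor count from cross-validated Q2Y_cum.

    Factors are added while each one raises Q2Y_cum by at least
    ``gain_threshold``; the floor is one factor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if y.shape[1] != len(codebook):
        raise ValueError("Y column count does not match codebook")
    if min_cut >= max_cut:
        raise ValueError("min_cut must be < max_cut")
    cv_spec = cv_spec or CVSpec()
    max_factors = min(max_factors, x.shape[1], x.shape[0] - 1)

    q2 = cross_validated_q2y(x, y, max_factors, cv_spec)
    n_factors = 1
    for a in range(1, max_factors):
        if q2[a] - q2[a - 1] < gain_threshold:
            break
        n_factors = a + 1

    xm, ym = x.mean(axis=0), y.mean(axis=0)
    fit = _pls_nipals(x - xm, y - ym, n_factors)
    n_factors = fit["W"].shape[1]
    coef = _coefficients(fit["W"], fit["P"], fit["Q"], n_factors)
    return PLSDAModel(
        codebook=codebook,
        x_mean=xm,
        y_mean=ym,
        weights=fit["W"],
        x_loadings=fit["P"],
        y_loadings=fit["Q"],
        scores=fit["T"],
        coef=coef,
        n_factors=n_factors,
        r2x_cum=fit["r2x_cum"],
        r2y_cum=fit["r2y_cum"],
        q2y_cum=q2[:n_factors],
        cv_spec=cv_spec,
        min_cut=min_cut,
        max_cut=max_cut,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_continuous(model: PLSDAModel, x_new: np.ndarray) -> np.ndarray:
    """Continuous dummy-Y predictions: (X - x_mean) @ B + y_mean."""
    x_new = np.asarray(x_new, dtype=float)
    if x_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"band count {x_new.shape[1]} does not match model ({model.x_mean.shape[0]})"
        )
    return (x_new - model.x_mean) @ model.coef + model.y_mean


def classify_yhat(
    yhat: np.ndarray,
    codebook: ClassCodebook,
    min_cut: float = DEFAULT_MIN_CUT,
    max_cut: float = DEFAULT_MAX_CUT,
) -> np.ndarray:
    """Hard labels from continuous predictions via the cut-off window.

    Candidates are classes whose prediction lies in [min_cut, max_cut]; a
    single candidate wins, several are resolved by argmax of Yhat (first
    index on exact ties), none means "no class".
    """
    if min_cut >= max_cut:
        raise ValueError("min_cut must be < max_cut")
    yhat = np.asarray(yhat, dtype=float)
    in_window = (yhat >= min_cut) & (yhat <= max_cut)
    masked = np.where(in_window, yhat, -np.inf)
    winner = masked.argmax(axis=1)
    any_candidate = in_window.any(axis=1)
    labels = np.array([codebook.labels[i] for i in winner], dtype=object)
    labels[~any_candidate] = NO_CLASS
    return labels


def classify_pixels(
    model: PLSDAModel,
    yhat_grid: np.ndarray,
    mask: np.ndarray,
    min_cut: float | None = None,
    max_cut: float | None = None,
) -> ClassPredictionImage:
    """Apply the cut-off rule to a (ny, nx, classes) prediction grid."""
    lo = model.min_cut if min_cut is None else min_cut
    hi = model.max_cut if max_cut is None else max_cut
    keep = np.asarray(mask, dtype=bool)
    ny, nx, _ = yhat_grid.shape
    labels = np.full((ny, nx), MASKED, dtype=object)
    flat = classify_yhat(yhat_grid[keep], model.codebook, lo, hi)
    labels[keep] = flat
    yhat_out = np.where(keep[:, :, None], yhat_grid, np.nan)
    return ClassPredictionImage(labels=labels, yhat=yhat_out, codebook=model.codebook)


# ---------------------------------------------------------------------------
# reporting


def quantify_composition(
    pred: ClassPredictionImage,
    layout: RegionLayout,
    mask: np.ndarray,
) -> pd.DataFrame:
    """Per-region class percentages over kept pixels — the product report.

    Columns: region label, claimed class (if any), one percentage column per
    class plus "no class", kept pixel count, dominant class, and a verdict
    comparing the dominant class with the claim.  Percentages use kept
    (non-background) pixels as denominator and sum to 100 per region.
    """
    keep = np.asarray(mask, dtype=bool)
    classes = list(pred.codebook.labels)
    rows = []
    for region in layout:
        inside = region.member_mask(keep.shape) & keep
        n_px = int(inside.sum())
        row: dict = {"region": region.label, "label_claim": region.class_hint or ""}
        if n_px == 0:
            for c in classes + [NO_CLASS]:
                row[f"pct_{c}"] = np.nan
            row.update(n_pixels=0, dominant="", verdict="unevaluable")
            rows.append(row)
            continue
        labels_here = pred.labels[inside]
        pcts = {}
        for c in classes + [NO_CLASS]:
            pcts[c] = 100.0 * float(np.sum(labels_here == c)) / n_px
            row[f"pct_{c}"] = pcts[c]
        dominant = max(classes + [NO_CLASS], key=lambda c: pcts[c])
        row["n_pixels"] = n_px
        row["dominant"] = dominant
        if not region.class_hint:
            verdict = ""
        elif dominant == NO_CLASS:
            verdict = "no_authentic_material"
        elif dominant in region.class_hint.split("+"):
            verdict = "match"
        else:
            verdict = "mismatch"
        row["verdict"] = verdict
        rows.append(row)
    cols = (
        ["region", "label_claim"]
        + [f"pct_{c}" for c in classes + [NO_CLASS]]
        + ["n_pixels", "dominant", "verdict"]
    )
    return pd.DataFrame(rows, columns=cols)


def external_validation(
    pred: ClassPredictionImage,
    regions: "RegionLayout | list[Region]",
    mask: np.ndarray,
) -> dict:
    """Held-out validation against regions whose class_hint is ground truth.

    Returns per-region dominant-class accuracy, a pixel confusion matrix
    (rows = true class, columns = predicted incl. no_class) and the
    misclassified-pixel fraction.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("empty test set")
    keep = np.asarray(mask, dtype=bool)
    classes = list(pred.codebook.labels)
    pred_cols = classes + [NO_CLASS]
    confusion = pd.DataFrame(0, index=classes, columns=pred_cols, dtype=int)
    region_rows = []
    for region in regions:
        truth = region.class_hint
        if truth not in classes:
            raise ValueError(f"region {region.label!r} has no usable class_hint")
        inside = region.member_mask(keep.shape) & keep
        labels_here = pred.labels[inside]
        n_px = int(inside.sum())
        counts = {c: int(np.sum(labels_here == c)) for c in pred_cols}
        for c, k in counts.items():
            confusion.loc[truth, c] += k
        dominant = max(pred_cols, key=lambda c: counts[c]) if n_px else ""
        region_rows.append(
            {"region": region.label, "true_class": truth, "n_pixels": n_px,
             "dominant": dominant, "dominant_correct": dominant == truth}
        )
    region_df = pd.DataFrame(region_rows)
    total = int(confusion.to_numpy().sum())
    correct = int(np.trace(confusion.to_numpy()[:, : len(classes)]))
    return {
        "regions": region_df,
        "confusion": confusion,
        "region_accuracy": float(region_df["dominant_correct"].mean()),
        "pixel_accuracy": correct / total if total else float("nan"),
        "misclassified_fraction": 1.0 - correct / total if total else float("nan"),
    }
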
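"""Config-driven orchestration: simulate - calibrate - mask - preprocess -
train - predict - report.

`run_train` fits the whole chemometric chain on a labelled scene and writes a
single deterministic model archive plus QC tables; `run_predict` applies a
saved model to a new scene and writes the per-region composition report.
`replicate` chains simulate, train and predict on the built-in study replica
from one seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envi
from .archive import load_archive, save_archive
from .hypercube import (
    Hypercube,
    RegionLayout,
    ReferencePair,
    calibrate_reflectance,
    extract_region_spectra,
    spectra_matrix,
    to_pseudo_absorbance,
)
from .masking import PixelMask, build_mask
from .pca import PCAModel, fit_pca, loadings_line_plot_data, select_n_components
from .plsda import (
    ClassCodebook,
    CVSpec,
    PLSDAModel,
    classify_pixels,
    encode_classes,
    external_validation,
    fit_plsda,
    predict_continuous,
    quantify_composition,
)
from .preprocess import PreprocessPlan
from .synthetic import SPECIES, Scene, make_study_replica

__all__ = ["RunConfig", "run_train", "run_predict", "replicate", "TrainResult"]


_SCHEMA = {
    "version": int,
    "seed": int,
    "inputs": dict,
    "simulate": dict,
    "preprocess": dict,
    "masking": dict,
    "pca": dict,
    "plsda": dict,
    "train": dict,
    "output_dir": str,
}

_SUBKEYS = {
    "inputs": {"scene_header", "dark_header", "white_header", "layout_csv"},
    "simulate": {"preset", "noise_sigma", "scatter_sigma", "offset_sigma", "shape", "n_bands"},
    "preprocess": {"steps"},
    "masking": {"edge_iterations", "background"},
    "pca": {"max_components", "gain_threshold"},
    "plsda": {"max_factors", "gain_threshold", "min_cut", "max_cut", "n_segments"},
    "train": {"max_pixels_per_region", "split"},
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are hard errors."""

    seed: int = 0
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=lambda: {"preset": "study_replica"})
    preprocess: dict = field(default_factory=dict)
    masking: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    plsda: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    output_dir: str = "hsiauth_run"
    version: int = 1

    def __post_init__(self) -> None:
        lo = float(self.plsda.get("min_cut", 0.5))
        hi = float(self.plsda.get("max_cut", 1.5))
        if lo >= hi:
            raise ValueError(f"min_cut ({lo}) must be < max_cut ({hi})")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, allowed in _SUBKEYS.items():
            sub = raw.get(key, {})
            extra = set(sub) - allowed
            if extra:
                raise ValueError(f"unknown key(s) under {key!r}: {sorted(extra)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def make_plan(self) -> PreprocessPlan:
        steps = self.preprocess.get("steps")
        if steps is None:
            return PreprocessPlan()
        return PreprocessPlan(steps=[(name, dict(params or {})) for name, params in steps])


@dataclass
class TrainResult:
    plan: PreprocessPlan
    pca: PCAModel
    plsda: PLSDAModel
    mask: PixelMask
    wavelengths_used: np.ndarray
    calibration_labels: list[str]
    test_labels: list[str]
    qc: dict
    x_train: np.ndarray | None = None  # preprocessed calibration pixels
    labels_train: np.ndarray | None = None
    archive_path: Path | None = None


# ---------------------------------------------------------------------------
# scene access


def load_scene_inputs(cfg: RunConfig) -> tuple[Hypercube, ReferencePair, RegionLayout]:
    inputs = cfg.inputs
    raw = envi.read_envi(inputs["scene_header"])
    dark = envi.read_envi(inputs["dark_header"])
    white = envi.read_envi(inputs["white_header"])
    layout = RegionLayout.from_csv(inputs["layout_csv"])
    return raw, ReferencePair(dark, white), layout


def prepare_absorbance(raw: Hypercube, refs: ReferencePair) -> Hypercube:
    return to_pseudo_absorbance(calibrate_reflectance(raw, refs))


def split_regions_stratified(
    layout: RegionLayout, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded 50/50 calibration/test split of labelled regions, stratified by
    class; when a class splits into two equal sub-groups (label prefix before
    '-', e.g. root/leaf wells), each sub-group contributes to both halves."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for region in layout:
        if region.class_hint:
            by_class.setdefault(region.class_hint, []).append(region.label)
    calib: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        labels = sorted(by_class[cls])
        prefixes: dict[str, list[str]] = {}
        for lab in labels:
            prefixes.setdefault(lab.split("-")[0], []).append(lab)
        half = len(labels) // 2
        if len(prefixes) == 2 and len(set(map(len, (v for v in prefixes.values())))) == 1:
            groups = [sorted(v) for _, v in sorted(prefixes.items())]
            big = int(rng.integers(0, 2))  # which sub-group contributes the extra well
            for gi, group in enumerate(groups):
                k = (len(group) + (1 if gi == big else 0)) // 2 if len(group) % 2 else len(group) // 2
                picked = rng.permutation(len(group))
                chosen = [group[i] for i in picked[:k]]
                calib.extend(chosen)
                test.extend([g for g in group if g not in chosen])
        else:
            picked = rng.permutation(len(labels))
            calib.extend(labels[i] for i in picked[:half])
            test.extend(labels[i] for i in picked[half:])
    return sorted(calib), sorted(test)


def _subsample_per_region(df: pd.DataFrame, max_rows: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    parts = []
    for label, block in df.groupby("label", sort=True):
        if len(block) > max_rows:
            idx = np.sort(rng.choice(len(block), size=max_rows, replace=False))
            block = block.iloc[idx]
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# training


def run_train(
    scene: Scene | None = None,
    cfg: RunConfig | None = None,
    output_dir: "str | Path | None" = None,
) -> TrainResult:
    """Calibrate, mask, preprocess and fit PCA + PLS-DA on a labelled scene."""
    cfg = cfg or RunConfig()
    if scene is None:
        if cfg.inputs:
            raw, refs, layout = load_scene_inputs(cfg)
            scene_obj = None
        else:
            replica = make_study_replica(cfg.seed, **_sim_kwargs(cfg))
            scene_obj = replica.calibration_scene
            raw, refs, layout = scene_obj.raw, scene_obj.refs, scene_obj.layout
    else:
        scene_obj = scene
        raw, refs, layout = scene.raw, scene.refs, scene.layout

    absorbance = prepare_absorbance(raw, refs)
    mask = build_mask(
        absorbance,
        edge_iterations=int(cfg.masking.get("edge_iterations", 1)),
        background=str(cfg.masking.get("background", "low")),
    )

    split = cfg.train.get("split", "stratified_half")
    if split == "stratified_half":
        calib_labels, test_labels = split_regions_stratified(layout, cfg.seed + 1)
    elif split == "all":
        calib_labels = [r.label for r in layout if r.class_hint]
        test_labels = []
    else:
        calib_labels = list(split["calibration"])
        test_labels = list(split.get("test", []))

    calib_regions = [layout.get(l) for l in calib_labels]
    df = extract_region_spectra(absorbance, calib_regions, mask.keep)
    df = _subsample_per_region(df, int(cfg.train.get("max_pixels_per_region", 200)),
                               cfg.seed + 2)
    x_raw = spectra_matrix(df)
    labels = df["label"].map({r.label: r.class_hint for r in calib_regions}).to_numpy()

    plan = cfg.make_plan()
    x, wl_used = plan.fit_transform(x_raw, absorbance.wavelengths_nm)

    n_comp = select_n_components(
        x,
        int(cfg.pca.get("max_components", 10)),
        gain_threshold=float(cfg.pca.get("gain_threshold", 0.01)),
        seed=cfg.seed + 3,
    )
    pca_model = fit_pca(x, n_comp)
    window = loadings_line_plot_data(pca_model, wl_used, component=0)

    codebook = ClassCodebook(tuple(sorted(set(labels))))
    y = encode_classes(labels, codebook)
    cv = CVSpec(n_segments=int(cfg.plsda.get("n_segments", 7)), seed=cfg.seed + 4)
    pls_model = fit_plsda(
        x,
        y,
        codebook,
        max_factors=int(cfg.plsda.get("max_factors", 10)),
        cv_spec=cv,
        gain_threshold=float(cfg.plsda.get("gain_threshold", 0.01)),
        min_cut=float(cfg.plsda.get("min_cut", 0.5)),
        max_cut=float(cfg.plsda.get("max_cut", 1.5)),
    )

    qc = {
        "n_calibration_pixels": int(x.shape[0]),
        "n_bands_used": int(x.shape[1]),
        "n_kept_pixels": mask.n_kept,
        "calibration_regions": calib_labels,
        "test_regions": test_labels,
        "pca_n_components": int(pca_model.n_components),
        "pca_r2x_cum": pca_model.r2x_cum.tolist(),
        "loadings_window_nm": list(window["window_nm"]),
        "plsda_n_factors": int(pls_model.n_factors),
        "plsda_r2x_cum": pls_model.r2x_cum.tolist(),
        "plsda_r2y_cum": pls_model.r2y_cum.tolist(),
        "plsda_q2y_cum": pls_model.q2y_cum.tolist(),
    }

    if test_labels:
        pred = _predict_image(pls_model, plan, absorbance, mask)
        val = external_validation(pred, [layout.get(l) for l in test_labels], mask.keep)
        qc["external_validation"] = {
            "region_accuracy": val["region_accuracy"],
            "pixel_accuracy": val["pixel_accuracy"],
        }

    result = TrainResult(
        plan=plan,
        pca=pca_model,
        plsda=pls_model,
        mask=mask,
        wavelengths_used=wl_used,
        calibration_labels=calib_labels,
        test_labels=test_labels,
        qc=qc,
        x_train=x,
        labels_train=labels,
    )
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.archive_path = outdir / "model.hsia"
        save_model(result.archive_path, result)
        with open(outdir / "train_qc.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        factor_table(result).to_csv(outdir / "factor_table.csv", index=False)
    return result


def factor_table(result: TrainResult) -> pd.DataFrame:
    m = result.plsda
    rows = []
    for a in range(m.n_factors):
        rows.append(
            {"factor": a + 1, "r2x_cum": m.r2x_cum[a], "r2y_cum": m.r2y_cum[a],
             "q2y_cum": m.q2y_cum[a]}
        )
    return pd.DataFrame(rows, columns=["factor", "r2x_cum", "r2y_cum", "q2y_cum"])


def _sim_kwargs(cfg: RunConfig) -> dict:
    sim = cfg.simulate
    kwargs = {}
    for key in ("noise_sigma", "scatter_sigma", "offset_sigma"):
        if key in sim:
            kwargs[key] = float(sim[key])
    if "shape" in sim:
        kwargs["shape"] = tuple(sim["shape"])
    if "n_bands" in sim:
        kwargs["n_bands"] = int(sim["n_bands"])
    return kwargs


def _predict_image(model: PLSDAModel, plan: PreprocessPlan, absorbance: Hypercube,
                   mask: PixelMask):
    keep = mask.keep
    x_kept, _ = plan.transform(absorbance.data[keep], absorbance.wavelengths_nm)
    yhat_kept = predict_continuous(model, x_kept)
    ny, nx = keep.shape
    yhat_grid = np.full((ny, nx, len(model.codebook)), np.nan)
    yhat_grid[keep] = yhat_kept
    return classify_pixels(model, yhat_grid, keep)


# ---------------------------------------------------------------------------
# model archive


def save_model(path, result: TrainResult) -> None:
    m, p = result.plsda, result.pca
    arrays = {
        "wavelengths_used": result.wavelengths_used,
        "pca_mean": p.mean,
        "pca_loadings": p.loadings,
        "pca_r2x_per_component": p.r2x_per_component,
        "pca_r2x_cum": p.r2x_cum,
        "pls_x_mean": m.x_mean,
        "pls_y_mean": m.y_mean,
        "pls_weights": m.weights,
        "pls_x_loadings": m.x_loadings,
        "pls_y_loadings": m.y_loadings,
        "pls_coef": m.coef,
        "pls_r2x_cum": m.r2x_cum,
        "pls_r2y_cum": m.r2y_cum,
        "pls_q2y_cum": m.q2y_cum,
    }
    meta = {
        "classes": list(m.codebook.labels),
        "min_cut": m.min_cut,
        "max_cut": m.max_cut,
        "n_factors": m.n_factors,
        "pca_n_components": p.n_components,
        "preprocess": result.plan.to_dict(),
        "calibration_regions": result.calibration_labels,
        "test_regions": result.test_labels,
    }
    save_archive(path, arrays, meta)


def load_model(path) -> tuple[PreprocessPlan, PLSDAModel]:
    arrays, meta = load_archive(path)
    plan = PreprocessPlan.from_dict(meta["preprocess"])
    codebook = ClassCodebook(tuple(meta["classes"]))
    a = int(meta["n_factors"])
    model = PLSDAModel(
        codebook=codebook,
        x_mean=arrays["pls_x_mean"],
        y_mean=arrays["pls_y_mean"],
        weights=arrays["pls_weights"],
        x_loadings=arrays["pls_x_loadings"],
        y_loadings=arrays["pls_y_loadings"],
        scores=np.zeros((0, a)),
        coef=arrays["pls_coef"],
        n_factors=a,
        r2x_cum=arrays["pls_r2x_cum"],
        r2y_cum=arrays["pls_r2y_cum"],
        q2y_cum=arrays["pls_q2y_cum"],
        min_cut=float(meta["min_cut"]),
        max_cut=float(meta["max_cut"]),
    )
    return plan, model


# ---------------------------------------------------------------------------
# prediction


def run_predict(
    model: "PLSDAModel | str | Path",
    scene: Scene | None = None,
    plan: PreprocessPlan | None = None,
    cfg: RunConfig | None = None,
    output_dir: "str | Path | None" = None,
) -> dict:
    """Apply a trained model to a scene; returns report + prediction image."""
    if not isinstance(model, PLSDAModel):
        plan, model = load_model(model)
    if plan is None:
        raise ValueError("a fitted PreprocessPlan is required alongside the model")
    cfg = cfg or RunConfig()
    if scene is None:
        raw, refs, layout = load_scene_inputs(cfg)
    else:
        raw, refs, layout = scene.raw, scene.refs, scene.layout
    absorbance = prepare_absorbance(raw, refs)
    mask = build_mask(
        absorbance,
        edge_iterations=int(cfg.masking.get("edge_iterations", 1)),
        background=str(cfg.masking.get("background", "low")),
    )
    pred = _predict_image(model, plan, absorbance, mask)
    report = quantify_composition(pred, layout, mask.keep)
    out = {"report": report, "prediction": pred, "mask": mask}
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "composition_report.csv", index=False, float_format="%.4f")
        _write_class_image(outdir / "class_image.png", pred)
        out["report_path"] = outdir / "composition_report.csv"
    return out


def _write_class_image(path, pred) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap
    except Exception:  # plotting is best-effort
        return
    classes = list(pred.codebook.labels)
    lut = {"masked": 0, "no_class": 1, **{c: i + 2 for i, c in enumerate(classes)}}
    idx = np.vectorize(lut.get)(pred.labels.astype(str))
    colors = ["black", "gold", "red", "green", "blue", "magenta", "cyan"][: len(lut)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(idx, cmap=ListedColormap(colors), vmin=0, vmax=len(lut) - 1,
                   interpolation="nearest")
    ax.set_title("predicted class per pixel")
    cbar = fig.colorbar(im, ticks=range(len(lut)))
    cbar.ax.set_yticklabels(list(lut))
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# one-command replica


def replicate(seed: int = 0, output_dir: "str | Path | None" = None,
              cfg: RunConfig | None = None) -> dict:
    """Simulate the study replica, train on scene 1, predict scene 2."""
    cfg = cfg or RunConfig(seed=seed)
    cfg.seed = seed
    replica = make_study_replica(seed, **_sim_kwargs(cfg))
    train_dir = Path(output_dir) / "train" if output_dir else None
    result = run_train(replica.calibration_scene, cfg, output_dir=train_dir)
    predict_dir = Path(output_dir) / "predict" if output_dir else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-region warnings are expected on product scenes
        pred = run_predict(result.plsda, replica.product_scene, plan=result.plan, cfg=cfg,
                           output_dir=predict_dir)
    return {"replica": replica, "train": result, "predict": pred}
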
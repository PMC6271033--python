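import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from hsiauth.hypercube import extract_region_spectra, spectra_matrix
from hsiauth.masking import build_mask
from hsiauth.pca import (
    fit_pca,
    loadings_line_plot_data,
    make_score_image,
    project_pixels,
    select_n_components,
)
from hsiauth.pipeline import prepare_absorbance
from hsiauth.preprocess import PreprocessPlan


def align_signs(a, b):
    """Flip columns of b to match the sign convention of a."""
    signs = np.sign((a * b).sum(axis=0))
    return b * signs


class TestFitPCA:
    def test_rank_one_matrix_fully_explained_by_one_component(self, rng):
        x = np.outer(rng.normal(size=30), rng.normal(size=10)) + rng.normal(size=10)
        model = fit_pca(x, 1)
        assert abs(model.r2x_cum[0] - 1.0) < 1e-10

    def test_matches_svd_oracle(self, rng):
        x = rng.normal(size=(50, 20))
        model = fit_pca(x, 5, tol=1e-12, max_iter=2000)
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        t_svd = align_signs(model.scores, u[:, :5] * s[:5])
        p_svd = align_signs(model.loadings, vt[:5].T)
        assert np.max(np.abs(model.scores - t_svd)) < 1e-6
        assert np.max(np.abs(model.loadings - p_svd)) < 1e-6

    def test_full_decomposition_explains_everything(self, rng):
        x = rng.normal(size=(12, 6))
        model = fit_pca(x, 6, tol=1e-13, max_iter=5000)
        assert abs(model.r2x_cum[-1] - 1.0) < 1e-8

    def test_orthogonality_invariants(self, rng):
        x = rng.normal(size=(40, 15))
        model = fit_pca(x, 4, tol=1e-12, max_iter=2000)
        gram = model.loadings.T @ model.loadings
        assert np.max(np.abs(gram - np.eye(4))) < 1e-8
        t = model.scores
        cos = t.T @ t / np.outer(np.linalg.norm(t, axis=0), np.linalg.norm(t, axis=0))
        assert np.max(np.abs(cos - np.diag(np.diag(cos)))) < 1e-8

    def test_reconstruction_residual_matches_r2x(self, rng):
        x = rng.normal(size=(30, 10)) @ np.diag(np.linspace(3, 0.5, 10))
        model = fit_pca(x, 3, tol=1e-12, max_iter=2000)
        xc = x - model.mean
        recon = model.scores @ model.loadings.T
        resid_ss = float(((xc - recon) ** 2).sum())
        total_ss = float((xc**2).sum())
        assert abs(resid_ss - (1 - model.r2x_cum[-1]) * total_ss) < 1e-8 * total_ss

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pca(np.full((5, 4), 2.0), 1)


class TestProjection:
    def test_training_matrix_reproduces_scores(self, rng):
        x = rng.normal(size=(25, 8))
        model = fit_pca(x, 3, tol=1e-12, max_iter=2000)
        np.testing.assert_allclose(project_pixels(model, x), model.scores, atol=1e-8)

    def test_mean_spectrum_maps_to_zero(self, rng):
        x = rng.normal(size=(25, 8))
        model = fit_pca(x, 3)
        np.testing.assert_allclose(project_pixels(model, model.mean[None, :]), 0.0, atol=1e-10)

    def test_band_mismatch_rejected(self, rng):
        model = fit_pca(rng.normal(size=(10, 6)), 2)
        with pytest.raises(ValueError, match="band count"):
            project_pixels(model, np.ones((3, 5)))


class TestScoreImage:
    def test_positional_roundtrip_and_nan_for_masked(self, rng):
        keep = np.array([[True, True], [True, False]])
        x = rng.normal(size=(3, 6))
        model = fit_pca(x, 2)
        img = make_score_image(model, keep, 0)
        np.testing.assert_allclose(img.values[keep], model.scores[:, 0])
        assert np.isnan(img.values[1, 1])
        assert img.vmin == -img.vmax

    def test_region_mean_matches_pixel_scan(self, rng):
        keep = np.ones((4, 5), dtype=bool)
        x = rng.normal(size=(20, 7))
        model = fit_pca(x, 1)
        img = make_score_image(model, keep, 0)
        sub = img.values[1:3, 2:5]
        grid = model.scores[:, 0].reshape(4, 5)
        np.testing.assert_allclose(sub.mean(), grid[1:3, 2:5].mean())


class TestLoadingsWindow:
    def test_spike_centers_window(self):
        wl = np.linspace(1000, 2500, 151)
        loading = np.zeros(151)
        loading[100] = 1.0  # spike at 2000 nm
        model = fit_pca(np.random.default_rng(0).normal(size=(10, 151)), 1)
        model.loadings[:, 0] = loading
        out = loadings_line_plot_data(model, wl, 0, window_nm=300.0)
        lo, hi = out["window_nm"]
        assert lo <= 2000.0 <= hi

    def test_flat_loadings_flagged(self):
        wl = np.linspace(1000, 2000, 50)
        model = fit_pca(np.random.default_rng(0).normal(size=(10, 50)), 1)
        model.loadings[:, 0] = 0.1
        out = loadings_line_plot_data(model, wl, 0)
        assert out["non_informative"]
        assert out["window_nm"][0] == wl[0]

    def test_window_matches_exhaustive_search(self, rng):
        wl = np.linspace(1000, 2500, 80)
        model = fit_pca(rng.normal(size=(12, 80)), 1)
        out = loadings_line_plot_data(model, wl, 0, window_nm=200.0)
        best = max(
            range(80),
            key=lambda i: np.abs(model.loadings[:, 0])[
                i : np.searchsorted(wl, wl[i] + 200.0, side="right")
            ].mean(),
        )
        assert out["window_nm"][0] == pytest.approx(wl[best])


class TestComponentSelection:
    def test_noiseless_rank_two_selects_two(self, rng):
        basis = rng.normal(size=(2, 12))
        x = rng.normal(size=(60, 2)) @ np.diag([5.0, 2.0]) @ basis
        assert select_n_components(x, 6, seed=5) == 2

    def test_pure_noise_floors_at_one(self, rng):
        x = rng.normal(size=(60, 12))
        assert select_n_components(x, 6, seed=5) == 1

    def test_never_exceeds_max(self, rng):
        x = rng.normal(size=(40, 20)) @ np.diag(np.linspace(10, 1, 20))
        assert select_n_components(x, 3, seed=5) <= 3


def test_root_classes_separate_on_pc1(small_replica):
    """PC1 of the root pixels alone separates the three species cleanly
    (silhouette > 0.5), as expected when roots carry the strongest
    species-specific chemistry."""
    scene = small_replica.calibration_scene
    absorbance = prepare_absorbance(scene.raw, scene.refs)
    mask = build_mask(absorbance)
    root_regions = [r for r in scene.layout if r.label.split("-")[0].endswith("R")]
    df = extract_region_spectra(absorbance, root_regions, mask.keep)
    x_raw = spectra_matrix(df)
    plan = PreprocessPlan()
    x, _ = plan.fit_transform(x_raw, absorbance.wavelengths_nm)
    model = fit_pca(x, 1)
    species = df["label"].str.split("-").str[0].str[:-1].to_numpy()
    score = silhouette_score(model.scores, species)
    assert score > 0.5
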
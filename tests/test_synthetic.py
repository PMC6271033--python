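import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from hsiauth.hypercube import extract_region_spectra, spectra_matrix
from hsiauth.pca import fit_pca
from hsiauth.pipeline import prepare_absorbance
from hsiauth.preprocess import snv
from hsiauth.synthetic import (
    EXCIPIENT,
    SPECIES,
    STAGE,
    SceneSpec,
    Well,
    default_echinacea_library,
    default_wavelength_grid,
    make_study_replica,
    render_scene,
)


def snv_angle(a, b):
    sa, _ = snv(a[None, :])
    sb, _ = snv(b[None, :])
    sa, sb = sa.ravel(), sb.ravel()
    cos = (sa @ sb) / (np.linalg.norm(sa) * np.linalg.norm(sb))
    return float(np.arccos(np.clip(cos, -1, 1)))


@pytest.fixture(scope="module")
def library():
    return default_echinacea_library()


@pytest.fixture(scope="module")
def wl():
    return default_wavelength_grid()


class TestLibrary:
    def test_pallida_root_most_distinct(self, library, wl):
        spectra = {n: e.spectrum(wl) for n, e in library.items()}
        base = snv_angle(spectra["angustifolia_root"], spectra["purpurea_root"])
        for other in ("angustifolia_root", "purpurea_root"):
            assert snv_angle(spectra["pallida_root"], spectra[other]) > base

    def test_roots_more_separated_than_leaves(self, library, wl):
        spectra = {n: e.spectrum(wl) for n, e in library.items()}
        pairs = [("angustifolia", "purpurea"), ("angustifolia", "pallida"),
                 ("purpurea", "pallida")]
        for a, b in pairs:
            root = snv_angle(spectra[f"{a}_root"], spectra[f"{b}_root"])
            leaf = snv_angle(spectra[f"{a}_leaf"], spectra[f"{b}_leaf"])
            assert root > leaf

    def test_stage_darkest_material(self, library, wl):
        means = {n: e.spectrum(wl).mean() for n, e in library.items()}
        stage = means.pop(STAGE)
        assert stage < min(means.values())

    def test_band_centers_inside_grid(self, library, wl):
        for e in library.values():
            for center, width, _ in e.bands:
                assert wl[0] <= center <= wl[-1]
                assert width > 0

    def test_species_differences_concentrated_in_discriminating_window(self, library, wl):
        """The wavelength where two species' spectra differ most lies in the
        1937-2400 nm combination region, for every species pair and organ."""
        for organ in ("root", "leaf"):
            for i, a in enumerate(SPECIES):
                for b in SPECIES[i + 1 :]:
                    diff = np.abs(library[f"{a}_{organ}"].spectrum(wl)
                                  - library[f"{b}_{organ}"].spectrum(wl))
                    peak = wl[np.argmax(diff)]
                    assert 1937.0 <= peak <= 2400.0


class TestRenderScene:
    def test_noiseless_pure_well_recovers_endmember(self, library):
        wl = default_wavelength_grid(64)
        spec = SceneSpec(shape=(24, 24), wavelengths_nm=wl,
                         wells=[Well("w", 12, 12, 6, "purpurea_root")],
                         scatter_sigma=0.0, offset_sigma=0.0, noise_sigma=0.0, seed=4)
        scene = render_scene(spec, library)
        absorbance = prepare_absorbance(scene.raw, scene.refs)
        target = library["purpurea_root"].spectrum(wl)
        inside = scene.sample_mask
        err = np.max(np.abs(absorbance.data[inside] - target))
        assert err < 1e-10

    def test_same_seed_bit_identical(self, library):
        wl = default_wavelength_grid(32)
        spec = SceneSpec(shape=(16, 16), wavelengths_nm=wl,
                         wells=[Well("w", 8, 8, 5, {"purpurea_root": 0.6, "pallida_root": 0.4})],
                         seed=9)
        s1 = render_scene(spec, library)
        s2 = render_scene(spec, library)
        assert s1.raw.data.tobytes() == s2.raw.data.tobytes()
        np.testing.assert_array_equal(s1.truth_map, s2.truth_map)

    def test_noisy_well_mean_correlates_with_endmember(self, library):
        wl = default_wavelength_grid(128)
        spec = SceneSpec(shape=(32, 32), wavelengths_nm=wl,
                         wells=[Well("w", 16, 16, 10, "angustifolia_leaf")], seed=21)
        scene = render_scene(spec, library)
        absorbance = prepare_absorbance(scene.raw, scene.refs)
        mean_spec = absorbance.data[scene.sample_mask].mean(axis=0)
        a, _ = snv(mean_spec[None, :])
        b, _ = snv(library["angustifolia_leaf"].spectrum(wl)[None, :])
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_overlapping_wells_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SceneSpec(shape=(32, 32), wells=[Well("a", 10, 10, 6, EXCIPIENT),
                                             Well("b", 14, 14, 6, EXCIPIENT)])

    def test_mixture_weights_validated(self):
        with pytest.raises(ValueError, match="sum"):
            Well("w", 5, 5, 2, {"purpurea_root": 0.8, "pallida_root": 0.4}).weights()
        with pytest.raises(ValueError, match="negative"):
            Well("w", 5, 5, 2, {"purpurea_root": -0.1}).weights()

    def test_remainder_assigned_to_excipient(self):
        w = Well("w", 5, 5, 2, {"purpurea_root": 0.7}).weights()
        assert w[EXCIPIENT] == pytest.approx(0.3)


class TestStudyReplica:
    def test_scene_counts(self, small_replica):
        assert len(small_replica.calibration_scene.layout) == 18
        assert len(small_replica.product_scene.layout) == 24

    def test_calibration_design_balanced(self, small_replica):
        hints = [r.class_hint for r in small_replica.calibration_scene.layout]
        for sp in SPECIES:
            assert hints.count(sp) == 6  # 2 organs x 3 replicates

    def test_truth_compositions_sum_to_one(self, small_replica):
        for scene in (small_replica.calibration_scene, small_replica.product_scene):
            totals = scene.composition[[*SPECIES, EXCIPIENT]].sum(axis=1)
            np.testing.assert_allclose(totals, 1.0, atol=1e-9)

    def test_snv_improves_class_separability(self, small_replica):
        """Multiplicative scatter hides class structure that SNV restores."""
        scene = small_replica.calibration_scene
        absorbance = prepare_absorbance(scene.raw, scene.refs)
        df = extract_region_spectra(absorbance, scene.layout, scene.sample_mask)
        sub = df.groupby("label").head(40)
        x_raw = spectra_matrix(sub)
        labels = sub["label"].map(
            {r.label: r.class_hint for r in scene.layout}
        ).to_numpy()
        x_snv, _ = snv(x_raw)
        sil_raw = silhouette_score(fit_pca(x_raw, 3).scores, labels)
        sil_snv = silhouette_score(fit_pca(x_snv, 3).scores, labels)
        assert sil_snv > sil_raw
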
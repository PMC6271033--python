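import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from hsiauth.hypercube import Region, RegionLayout
from hsiauth.plsda import (
    NO_CLASS,
    ClassCodebook,
    ClassPredictionImage,
    CVSpec,
    classify_yhat,
    cross_validated_q2y,
    encode_classes,
    external_validation,
    fit_plsda,
    predict_continuous,
    quantify_composition,
)

ABC = ClassCodebook(("A", "B", "C"))


def separable_data(rng, n_per_class=40, n_bands=20, gap=4.0, noise=0.3):
    """Three spectral classes offset along distinct band directions."""
    protos = np.zeros((3, n_bands))
    protos[0, 3] = gap
    protos[1, 9] = gap
    protos[2, 15] = gap
    x, labels = [], []
    for c, proto in enumerate(protos):
        x.append(proto + noise * rng.normal(size=(n_per_class, n_bands)))
        labels += [ABC.labels[c]] * n_per_class
    return np.vstack(x), np.array(labels)


class TestEncoding:
    def test_one_hot_row(self):
        y = encode_classes(["B"], ABC)
        np.testing.assert_array_equal(y, [[0.0, 1.0, 0.0]])

    def test_row_sums_and_column_counts(self, rng):
        labels = rng.choice(ABC.labels, size=50)
        y = encode_classes(labels, ABC)
        np.testing.assert_array_equal(y.sum(axis=1), 1.0)
        for i, c in enumerate(ABC.labels):
            assert y[:, i].sum() == np.sum(labels == c)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            encode_classes(["D"], ABC)


class TestFit:
    def test_separable_classes_perfectly_recalled(self, rng):
        x, labels = separable_data(rng, noise=0.05)
        y = encode_classes(labels, ABC)
        model = fit_plsda(x, y, ABC, max_factors=5, cv_spec=CVSpec(seed=3))
        yhat = predict_continuous(model, x)
        pred = classify_yhat(yhat, ABC)
        assert np.mean(pred == labels) == 1.0

    def test_permuted_labels_have_no_predictive_power(self, rng):
        x, labels = separable_data(rng)
        y = encode_classes(rng.permutation(labels), ABC)
        q2 = cross_validated_q2y(x, y, 1, CVSpec(seed=3))
        assert q2[0] <= 0.05

    def test_coefficients_reproduce_factorized_prediction(self, rng):
        x, labels = separable_data(rng)
        y = encode_classes(labels, ABC)
        model = fit_plsda(x, y, ABC, max_factors=4, cv_spec=CVSpec(seed=3))
        x_new = rng.normal(size=(10, x.shape[1]))
        xc = x_new - model.x_mean
        t = xc @ model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
        yhat_fact = t @ model.y_loadings.T + model.y_mean
        np.testing.assert_allclose(predict_continuous(model, x_new), yhat_fact, atol=1e-8)

    def test_matches_sklearn_pls_oracle(self, rng):
        """Fitted predictions agree with an independent PLS2 implementation
        at the same factor count."""
        x, labels = separable_data(rng)
        y = encode_classes(labels, ABC)
        model = fit_plsda(x, y, ABC, max_factors=2, cv_spec=CVSpec(seed=3),
                          gain_threshold=-np.inf)
        assert model.n_factors == 2
        sk = PLSRegression(n_components=2, scale=False, tol=1e-12, max_iter=5000).fit(x, y)
        np.testing.assert_allclose(
            predict_continuous(model, x), sk.predict(x), atol=1e-6
        )

    def test_q2_bounded_by_r2y(self, rng):
        x, labels = separable_data(rng, noise=0.8)
        y = encode_classes(labels, ABC)
        model = fit_plsda(x, y, ABC, max_factors=4, cv_spec=CVSpec(seed=3))
        assert np.all(model.q2y_cum <= model.r2y_cum + 1e-9)
        assert np.all(model.r2y_cum <= 1.0)

    def test_fewer_rows_than_segments_rejected(self, rng):
        x = rng.normal(size=(5, 4))
        y = encode_classes(["A", "B", "C", "A", "B"], ABC)
        with pytest.raises(ValueError, match="segments"):
            fit_plsda(x, y, ABC, cv_spec=CVSpec(n_segments=7))


class TestClassify:
    def test_single_candidate_wins(self):
        assert classify_yhat(np.array([[1.02, -0.01, 0.03]]), ABC)[0] == "A"

    def test_all_below_cutoff_is_no_class(self):
        assert classify_yhat(np.array([[0.3, 0.4, 0.2]]), ABC)[0] == NO_CLASS

    def test_multiple_candidates_resolved_by_argmax(self):
        assert classify_yhat(np.array([[0.8, 0.7, 0.1]]), ABC)[0] == "A"
        assert classify_yhat(np.array([[0.7, 0.8, 0.1]]), ABC)[0] == "B"

    def test_infinite_cutoffs_degenerate_to_argmax(self, rng):
        yhat = rng.normal(size=(200, 3))
        labels = classify_yhat(yhat, ABC, -np.inf, np.inf)
        argmax = np.array([ABC.labels[i] for i in yhat.argmax(axis=1)])
        np.testing.assert_array_equal(labels, argmax)


def prediction_image(labels_grid, codebook=ABC):
    ny, nx = labels_grid.shape
    return ClassPredictionImage(
        labels=labels_grid, yhat=np.zeros((ny, nx, len(codebook))), codebook=codebook
    )


class TestComposition:
    def test_counting_example(self):
        grid = np.full((10, 10), "A", dtype=object)
        grid.ravel()[90:95] = "B"
        grid.ravel()[95:] = NO_CLASS
        layout = RegionLayout([Region("prod", "rect", (0, 0, 10, 10), "A")])
        rep = quantify_composition(prediction_image(grid), layout, np.ones((10, 10), bool))
        row = rep.iloc[0]
        assert (row.pct_A, row.pct_B, row.pct_C, row.pct_no_class) == (90.0, 5.0, 0.0, 5.0)
        assert row.dominant == "A" and row.verdict == "match"

    def test_all_no_class_flags_inauthentic_material(self):
        grid = np.full((4, 4), NO_CLASS, dtype=object)
        layout = RegionLayout([Region("extract", "rect", (0, 0, 4, 4), "A")])
        rep = quantify_composition(prediction_image(grid), layout, np.ones((4, 4), bool))
        assert rep.iloc[0].pct_no_class == 100.0
        assert rep.iloc[0].verdict == "no_authentic_material"

    def test_percentages_sum_to_100_and_match_brute_force(self, rng):
        grid = rng.choice(np.array(["A", "B", "C", NO_CLASS], dtype=object), size=(12, 12))
        mask = rng.random((12, 12)) > 0.2
        layout = RegionLayout([Region("r", "disk", (6.0, 6.0, 4.0))])
        rep = quantify_composition(prediction_image(grid), layout, mask)
        row = rep.iloc[0]
        total = row.pct_A + row.pct_B + row.pct_C + row.pct_no_class
        assert abs(total - 100.0) < 0.01
        inside = Region("r", "disk", (6.0, 6.0, 4.0)).member_mask((12, 12)) & mask
        assert row.pct_B == 100.0 * np.sum(grid[inside] == "B") / inside.sum()

    def test_relabeling_equivariance(self, rng):
        grid = rng.choice(np.array(["A", "B", "C"], dtype=object), size=(8, 8))
        layout = RegionLayout([Region("r", "rect", (0, 0, 8, 8))])
        mask = np.ones((8, 8), bool)
        rep1 = quantify_composition(prediction_image(grid), layout, mask)
        swap = {"A": "B", "B": "A", "C": "C"}
        grid2 = np.vectorize(swap.get)(grid.astype(str)).astype(object)
        rep2 = quantify_composition(prediction_image(grid2), layout, mask)
        assert rep1.iloc[0].pct_A == rep2.iloc[0].pct_B
        assert rep1.iloc[0].pct_C == rep2.iloc[0].pct_C

    def test_empty_region_unevaluable(self):
        grid = np.full((4, 4), "A", dtype=object)
        layout = RegionLayout([Region("gone", "rect", (0, 0, 2, 2), "A")])
        mask = np.zeros((4, 4), bool)
        rep = quantify_composition(prediction_image(grid), layout, mask)
        assert rep.iloc[0].verdict == "unevaluable"


class TestExternalValidation:
    def test_identical_region_perfect_accuracy(self):
        grid = np.full((6, 6), "B", dtype=object)
        regions = [Region("t", "rect", (0, 0, 6, 6), "B")]
        out = external_validation(prediction_image(grid), regions, np.ones((6, 6), bool))
        assert out["region_accuracy"] == 1.0
        assert out["pixel_accuracy"] == 1.0

    def test_confusion_row_sums_equal_kept_counts(self, rng):
        grid = rng.choice(np.array(["A", "B", NO_CLASS], dtype=object), size=(10, 10))
        regions = [Region("a", "rect", (0, 0, 5, 10), "A"),
                   Region("b", "rect", (5, 0, 10, 10), "B")]
        mask = rng.random((10, 10)) > 0.3
        out = external_validation(prediction_image(grid), regions, mask)
        per_region = out["regions"].set_index("true_class")["n_pixels"]
        row_sums = out["confusion"].sum(axis=1)
        assert row_sums["A"] == per_region["A"]
        assert row_sums["B"] == per_region["B"]

    def test_empty_test_set_rejected(self):
        grid = np.full((2, 2), "A", dtype=object)
        with pytest.raises(ValueError, match="empty"):
            external_validation(prediction_image(grid), [], np.ones((2, 2), bool))
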
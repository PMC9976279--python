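"""Regressor contracts: memorization, determinism, Gini importances."""

import numpy as np
import pytest

from solqspr.features import FeatureMatrix, compute_descriptors
from solqspr.models import (
    ModelSpec,
    fit,
    gini_importances,
    load_model,
    predict,
    save_model,
)
from solqspr.synthetic import SyntheticSpec, count_features, generate_library
from solqspr.validation import nested_cv


def matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = tuple(names or [f"f{i}" for i in range(values.shape[1])])
    return FeatureMatrix(
        ids=tuple(str(i) for i in range(values.shape[0])), names=names, values=values
    )


@pytest.fixture(scope="module")
def memorization_fixture(rng=np.random.default_rng(1)):
    X = matrix(rng.normal(size=(10, 3)))
    y = rng.normal(-3, 1, 10)
    return X, y


class TestSpecValidation:
    def test_nn_widths_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            ModelSpec("nn", {"widths": (64, 64, 32)})

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            ModelSpec("svm")

    def test_nonpositive_hyperparameter(self):
        with pytest.raises(ValueError, match="positive"):
            ModelSpec("rf", {"n_trees": 0})


class TestFitPredict:
    def test_rf_memorizes_separable_points(self, memorization_fixture):
        # full-depth trees grown on the whole sample memorize distinct points
        X, y = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 500, "min_samples_leaf": 1, "bootstrap": False}, 0), X, y)
        assert predict(m, X) == pytest.approx(y, abs=0.05)

    def test_constant_target_predicts_constant(self, memorization_fixture):
        X, _ = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 50}, 0), X, np.full(10, -2.5))
        other = matrix(np.random.default_rng(2).normal(size=(4, 3)))
        assert predict(m, other) == pytest.approx(np.full(4, -2.5))

    def test_rf_prediction_within_training_range(self, memorization_fixture):
        X, y = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 100}, 0), X, y)
        far = matrix(np.random.default_rng(3).normal(scale=20, size=(30, 3)))
        p = predict(m, far)
        assert p.min() >= y.min() - 1e-12 and p.max() <= y.max() + 1e-12

    def test_same_seed_identical_predictions(self, memorization_fixture):
        X, y = memorization_fixture
        for family, params in (("rf", {"n_trees": 50}), ("nn", {"widths": (16, 8, 4), "epochs": 30})):
            if family == "nn":
                X_, y_ = matrix(np.random.default_rng(4).normal(size=(60, 3))), np.random.default_rng(5).normal(size=60)
            else:
                X_, y_ = X, y
            a = predict(fit(ModelSpec(family, params, 7), X_, y_), X_)
            b = predict(fit(ModelSpec(family, params, 7), X_, y_), X_)
            assert np.array_equal(a, b)

    def test_row_equivariance_and_duplication(self, memorization_fixture):
        X, y = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 50}, 0), X, y)
        perm = np.random.default_rng(6).permutation(10)
        permuted = FeatureMatrix(
            ids=tuple(X.ids[i] for i in perm), names=X.names, values=X.values[perm]
        )
        assert predict(m, permuted) == pytest.approx(predict(m, X)[perm])
        dup = matrix(np.vstack([X.values[:1], X.values[:1]]))
        p = predict(m, dup)
        assert p[0] == p[1]

    def test_column_mismatch_names_offenders(self, memorization_fixture):
        X, y = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 20}, 0), X, y)
        bad = matrix(X.values, names=("f0", "f1", "zzz"))
        with pytest.raises(ValueError, match="zzz"):
            predict(m, bad)

    def test_nonfinite_target_rejected(self, memorization_fixture):
        X, _ = memorization_fixture
        with pytest.raises(ValueError):
            fit(ModelSpec("rf", {}, 0), X, [np.nan] * 10)

    def test_nn_recovers_linear_truth(self):
        """Dense net reaches held-out R2 >= 0.9 on noiseless synthetic data."""
        lib = generate_library(SyntheticSpec(n_molecules=500, seed=21, noise_sigma=0.0))
        C = count_features(lib.records)
        tr, te = np.arange(0, 400), np.arange(400, 500)
        Xtr = FeatureMatrix(ids=tuple(C.ids[i] for i in tr), names=C.names, values=C.values[tr])
        Xte = FeatureMatrix(ids=tuple(C.ids[i] for i in te), names=C.names, values=C.values[te])
        m = fit(ModelSpec("nn", {"widths": (64, 32, 16), "epochs": 400}, 0), Xtr, lib.truth[tr])
        pred = predict(m, Xte)
        yte = lib.truth[te]
        r2 = 1 - np.sum((pred - yte) ** 2) / np.sum((yte - yte.mean()) ** 2)
        assert r2 >= 0.9


class TestGini:
    def test_importances_normalized_and_sorted(self, memorization_fixture):
        X, y = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 100}, 0), X, y)
        gi = gini_importances(m)
        vals = [v for _, v in gi]
        assert sum(vals) == pytest.approx(1.0)
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert min(vals) >= 0

    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        X = matrix(rng.normal(size=(200, 4)), names=("noise1", "signal", "noise2", "noise3"))
        y = 3.0 * X.values[:, 1] + rng.normal(0, 0.01, 200)
        m = fit(ModelSpec("rf", {"n_trees": 100}, 0), X, y)
        assert gini_importances(m)[0][0] == "signal"

    def test_lipophilicity_count_ranks_first_on_truth_features(self, tight_library, counts):
        """On the generator's own structural counts the lipophilicity-like
        aliphatic-carbon term dominates the Gini ranking."""
        m = fit(ModelSpec("rf", {"n_trees": 200}, 0), counts, tight_library.truth)
        assert gini_importances(m)[0][0] == "aliphatic_carbons"

    def test_lipophilicity_descriptor_family_dominates_panel(self, tight_library):
        """On the full 2D panel the top-ranked descriptor is calculated logP
        or one of its lipophilicity/molar-refractivity surface-area variants,
        and calculated logP itself sits in the top five."""
        X = compute_descriptors(tight_library.records)
        m = fit(ModelSpec("rf", {"n_trees": 300}, 0), X, tight_library.truth)
        ranked = [n for n, _ in gini_importances(m)]
        assert ranked[0] == "MolLogP" or ranked[0].startswith(("SlogP_VSA", "SMR_VSA"))
        assert "MolLogP" in ranked[:5]

    def test_undefined_for_nn(self):
        rng = np.random.default_rng(9)
        X = matrix(rng.normal(size=(60, 3)))
        m = fit(ModelSpec("nn", {"widths": (8, 4, 2), "epochs": 20}, 0), X, rng.normal(size=60))
        with pytest.raises(ValueError, match="rf"):
            gini_importances(m)


class TestBundle:
    def test_roundtrip(self, tmp_path, memorization_fixture):
        X, y = memorization_fixture
        m = fit(ModelSpec("rf", {"n_trees": 50}, 0), X, y)
        save_model(m, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        assert np.array_equal(predict(loaded, X), predict(m, X))
        assert loaded.spec == m.spec and loaded.columns == m.columns
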
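"""Monotone projection, splitting, training and model persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.isotonic import IsotonicRegression

from d4screen.features import FingerprintConfig
from d4screen.qsar import (
    MultitaskThresholdClassifier,
    enforce_threshold_monotonicity,
    load_model,
    predict_profiles,
    save_model,
    split_dataset,
    train_receptor_model,
)


def sklearn_isotonic(v):
    """Independent oracle: least-squares isotonic fit of a 5-vector."""
    return IsotonicRegression().fit_transform(np.arange(len(v)), v)


class TestMonotoneProjection:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ((0.1, 0.3, 0.5, 0.7, 0.9), (0.1, 0.3, 0.5, 0.7, 0.9)),
            ((0.9, 0.5, 0.7, 0.8, 0.9), (0.7, 0.7, 0.7, 0.8, 0.9)),
            ((1.0, 0.0, 0.0, 0.0, 0.0), (0.2, 0.2, 0.2, 0.2, 0.2)),
        ],
    )
    def test_known_projections(self, raw, expected):
        assert enforce_threshold_monotonicity(raw) == pytest.approx(expected, abs=1e-12)

    def test_matches_isotonic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        V = rng.random((2000, 5))
        ours = enforce_threshold_monotonicity(V)
        for v, o in zip(V, ours):
            assert o == pytest.approx(sklearn_isotonic(v), abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=5, max_size=5))
    def test_idempotent_and_monotone(self, v):
        once = enforce_threshold_monotonicity(v)
        assert np.all(np.diff(once) >= -1e-15)
        assert enforce_threshold_monotonicity(once) == pytest.approx(once, abs=1e-12)

    def test_already_monotone_preserved_exactly(self):
        v = np.array([0.12, 0.12, 0.5, 0.81, 0.97])
        assert np.array_equal(enforce_threshold_monotonicity(v), v)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enforce_threshold_monotonicity([0.1, 0.2, 1.3, 0.4, 0.5])


class TestSplit:
    def test_random_split_is_reproducible_and_disjoint(self):
        a_train, a_val = split_dataset(100, fraction=0.8, seed=4)
        b_train, b_val = split_dataset(100, fraction=0.8, seed=4)
        assert np.array_equal(a_train, b_train) and np.array_equal(a_val, b_val)
        assert len(a_train) == 80 and len(a_val) == 20
        assert len(np.intersect1d(a_train, a_val)) == 0

    def test_scaffold_families_do_not_straddle(self):
        # two scaffold families: benzenes and pyridines with varying chains
        smiles = [f"{'C' * i}c1ccccc1" for i in range(1, 11)] + [
            f"{'C' * i}c1ccncc1" for i in range(1, 11)
        ]
        train, val = split_dataset(20, fraction=0.5, strategy="scaffold", seed=0, smiles=smiles)
        benzenes, pyridines = set(range(10)), set(range(10, 20))
        for fam in (benzenes, pyridines):
            assert fam <= set(train) or fam <= set(val)

    def test_too_few_molecules(self):
        with pytest.raises(ValueError):
            split_dataset(10)


def separable_dataset(n=240, seed=0):
    """Zero-noise, linearly separable labels driven by a single bit."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, 32)) < 0.2).astype(np.uint8)
    X[:, 0] = rng.random(n) < 0.5
    y = X[:, 0].astype(float)
    Y = np.tile(y[:, None], (1, 5))
    return X, Y


class TestTraining:
    def test_separable_task_reaches_perfect_validation_auroc(self):
        X, Y = separable_dataset()
        model = train_receptor_model(X, Y, "D4", seed=0, n_epochs=200)
        assert model.manifest["val_auroc"]["10.0"] == 1.0

    def test_shuffled_labels_give_chance_auroc(self):
        rng = np.random.default_rng(1)
        X, Y = separable_dataset(n=2000, seed=1)
        Y = Y[rng.permutation(len(Y))]
        model = train_receptor_model(X, Y, "D4", seed=1)
        assert 0.4 <= model.manifest["val_auroc"]["10.0"] <= 0.6

    def test_retraining_is_bit_identical(self):
        X, Y = separable_dataset()
        a = train_receptor_model(X, Y, "D4", seed=7)
        b = train_receptor_model(X, Y, "D4", seed=7)
        assert np.array_equal(
            a.classifier.predict_proba(X), b.classifier.predict_proba(X)
        )

    def test_single_class_task_is_masked_with_prior(self):
        X, Y = separable_dataset()
        Y = Y.copy()
        Y[:, 0] = 1.0  # the 1 nM task has no inactives
        with pytest.warns(UserWarning, match="masked"):
            model = train_receptor_model(X, Y, "D4", seed=0)
        proba = model.classifier.predict_proba(X, monotone=False)
        assert len(np.unique(proba[:, 0])) == 1

    def test_unknowns_are_masked_not_imputed(self):
        X, Y = separable_dataset()
        Ymasked = Y.copy()
        # hide half of task 3's labels; flip the hidden ones to garbage
        hide = np.arange(0, len(Y), 2)
        Ymasked[hide, 3] = np.nan
        a = MultitaskThresholdClassifier(random_state=0, n_epochs=20).fit(X, Ymasked)
        Ygarbage = Ymasked.copy()
        b = MultitaskThresholdClassifier(random_state=0, n_epochs=20).fit(X, Ygarbage)
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_all_tasks_masked_is_an_error(self):
        X, Y = separable_dataset()
        with pytest.raises(ValueError):
            MultitaskThresholdClassifier().fit(X, np.ones_like(Y))


class TestPrediction:
    def test_profiles_are_monotone_and_in_range(self):
        X, Y = separable_dataset()
        model = train_receptor_model(X, Y, "D4", seed=0)
        proba = model.classifier.predict_proba(X)
        assert np.all((proba >= 0) & (proba <= 1))
        assert np.all(np.diff(proba, axis=1) >= -1e-12)

    def test_batch_equals_per_molecule(self):
        X, Y = separable_dataset()
        model = train_receptor_model(X, Y, "D4", seed=0)
        batch = model.classifier.predict_proba(X[:10])
        singles = np.vstack([model.classifier.predict_proba(X[i : i + 1]) for i in range(10)])
        assert np.allclose(batch, singles, atol=1e-10)

    def test_feature_config_mismatch_is_hard_error(self):
        X, Y = separable_dataset()
        model = train_receptor_model(X, Y, "D4", seed=0)
        with pytest.raises(ValueError, match="config mismatch"):
            predict_profiles(model, X, ["m"] * len(X), FingerprintConfig(n_bits=4096))

    def test_profile_objects_carry_all_thresholds(self):
        X, Y = separable_dataset(n=30)
        model = train_receptor_model(X[:25], Y[:25], "D4", seed=0)
        profiles = predict_profiles(model, X[25:], [f"m{i}" for i in range(5)])
        assert len(profiles) == 5
        assert set(profiles[0].probs) == {1.0, 10.0, 100.0, 1000.0, 10000.0}


def test_archive_round_trip_is_bit_identical(tmp_path):
    X, Y = separable_dataset()
    model = train_receptor_model(X, Y, "D4", seed=3)
    before = model.classifier.predict_proba(X)
    path = tmp_path / "d4.npz"
    save_model(model, path)
    reloaded = load_model(path)
    assert reloaded.receptor == "D4"
    assert reloaded.manifest == model.manifest
    assert np.array_equal(reloaded.classifier.predict_proba(X), before)
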
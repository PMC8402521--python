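import numpy as np
import pytest

from myobench.classifiers import CLASSIFIER_NAMES, ClassifierSpec, load_model, save_model, train
from myobench.session_io import ConfigError

from conftest import make_separable_dataset


def _two_clusters(seed=0, n=50, d=4, spacing=8.0):
    # centers separated in direction (alternating channels active), the way
    # distinct movements activate different channels
    rng = np.random.default_rng(seed)
    direction = np.where(np.arange(d) % 2 == 0, 1.0, -1.0)
    Xa = rng.standard_normal((n, d)) + spacing * direction
    Xb = rng.standard_normal((n, d)) - spacing * direction
    X = np.vstack([Xa, Xb])
    y = np.asarray(["a"] * n + ["b"] * n, dtype=object)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]


class TestTrainContract:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_two_separated_clusters_perfect_training_accuracy(self, name):
        X, y = _two_clusters(seed=0)
        model = train(ClassifierSpec(name=name, seed=0), X, y, X[:20], y[:20])
        pred = model.predict_batch(X)
        assert np.mean(pred == y) == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.asarray(["a"] * 10, dtype=object)
        with pytest.raises(ConfigError, match="2 classes"):
            train(ClassifierSpec(name="LDA"), X, y)

    def test_nan_features_rejected(self):
        X, y = _two_clusters()
        X[0, 0] = np.nan
        with pytest.raises(ConfigError, match="finite"):
            train(ClassifierSpec(name="KNN"), X, y)

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_deterministic_given_seed(self, name):
        X, y = _two_clusters(seed=1, spacing=2.0)
        probe = np.random.default_rng(99).normal(size=(30, 4)) * 3
        m1 = train(ClassifierSpec(name=name, seed=5), X, y, X[:20], y[:20])
        m2 = train(ClassifierSpec(name=name, seed=5), X, y, X[:20], y[:20])
        np.testing.assert_array_equal(m1.predict_batch(probe), m2.predict_batch(probe))

    def test_dimension_mismatch_rejected(self):
        X, y = _two_clusters()
        model = train(ClassifierSpec(name="LDA"), X, y)
        with pytest.raises(ConfigError, match="dimension"):
            model.predict(np.zeros(7))

    @pytest.mark.parametrize("name", ["LDA", "MLE", "KNN", "NMF", "DT"])
    def test_row_order_free_fits(self, name):
        """Order-free classifiers: permuting training rows changes nothing."""
        X, y = make_separable_dataset(3, n_classes=4, n_per_class=20, spacing=3.0)
        probe = np.random.default_rng(1).normal(scale=4, size=(40, X.shape[1]))
        perm = np.random.default_rng(2).permutation(len(y))
        m1 = train(ClassifierSpec(name=name, seed=0), X, y)
        m2 = train(ClassifierSpec(name=name, seed=0), X[perm], y[perm])
        np.testing.assert_array_equal(m1.predict_batch(probe), m2.predict_batch(probe))

    @pytest.mark.parametrize("name", ["MLP", "SSOM"])
    def test_seeded_stochastic_fits_reproducible(self, name):
        X, y = make_separable_dataset(4, n_classes=3, n_per_class=20, spacing=3.0)
        probe = np.random.default_rng(1).normal(scale=4, size=(40, X.shape[1]))
        m1 = train(ClassifierSpec(name=name, seed=11), X, y, X[:15], y[:15])
        m2 = train(ClassifierSpec(name=name, seed=11), X, y, X[:15], y[:15])
        np.testing.assert_array_equal(m1.predict_batch(probe), m2.predict_batch(probe))

    def test_model_persistence_roundtrip(self, tmp_path):
        X, y = _two_clusters()
        model = train(ClassifierSpec(name="MLE", seed=0), X, y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        probe = np.random.default_rng(3).normal(size=(20, 4))
        np.testing.assert_array_equal(model.predict_batch(probe), back.predict_batch(probe))


class TestKnn:
    def test_training_sample_maps_to_own_label(self):
        X, y = make_separable_dataset(0, n_classes=3, n_per_class=15)
        model = train(ClassifierSpec(name="KNN"), X, y)
        pred = model.predict_batch(X)
        assert np.all(pred == y)


class TestNnls:
    def test_self_query_returns_own_class_undercomplete(self):
        """Fewer basis columns than dimensions: the self-reconstruction is the
        unique exact solution, so a training sample maps to its own class."""
        X, y = make_separable_dataset(1, n_classes=4, n_per_class=6, d=32)
        model = train(ClassifierSpec(name="NMF"), X, y)
        pred = model.predict_batch(X)
        assert np.mean(pred == y) == 1.0

    def test_self_query_overcomplete_usually_own_class(self):
        # overcomplete basis admits many exact reconstructions; the dominant
        # coefficient still lands in the right class almost always
        X, y = make_separable_dataset(1, n_classes=4, n_per_class=15, d=8)
        model = train(ClassifierSpec(name="NMF"), X, y)
        assert np.mean(model.predict_batch(X) == y) >= 0.95

    def test_per_class_sum_variant_runs(self):
        X, y = make_separable_dataset(1, n_classes=3, n_per_class=10)
        model = train(ClassifierSpec(name="NMF", params={"per_class_sum": True}), X, y)
        assert np.mean(model.predict_batch(X) == y) == 1.0


class TestMle:
    def test_1d_two_class_closed_form(self):
        """Equal-variance 1-D Gaussians: decision at the midpoint of the means."""
        rng = np.random.default_rng(0)
        n = 2001
        base = rng.standard_normal(n)
        base = (base - base.mean()) / base.std(ddof=1)  # exactly mean 0, sd 1
        X = np.concatenate([base, base + 10.0])[:, None]
        y = np.asarray(["lo"] * n + ["hi"] * n, dtype=object)
        model = train(ClassifierSpec(name="MLE"), X, y)
        assert model.predict(np.array([1.0])) == "lo"
        assert model.predict(np.array([4.999])) == "lo"
        assert model.predict(np.array([5.001])) == "hi"
        # exact agreement with the closed-form Gaussian likelihood rule
        # (probe grid avoids the exact decision point, where only the
        # tie-break differs)
        probes = np.linspace(-5, 15, 400)[:, None]
        mu = np.array([0.0, 10.0])
        var = np.array([base.var(ddof=1), base.var(ddof=1)])
        ll = -0.5 * np.log(2 * np.pi * var) - (probes - mu) ** 2 / (2 * var)
        expected = np.where(ll[:, 0] >= ll[:, 1], "lo", "hi")
        np.testing.assert_array_equal(model.predict_batch(probes), expected)

    def test_singular_covariance_survives(self):
        # duplicated feature column makes the covariance singular
        rng = np.random.default_rng(2)
        base = rng.standard_normal((40, 1))
        X = np.hstack([base, base])
        X[:20] += 6.0
        y = np.asarray(["a"] * 20 + ["b"] * 20, dtype=object)
        model = train(ClassifierSpec(name="MLE"), X, y)
        assert np.mean(model.predict_batch(X) == y) == 1.0


class TestRfn:
    def test_orthogonal_patterns_reduce_to_nearest_mean(self):
        """Disjoint-support, equal-norm class means: RFN equals nearest-mean.

        Noise is paired symmetrically (e, -e) on the support coordinates so
        the fitted class means are *exactly* the orthogonal patterns; the
        one-step fixed point then equals the normalized pattern match, which
        for equal support sizes is nearest-mean classification.
        """
        rng = np.random.default_rng(0)
        d, C, n_half = 12, 3, 15
        patterns = np.zeros((C, d))
        for k in range(C):
            patterns[k, 4 * k:4 * (k + 1)] = 1.0
        blocks, labels = [], []
        for k in range(C):
            noise = rng.uniform(-0.2, 0.2, size=(n_half, d)) * patterns[k]
            blocks.append(patterns[k] + np.vstack([noise, -noise]))
            labels += [f"c{k}"] * (2 * n_half)
        X = np.vstack(blocks)
        y = np.asarray(labels, dtype=object)
        model = train(ClassifierSpec(name="RFN", normalization="none"), X, y)
        np.testing.assert_allclose(
            model.model.W_, patterns, atol=1e-12
        )  # means are exactly the patterns
        probes = rng.uniform(0, 1, size=(200, d))
        nearest = np.asarray(
            [f"c{int(np.argmin(((p - patterns) ** 2).sum(axis=1)))}" for p in probes],
            dtype=object,
        )
        np.testing.assert_array_equal(model.predict_batch(probes), nearest)


class TestMlp:
    def test_early_stopping_bounded_epochs(self):
        X, y = _two_clusters(seed=3, spacing=6.0)
        model = train(ClassifierSpec(name="MLP", seed=0), X, y, X[:30], y[:30])
        assert 1 <= model.model.epochs_run_ <= 200
        # clearly separable data should stop well before the epoch cap
        assert model.model.epochs_run_ < 200


class TestSvm:
    def test_multiclass_separable(self):
        X, y = make_separable_dataset(7, n_classes=4, n_per_class=25, spacing=6.0)
        model = train(ClassifierSpec(name="SVM", seed=0), X, y)
        assert np.mean(model.predict_batch(X) == y) == 1.0
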
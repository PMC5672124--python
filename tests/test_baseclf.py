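"""Base classifiers: closed-form checks, oracle equivalence, separability."""

import numpy as np
import pytest

from lfpdecode.baseclf import (FbannHyper, FbannModel, PnnHyper, PnnModel,
                               RbfnnHyper, RbfnnModel, ZScore, fbann_forward,
                               fbann_train, model_from_dict, pnn_predict, pnn_train,
                               rbfnn_predict, rbfnn_train, sigmoid)
from lfpdecode.errors import (ConfigurationError, DegenerateTrainingError)


def _blobs(n=200, seed=0, sep=4.0, dim=5):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n // 2, dim))
    X1 = rng.normal(sep, 1.0, size=(n // 2, dim))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestFbannForward:
    def test_all_zero_parameters_give_half(self):
        m = FbannModel(W1=np.zeros((3, 2)), b1=np.zeros(3), w2=np.zeros(3), b2=0.0)
        assert fbann_forward(m, np.zeros(2)) == pytest.approx(0.5)

    def test_single_unit_closed_form(self):
        # f(1 * f(1*0 + 0) + 0) = f(f(0)) = f(0.5)
        m = FbannModel(W1=[[1.0]], b1=[0.0], w2=[1.0], b2=0.0)
        assert fbann_forward(m, [0.0]) == pytest.approx(1 / (1 + np.exp(-0.5)))
        assert fbann_forward(m, [0.0]) == pytest.approx(0.6225, abs=1e-4)

    def test_monotone_in_inputs_with_positive_weights(self):
        rng = np.random.default_rng(0)
        m = FbannModel(W1=rng.uniform(0.1, 1, (4, 3)), b1=rng.uniform(-1, 1, 4),
                       w2=rng.uniform(0.1, 1, 4), b2=0.0)
        x = np.array([0.0, 0.0, 0.0])
        base = fbann_forward(m, x)
        for q in range(3):
            x2 = x.copy()
            x2[q] += 0.5
            assert fbann_forward(m, x2) >= base

    def test_agrees_with_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, mdim = rng.integers(1, 6), rng.integers(1, 6)
            model = FbannModel(W1=rng.normal(size=(n, mdim)), b1=rng.normal(size=n),
                               w2=rng.normal(size=n), b2=float(rng.normal()))
            x = rng.normal(size=mdim)
            # independent elementwise evaluation of the defining equation
            acc = model.b2
            for p in range(n):
                h = model.b1[p]
                for q in range(mdim):
                    h += model.W1[p, q] * x[q]
                acc += model.w2[p] * (1 / (1 + np.exp(-h)))
            expected = 1 / (1 + np.exp(-acc))
            assert fbann_forward(model, x) == pytest.approx(expected, abs=1e-12)

    def test_score_in_open_unit_interval(self):
        m = FbannModel(W1=[[10.0]], b1=[5.0], w2=[30.0], b2=10.0)
        assert 0.0 < fbann_forward(m, [100.0]) <= 1.0

    def test_dimension_mismatch(self):
        m = FbannModel(W1=np.zeros((2, 3)), b1=np.zeros(2), w2=np.zeros(2), b2=0.0)
        with pytest.raises(ConfigurationError):
            fbann_forward(m, np.zeros(4))


class TestFbannTrain:
    def test_separable_blobs(self):
        X, y = _blobs(seed=0)
        m = fbann_train(X, y, FbannHyper(seed=0))
        acc = ((m.predict_score(X) >= 0.5) == y).mean()
        assert acc >= 0.95

    def test_flipped_labels_symmetric_accuracy(self):
        X, y = _blobs(seed=1)
        acc = ((fbann_train(X, y, FbannHyper(seed=0)).predict_score(X) >= 0.5) == y).mean()
        accf = ((fbann_train(X, 1 - y, FbannHyper(seed=0)).predict_score(X) >= 0.5) == (1 - y)).mean()
        assert acc >= 0.95 and accf >= 0.95

    def test_xor_with_enough_capacity(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        m = fbann_train(X, y, FbannHyper(n_hidden=4, learning_rate=2.0,
                                         max_epochs=5000, seed=1))
        assert (((m.predict_score(X) >= 0.5)) == y).all()

    def test_training_error_decreases(self):
        X, y = _blobs(seed=2)
        m = fbann_train(X, y, FbannHyper(seed=0, learning_rate=0.1, max_epochs=300))
        h = np.array(m.history)
        assert h[-1] < h[0]
        # steepest descent with a fixed step: allow only tiny upticks
        assert np.all(np.diff(h) <= 1e-3)

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(DegenerateTrainingError):
            fbann_train(X, np.ones(5))


class TestRbfnn:
    def test_unit_activation_at_center(self):
        m = RbfnnModel(centers=[[1.0, 2.0]], widths=[1.0], weights=[1.0], bias=0.0)
        assert rbfnn_predict(m, [1.0, 2.0]) == pytest.approx(1.0)

    def test_kernel_decay_far_away(self):
        m = RbfnnModel(centers=[[0.0]], widths=[1.0], weights=[1.0], bias=0.0)
        assert rbfnn_predict(m, [50.0]) == pytest.approx(0.0, abs=1e-12)

    def test_separable_blobs(self):
        X, y = _blobs(seed=3)
        m = rbfnn_train(X, y, RbfnnHyper(seed=0))
        acc = ((m.predict_score(X) >= 0.5) == y).mean()
        assert acc >= 0.95

    def test_output_clipped_to_unit_interval(self):
        X, y = _blobs(seed=4, n=60)
        m = rbfnn_train(X, y, RbfnnHyper(n_centers=10, seed=0))
        s = m.predict_score(np.vstack([X, X * 10]))
        assert np.all((s >= 0.0) & (s <= 1.0))

    def test_too_few_samples_for_centers(self):
        X, y = _blobs(n=10, seed=5)
        with pytest.raises(ConfigurationError):
            rbfnn_train(X, y, RbfnnHyper(n_centers=20))

    def test_invalid_width_rejected(self):
        with pytest.raises(ConfigurationError):
            RbfnnModel(centers=[[0.0]], widths=[0.0], weights=[1.0], bias=0.0)


class TestPnn:
    def test_posterior_concentrates_on_stored_pattern(self):
        m = PnnModel(classes=[0, 1], patterns=[np.array([[0.0, 0.0]]), np.array([[5.0, 5.0]])],
                     sigma=0.1, priors=[0.5, 0.5])
        post = pnn_predict(m, [0.0, 0.0])
        assert post[0] > 0.999

    def test_equidistant_point_splits_evenly(self):
        m = PnnModel(classes=[0, 1], patterns=[np.array([[-1.0]]), np.array([[1.0]])],
                     sigma=1.0, priors=[0.5, 0.5])
        post = pnn_predict(m, [0.0])
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_duplicating_patterns_leaves_posterior_unchanged(self):
        rng = np.random.default_rng(6)
        pats = [rng.normal(0, 1, (10, 3)), rng.normal(2, 1, (8, 3))]
        m1 = PnnModel(classes=[0, 1], patterns=pats, sigma=0.7, priors=[0.5, 0.5])
        m2 = PnnModel(classes=[0, 1], patterns=[np.vstack([p, p]) for p in pats],
                      sigma=0.7, priors=[0.5, 0.5])
        x = rng.normal(1, 1, 3)
        np.testing.assert_allclose(pnn_predict(m1, x), pnn_predict(m2, x), rtol=1e-12)

    def test_separable_blobs(self):
        X, y = _blobs(seed=7)
        Xte, yte = _blobs(seed=8)
        m = pnn_train(X, y, PnnHyper(seed=0))
        pred = np.asarray(m.predict(Xte))
        assert (pred == yte).mean() >= 0.95

    def test_sigma_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            PnnModel(classes=[0, 1], patterns=[np.zeros((1, 2)), np.ones((1, 2))],
                     sigma=0.0, priors=[0.5, 0.5])
        with pytest.raises(ConfigurationError):
            pnn_train(np.zeros((4, 2)), np.array([0, 0, 1, 1]), PnnHyper(sigma=-1.0))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            pnn_train(np.zeros((4, 2)), np.zeros(4))


class TestNormalizationAndSerialization:
    def test_zscore_statistics(self):
        X = np.array([[1.0, 10.0], [3.0, 10.0]])
        z = ZScore().fit(X)
        Z = z.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z[:, 0].std(), 1.0)
        assert np.all(np.isfinite(Z))  # constant column passes through

    @pytest.mark.parametrize("trainer, hyper", [
        (fbann_train, FbannHyper(max_epochs=50, seed=0)),
        (rbfnn_train, RbfnnHyper(n_centers=5, seed=0)),
        (pnn_train, PnnHyper(sigma=1.0)),
    ])
    def test_model_json_roundtrip_preserves_predictions(self, trainer, hyper):
        X, y = _blobs(n=40, seed=9)
        model = trainer(X, y, hyper)
        clone = model_from_dict(model.to_dict())
        np.testing.assert_allclose(model.predict_score(X), clone.predict_score(X),
                                   rtol=1e-12)
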
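"""Learners against linear-algebra oracles: LSSVM KKT system, ELM normal
equations, BPNN descent, classifier determinism and the frozen prediction path."""

import numpy as np
import pytest

from hsichem import (
    BPNNConfig,
    ClassifierSpec,
    ELMConfig,
    LSSVMConfig,
    bpnn_train,
    chain_from_name,
    elm_train,
    load_model,
    lssvm_train,
    predict,
    save_model,
    train_classifier,
)
from hsichem.models import _rbf_kernel, _sigmoid


@pytest.fixture()
def toy_regression(rng):
    X = rng.normal(size=(20, 6))
    y = X @ rng.normal(size=6) + rng.normal(0, 0.1, 20)
    return X, y


class TestClassifiers:
    def _separable(self):
        rng = np.random.default_rng(0)
        centers = {"a": (0, 0), "b": (8, 0), "c": (0, 8)}
        X, labels = [], []
        for lab, c in centers.items():
            X.append(rng.normal(c, 0.3, size=(10, 2)))
            labels += [lab] * 10
        return np.vstack(X), np.array(labels)

    def test_lr_separable_training_accuracy(self):
        X, labels = self._separable()
        model = train_classifier(X, labels, ClassifierSpec(kind="LR"))
        assert (model.predict(X) == labels).all()

    def test_lr_row_permutation_invariance(self):
        X, labels = self._separable()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(labels))
        a = train_classifier(X, labels, ClassifierSpec(kind="LR"))
        b = train_classifier(X[perm], labels[perm], ClassifierSpec(kind="LR"))
        assert (a.predict(X) == b.predict(X)).all()

    @pytest.mark.parametrize("kind", ["SVM", "MLP"])
    def test_seeded_determinism(self, kind):
        X, labels = self._separable()
        spec = ClassifierSpec(kind=kind, seed=3)
        a = train_classifier(X, labels, spec)
        b = train_classifier(X, labels, spec)
        assert (a.predict(X) == b.predict(X)).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(10, 3)), np.repeat("a", 10),
                             ClassifierSpec())

    def test_predicted_labels_from_training_set(self, rng):
        X, labels = self._separable()
        model = train_classifier(X, labels, ClassifierSpec(kind="SVM"))
        preds = model.predict(rng.normal(0, 10, size=(50, 2)))
        assert set(preds) <= set(labels)


class TestLSSVM:
    def test_rbf_kernel_unity_at_zero_distance(self, rng):
        x = rng.normal(size=(1, 7))
        assert _rbf_kernel(x, x, 2.0)[0, 0] == pytest.approx(1.0)

    def test_kkt_system_matches_dense_oracle(self, toy_regression):
        X, y = toy_regression
        cfg = LSSVMConfig(gamma=2.0, sigma2=2.0)
        model = lssvm_train(X, y, cfg)
        # independent assembly: explicit loops, generic dense solve
        Xs = (X - model.x_mean) / model.x_scale
        n, p = Xs.shape
        K = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                K[i, j] = np.exp(-np.mean((Xs[i] - Xs[j]) ** 2) / cfg.sigma2)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1
        A[1:, 0] = 1
        A[1:, 1:] = K + np.eye(n) / cfg.gamma
        sol = np.linalg.solve(A, np.concatenate([[0.0], y]))
        np.testing.assert_allclose(model.extras["b"], sol[0], atol=1e-8)
        np.testing.assert_allclose(model.extras["alpha"], sol[1:], atol=1e-8)

    def test_large_gamma_interpolates_toy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        model = lssvm_train(X, y, LSSVMConfig(gamma=1e9, sigma2=2.0))
        np.testing.assert_allclose(model.predict(X), y, atol=1e-4)

    def test_linear_kernel_large_gamma_approaches_ols(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.5, -2.0, 0.7]) + rng.normal(0, 0.05, 40)
        model = lssvm_train(X, y, LSSVMConfig(gamma=1e8, kernel="linear"))
        # effective primal coefficients: w = X_std^T alpha (per standardized band)
        w = model.extras["X_train"].T @ model.extras["alpha"]
        Xs = model.extras["X_train"]
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(40), Xs]), y, rcond=None
        )[0][1:]
        np.testing.assert_allclose(w, beta, atol=1e-3)


class TestELM:
    def test_interpolation_capacity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = elm_train(X, y, ELMConfig(n_hidden=12, seed=0))
        assert float(np.mean((model.predict(X) - y) ** 2)) <= 1e-6

    def test_normal_equations_satisfied(self, toy_regression):
        X, y = toy_regression
        model = elm_train(X, y, ELMConfig(n_hidden=40, seed=1))
        H, beta = model.extras["H_train"], model.extras["beta"]
        residual = H.T @ (H @ beta - y)
        assert np.abs(residual).max() <= 1e-8

    def test_beta_matches_pinv_oracle(self, toy_regression):
        X, y = toy_regression
        model = elm_train(X, y, ELMConfig(n_hidden=15, seed=2))
        Xs = (X - model.x_mean) / model.x_scale
        H = _sigmoid(Xs @ model.extras["W"] + model.extras["bias"])
        np.testing.assert_allclose(model.extras["beta"],
                                   np.linalg.pinv(H) @ y, atol=1e-8)

    def test_seed_determinism(self, toy_regression):
        X, y = toy_regression
        a = elm_train(X, y, ELMConfig(seed=7))
        b = elm_train(X, y, ELMConfig(seed=7))
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestBPNN:
    def test_loss_descends(self, toy_regression):
        X, y = toy_regression
        model = bpnn_train(X, y, BPNNConfig(epochs=1000, seed=0))
        traj = model.extras["loss_trajectory"]
        assert traj[-1] <= traj[0]

    def test_early_stop_flag(self, rng):
        # a linear target an 8-neuron net can hit quickly; target on the
        # standardized scale the trainer works in
        X = rng.normal(size=(15, 2))
        y = X[:, 0]
        model = bpnn_train(X, y, BPNNConfig(epochs=5000, target_mse=0.05, seed=0))
        assert model.extras["early_stop"]
        assert model.extras["loss_trajectory"][-1] <= 0.05
        assert len(model.extras["loss_trajectory"]) < 5000

    def test_trajectory_deterministic(self, toy_regression):
        X, y = toy_regression
        a = bpnn_train(X, y, BPNNConfig(epochs=50, seed=3))
        b = bpnn_train(X, y, BPNNConfig(epochs=50, seed=3))
        np.testing.assert_array_equal(a.extras["loss_trajectory"],
                                      b.extras["loss_trajectory"])


class TestPredictionPath:
    def test_predict_is_pure(self, toy_regression):
        X, y = toy_regression
        model = elm_train(X, y, ELMConfig(seed=0))
        np.testing.assert_array_equal(predict(model, X), predict(model, X))

    def test_band_axis_mismatch_rejected(self, small_spectrum_set):
        sset = small_spectrum_set
        model = elm_train(sset.spectra, sset.concentrations.iloc[:, 0],
                          ELMConfig(seed=0), wavelengths=sset.wavelengths)
        with pytest.raises(ValueError, match="axis"):
            model.predict(sset.spectra, wavelengths=sset.wavelengths + 1.0)
        with pytest.raises(ValueError, match="bands"):
            model.predict(sset.spectra[:, :100])

    def test_chain_and_subset_replayed(self, small_spectrum_set):
        from hsichem.selection import WavelengthSubset

        sset = small_spectrum_set
        chain = chain_from_name("SNV")
        subset = WavelengthSubset(indices=np.arange(0, 270, 5), selector="manual")
        y = sset.concentrations.iloc[:, 0].to_numpy()
        model = lssvm_train(chain(sset.spectra)[:, subset.indices], y)
        model.chain = chain
        model.subset = subset
        direct = lssvm_train(chain(sset.spectra)[:, subset.indices], y)
        np.testing.assert_allclose(
            model.predict(sset.spectra),
            direct.predict(chain(sset.spectra)[:, subset.indices]),
            atol=1e-10,
        )

    def test_archive_roundtrip(self, tmp_path, toy_regression):
        X, y = toy_regression
        model = lssvm_train(X, y)
        path = save_model(model, tmp_path / "m.pkl")
        back = load_model(path)
        np.testing.assert_array_equal(back.predict(X), model.predict(X))
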
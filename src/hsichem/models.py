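"""Calibration and classification learners, bundled with their pre-processing.

Classifiers (logistic regression, SVM, MLP) ride on scikit-learn.  The three
regression learners are implemented here with the study's fixed settings:

* LSSVM — least-squares SVM regression solved from the single KKT linear
  system ``[[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]`` with an RBF
  kernel.  The kernel uses the *mean* squared band difference,
  ``K(u, v) = exp(-mean((u - v)^2) / sigma2)``, so the width ``sigma2 = 2`` is
  meaningful independently of how many bands the subset retains.
* ELM — extreme learning machine: random sigmoid hidden layer (weights
  uniform(-1, 1), biases uniform(0, 1), seeded), minimum-norm least-squares
  output weights.
* BPNN — single-hidden-layer sigmoid network trained by plain full-batch
  gradient descent (8 neurons, 1000 epochs, learning rate 0.6, target MSE
  1e-5); inputs and targets are standardized internally so that rate is
  stable.

A :class:`TrainedPredictor` freezes the pre-processing chain, band subset,
band axis and normalization constants alongside the learner, so prediction on
raw spectra always replays the exact training path.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import PreprocessChain, apply_chain
from .selection import WavelengthSubset

__all__ = [
    "ClassifierSpec",
    "LSSVMConfig",
    "ELMConfig",
    "BPNNConfig",
    "TrainedPredictor",
    "train_classifier",
    "lssvm_train",
    "elm_train",
    "bpnn_train",
    "predict",
    "save_model",
    "load_model",
]

ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to fit and its fixed settings."""

    kind: str = "LR"                  # LR | SVM | MLP
    mlp_hidden: int = 50
    svm_kernel: str = "rbf"
    svm_c: float = 10.0
    lr_c: float = 1e4                 # large C ~ unregularized multinomial fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("LR", "SVM", "MLP"):
            raise ValueError("classifier kind must be LR, SVM or MLP")


@dataclass(frozen=True)
class LSSVMConfig:
    gamma: float = 2.0
    sigma2: float = 2.0
    kernel: str = "rbf"               # rbf | linear

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.sigma2 <= 0:
            raise ValueError("gamma and sigma2 must be positive")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")


@dataclass(frozen=True)
class ELMConfig:
    n_hidden: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden node")


@dataclass(frozen=True)
class BPNNConfig:
    n_hidden: int = 8
    epochs: int = 1000
    learning_rate: float = 0.6
    target_mse: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class TrainedPredictor:
    """A fitted learner plus everything needed to replay its input pipeline."""

    task: str                          # "classification" | "regression"
    kind: str
    learner: object
    chain: PreprocessChain | None = None
    subset: WavelengthSubset | None = None
    wavelengths: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def _prepare(self, spectra: np.ndarray, wavelengths=None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        if wavelengths is not None:
            if self.wavelengths is None or not np.array_equal(
                np.asarray(wavelengths), self.wavelengths
            ):
                raise ValueError("band axis does not match the model's stored axis")
        elif self.wavelengths is not None and X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"expected {self.wavelengths.size} bands, got {X.shape[1]}"
            )
        if self.chain is not None:
            X = apply_chain(X, self.chain)
        if self.subset is not None:
            X = X[:, self.subset.indices]
        if self.x_mean is not None:
            X = (X - self.x_mean) / self.x_scale
        return X

    def predict(self, spectra: np.ndarray, wavelengths=None) -> np.ndarray:
        X = self._prepare(spectra, wavelengths)
        if self.task == "classification":
            return self.learner.predict(X)
        kind = self.kind
        if kind == "LSSVM":
            K = _lssvm_kernel(
                X, self.extras["X_train"], self.extras["sigma2"],
                self.extras.get("kernel", "rbf"),
            )
            return K @ self.extras["alpha"] + self.extras["b"]
        if kind == "ELM":
            H = _sigmoid(X @ self.extras["W"] + self.extras["bias"])
            return H @ self.extras["beta"]
        if kind == "BPNN":
            h = _sigmoid(X @ self.extras["W1"] + self.extras["b1"])
            z = h @ self.extras["W2"] + self.extras["b2"]
            return z.ravel() * self.extras["y_scale"] + self.extras["y_mean"]
        raise ValueError(f"unknown learner kind {kind!r}")


def _standardize_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _apply_pipeline(X, chain, subset):
    X = np.asarray(X, dtype=float)
    if chain is not None:
        X = apply_chain(X, chain)
    if subset is not None:
        X = X[:, subset.indices]
    return X


def train_classifier(
    X,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    chain: PreprocessChain | None = None,
    subset: WavelengthSubset | None = None,
    wavelengths=None,
) -> TrainedPredictor:
    """Fit a multiclass classifier (LR multinomial, SVM one-vs-rest, MLP)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.multiclass import OneVsRestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples")
    Xp = _apply_pipeline(X, chain, subset)
    mu, sd = _standardize_fit(Xp)
    Xs = (Xp - mu) / sd

    if spec.kind == "LR":
        learner = LogisticRegression(C=spec.lr_c, max_iter=5000)
    elif spec.kind == "SVM":
        learner = OneVsRestClassifier(
            SVC(kernel=spec.svm_kernel, C=spec.svm_c, gamma="scale")
        )
    else:
        learner = MLPClassifier(
            hidden_layer_sizes=(spec.mlp_hidden,),
            max_iter=3000,
            random_state=spec.seed,
        )
    learner.fit(Xs, labels)
    return TrainedPredictor(
        task="classification", kind=spec.kind, learner=learner, chain=chain,
        subset=subset,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        x_mean=mu, x_scale=sd,
    )


def _rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """RBF on the mean squared band difference: K = exp(-mean((u-v)^2)/sigma2)."""
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).mean(axis=2)
    return np.exp(-d2 / sigma2)


def _lssvm_kernel(A, B, sigma2: float, kernel: str) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    return _rbf_kernel(A, B, sigma2)


def lssvm_train(
    X,
    y,
    config: LSSVMConfig = LSSVMConfig(),
    chain: PreprocessChain | None = None,
    subset: WavelengthSubset | None = None,
    wavelengths=None,
) -> TrainedPredictor:
    """LS-SVM regression from the KKT system (see module docstring)."""
    y = np.asarray(y, dtype=float).ravel()
    Xp = _apply_pipeline(X, chain, subset)
    if Xp.shape[0] < 2:
        raise ValueError("LSSVM needs at least 2 training samples")
    mu, sd = _standardize_fit(Xp)
    Xs = (Xp - mu) / sd
    n = Xs.shape[0]
    K = _lssvm_kernel(Xs, Xs, config.sigma2, config.kernel)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / config.gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular LS-SVM system: {exc}") from exc
    return TrainedPredictor(
        task="regression", kind="LSSVM", learner=None, chain=chain, subset=subset,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        x_mean=mu, x_scale=sd,
        extras={"alpha": sol[1:], "b": float(sol[0]), "X_train": Xs,
                "sigma2": config.sigma2, "gamma": config.gamma,
                "kernel": config.kernel, "kernel_matrix": K},
    )


def elm_train(
    X,
    y,
    config: ELMConfig = ELMConfig(),
    chain: PreprocessChain | None = None,
    subset: WavelengthSubset | None = None,
    wavelengths=None,
) -> TrainedPredictor:
    """Extreme learning machine: seeded random hidden layer, pseudoinverse output."""
    y = np.asarray(y, dtype=float).ravel()
    Xp = _apply_pipeline(X, chain, subset)
    mu, sd = _standardize_fit(Xp)
    Xs = (Xp - mu) / sd
    rng = np.random.default_rng(config.seed)
    p = Xs.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(p, config.n_hidden))
    bias = rng.uniform(0.0, 1.0, size=config.n_hidden)
    H = _sigmoid(Xs @ W + bias)
    beta = np.linalg.pinv(H) @ y            # minimum-norm least squares
    return TrainedPredictor(
        task="regression", kind="ELM", learner=None, chain=chain, subset=subset,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        x_mean=mu, x_scale=sd,
        extras={"W": W, "bias": bias, "beta": beta, "H_train": H, "y_train": y},
    )


def bpnn_train(
    X,
    y,
    config: BPNNConfig = BPNNConfig(),
    chain: PreprocessChain | None = None,
    subset: WavelengthSubset | None = None,
    wavelengths=None,
) -> TrainedPredictor:
    """Backpropagation network: full-batch gradient descent on the MSE."""
    y = np.asarray(y, dtype=float).ravel()
    Xp = _apply_pipeline(X, chain, subset)
    mu, sd = _standardize_fit(Xp)
    Xs = (Xp - mu) / sd
    y_mean, y_scale = float(y.mean()), float(y.std() or 1.0)
    ys = (y - y_mean) / y_scale

    rng = np.random.default_rng(config.seed)
    n, p = Xs.shape
    h = config.n_hidden
    W1 = rng.uniform(-0.5, 0.5, size=(p, h))
    b1 = np.zeros(h)
    W2 = rng.uniform(-0.5, 0.5, size=(h, 1))
    b2 = np.zeros(1)
    eta = config.learning_rate
    trajectory = []
    early_stop = False
    for epoch in range(config.epochs):
        H = _sigmoid(Xs @ W1 + b1)
        out = (H @ W2 + b2).ravel()
        err = out - ys
        mse = float(err @ err) / n
        trajectory.append(mse)
        if not np.isfinite(mse):
            raise ValueError(f"BPNN training diverged at epoch {epoch}")
        if mse <= config.target_mse:
            early_stop = True
            break
        g_out = 2.0 * err[:, None] / n
        gW2 = H.T @ g_out
        gb2 = g_out.sum(axis=0)
        g_h = (g_out @ W2.T) * H * (1.0 - H)
        gW1 = Xs.T @ g_h
        gb1 = g_h.sum(axis=0)
        W1 -= eta * gW1
        b1 -= eta * gb1
        W2 -= eta * gW2
        b2 -= eta * gb2
    return TrainedPredictor(
        task="regression", kind="BPNN", learner=None, chain=chain, subset=subset,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        x_mean=mu, x_scale=sd,
        extras={"W1": W1, "b1": b1, "W2": W2, "b2": b2,
                "y_mean": y_mean, "y_scale": y_scale,
                "loss_trajectory": np.array(trajectory), "early_stop": early_stop},
    )


def predict(model: TrainedPredictor, spectra, wavelengths=None) -> np.ndarray:
    """Apply the model's stored chain, band subset and learner to raw spectra."""
    return model.predict(spectra, wavelengths)


def save_model(model: TrainedPredictor, path) -> Path:
    """Serialize a trained predictor (versioned pickle archive)."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"version": ARCHIVE_VERSION, "model": model}, fh)
    return path


def load_model(path) -> TrainedPredictor:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError("unsupported model archive version")
    return payload["model"]
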
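"""Extreme Learning Machine classifier.

A single-hidden-layer feed-forward network in which the hidden layer is
*random and fixed*: input weights w and biases b are drawn once from
U(-1, 1), the hidden activations form

    H[j, i] = g(<w_i, x_j> + b_i),        j = 1..N samples, i = 1..L nodes,

and only the output weights beta are learned, as the minimum-norm
least-squares solution of H beta = Y with Y the {0, 1} one-hot target matrix:

    beta = H^+ Y                       (Moore-Penrose pseudoinverse, ridge = 0)
    beta = (H'H + lambda I)^-1 H' Y    (ridge regularization, lambda > 0)

Prediction is the argmax over class scores H beta, ties broken toward the
lowest class index.  The pseudoinverse route uses a rank-revealing solve with
singular values below max(N, L) * eps * sigma_max treated as zero.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ContractViolation
from .synthetic import FeatureTable

__all__ = ["ELMClassifier", "hidden_matrix", "elm_train", "elm_predict", "save_model", "load_model"]

ACTIVATIONS = {
    "sigmoid": expit,
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
}


def hidden_matrix(X: np.ndarray, w, b: np.ndarray | None = None, activation: str | None = None) -> np.ndarray:
    """Hidden-layer output matrix H with H[j, i] = g(<w_i, x_j> + b_i).

    Accepts either a fitted :class:`ELMClassifier` as the second argument or
    explicit ``(w, b, activation)``.
    """
    if isinstance(w, ELMClassifier):
        model = w
        check_is_fitted(model, "input_weights_")
        w, b, activation = model.input_weights_, model.biases_, model.activation
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ContractViolation("X contains non-finite entries")
    if X.ndim != 2 or X.shape[1] != w.shape[1]:
        raise ContractViolation(
            f"X has shape {X.shape}, expected (*, {w.shape[1]}) to match input weights"
        )
    try:
        g = ACTIVATIONS[activation]
    except KeyError:
        raise ContractViolation(
            f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None
    return g(X @ w.T + b)


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Extreme learning machine for multiclass classification.

    Parameters
    ----------
    n_hidden : int, default 100
        Number of hidden nodes L.
    activation : {"sigmoid", "relu", "tanh"}, default "sigmoid"
        Hidden-node activation g.
    alpha : float, default 0.0
        Ridge coefficient lambda; 0 selects the pure pseudoinverse solution.
    random_state : int or None
        Seed for the U(-1, 1) draw of input weights and biases.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique class labels.
    input_weights_ : ndarray of shape (L, n)
    biases_ : ndarray of shape (L,)
    output_weights_ : ndarray of shape (L, n_classes)
        The learned beta.
    """

    def __init__(
        self,
        n_hidden: int = 100,
        activation: str = "sigmoid",
        alpha: float = 0.0,
        random_state: int | None = 0,
    ):
        self.n_hidden = n_hidden
        self.activation = activation
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ContractViolation("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ContractViolation("X contains non-finite entries")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha (ridge coefficient) must be >= 0")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError(
                f"training data contains a single class ({self.classes_[0]!r}); "
                "at least two classes are required"
            )
        N, n = X.shape
        L = self.n_hidden
        if L > N:
            warnings.warn(
                f"n_hidden={L} exceeds the {N} training samples; the system is "
                "underdetermined (minimum-norm solution returned)",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(L, n))
        self.biases_ = rng.uniform(-1.0, 1.0, size=L)
        H = hidden_matrix(X, self.input_weights_, self.biases_, self.activation)
        Y = np.zeros((N, len(self.classes_)))
        Y[np.arange(N), y_idx] = 1.0
        if self.alpha == 0.0:
            # minimum-norm least squares; rcond=None applies the
            # max(N, L) * eps * sigma_max singular-value cutoff
            beta, *_ = np.linalg.lstsq(H, Y, rcond=None)
        else:
            A = H.T @ H + self.alpha * np.eye(L)
            beta = np.linalg.solve(A, H.T @ Y)
        self.output_weights_ = beta
        self.n_features_in_ = n
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "output_weights_")
        H = hidden_matrix(X, self.input_weights_, self.biases_, self.activation)
        return H @ self.output_weights_

    def predict(self, X) -> np.ndarray:
        # np.argmax returns the first maximum: ties go to the lowest class index
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def elm_train(
    table: FeatureTable,
    n_hidden: int = 100,
    activation: str = "sigmoid",
    alpha: float = 0.0,
    seed: int = 0,
) -> ELMClassifier:
    """Train an ELM on a feature table (thin wrapper over :class:`ELMClassifier`)."""
    return ELMClassifier(
        n_hidden=n_hidden, activation=activation, alpha=alpha, random_state=seed
    ).fit(table.X, table.labels)


def elm_predict(model: ELMClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted integer labels plus the raw class-score matrix."""
    scores = model.decision_function(X)
    return model.classes_[np.argmax(scores, axis=1)], scores


def save_model(model: ELMClassifier, path: str | Path) -> None:
    """Serialize to ``<path>.json`` (metadata) + ``<path>.npz`` (weights)."""
    check_is_fitted(model, "output_weights_")
    path = Path(path)
    meta = {
        "n_hidden": model.n_hidden,
        "activation": model.activation,
        "alpha": model.alpha,
        "random_state": model.random_state,
        "classes": model.classes_.tolist(),
        "n_features_in": int(model.n_features_in_),
        "weights_file": path.with_suffix(".npz").name,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(
        path.with_suffix(".npz"),
        input_weights=model.input_weights_,
        biases=model.biases_,
        output_weights=model.output_weights_,
    )


def load_model(path: str | Path) -> ELMClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    model = ELMClassifier(
        n_hidden=meta["n_hidden"],
        activation=meta["activation"],
        alpha=meta["alpha"],
        random_state=meta["random_state"],
    )
    model.classes_ = np.asarray(meta["classes"])
    model.n_features_in_ = meta["n_features_in"]
    model.input_weights_ = arrays["input_weights"]
    model.biases_ = arrays["biases"]
    model.output_weights_ = arrays["output_weights"]
    return model
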
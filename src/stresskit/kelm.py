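"""Extreme learning machine (ELM) and its kernel variant (K-ELM).

An ELM is a single-hidden-layer feedforward network whose input weights
W and biases b are drawn at random and never trained; only the output
weights B are fit, in closed form, by ridge-regularized least squares:

    B = H' (I/C + H H')^{-1} T          (hidden-layer matrix H, N x L)

with T the one-hot target matrix and C the regularization coefficient.
The kernel ELM replaces the explicit hidden map by a Mercer kernel,
Omega_ij = k(x_i, x_j), giving the decision function

    f(x) = [k(x, x_1), ..., k(x, x_N)] (I/C + Omega)^{-1} T

so nothing random remains and the fit is a single symmetric
positive-definite solve. The RBF kernel k(x, x') = exp(-gamma ||x-x'||^2)
is the default. Multiclass decisions take the argmax of the score
vector, ties broken toward the lowest class index.
"""
from __future__ import annotations

import base64
import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import InvalidArgumentError, NumericalError


def rbf_kernel(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """K[i, j] = exp(-gamma * ||X_i - Y_j||^2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise InvalidArgumentError(
            f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if gamma < 0:
        raise InvalidArgumentError("gamma must be >= 0")
    sq = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Y ** 2, axis=1)[None, :]
          - 2.0 * X @ Y.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def linear_kernel(X: np.ndarray, Y: np.ndarray, gamma: float = 0.0):
    """K[i, j] = X_i . Y_j (gamma ignored; kept for a uniform signature)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise InvalidArgumentError("dimension mismatch")
    return X @ Y.T

KERNELS = {"rbf": rbf_kernel, "linear": linear_kernel}


def one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    T = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        T[r, idx[lab]] = 1.0
    return T


def standardize(train_X: np.ndarray, query_X: np.ndarray | None = None):
    """Z-score by the training columns' mean/SD; queries reuse train stats.

    Zero-variance columns are centred only (no division), so constant
    features pass through as zeros instead of raising.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 training rows to standardize")
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out_train = (train_X - mu) / sd_safe
    if query_X is None:
        return out_train, None
    return out_train, (np.asarray(query_X, dtype=float) - mu) / sd_safe


def _ridge_solve(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve M X = B for symmetric positive-definite M via Cholesky."""
    try:
        return cho_solve(cho_factor(M, lower=True), B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
        raise NumericalError(f"SPD solve failed: {exc}") from exc


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class ELMModel:
    """Random-feature ELM with closed-form ridge output weights."""

    W: np.ndarray            # L x D input weights
    b: np.ndarray            # L biases
    B_hat: np.ndarray        # L x M output weights
    C: float
    classes: np.ndarray
    seed: int
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """H[i, j] = sigmoid(w_j . x_i + b_j)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _sigmoid(X @ self.W.T + self.b)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mu is not None:
            X = (X - self.mu) / self.sd
        return self.hidden(X) @ self.B_hat

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def train_elm(X: np.ndarray, labels, L: int, C: float,
              seed: int = 0, standardize_features: bool = False) -> ELMModel:
    """Fit an ELM: seeded random hidden layer, ridge output weights.

    Input weights are uniform on [-1, 1], biases uniform on [0, 1],
    activation sigmoid. When ``L >= N`` the N-side ridge identity
    ``B = H'(I/C + HH')^{-1}T`` is used; otherwise the algebraically
    equivalent L-side form ``B = (I/C + H'H)^{-1}H'T`` (cheaper solve).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if C <= 0:
        raise InvalidArgumentError("C must be positive")
    if L < 1 or X.shape[0] < 1:
        raise InvalidArgumentError("need L >= 1 and N >= 1")
    mu = sd = None
    if standardize_features:
        Xs, _ = standardize(X)
        mu = X.mean(axis=0)
        sd_raw = X.std(axis=0, ddof=1)
        sd = np.where(sd_raw > 0, sd_raw, 1.0)
        X = Xs
    rng = np.random.default_rng(seed)
    n, d = X.shape
    W = rng.uniform(-1.0, 1.0, size=(L, d))
    b = rng.uniform(0.0, 1.0, size=L)
    H = _sigmoid(X @ W.T + b)
    classes = np.unique(labels)
    T = one_hot(labels, classes)
    if L >= n:
        M = np.eye(n) / C + H @ H.T
        B_hat = H.T @ _ridge_solve(M, T)
    else:
        M = np.eye(L) / C + H.T @ H
        B_hat = _ridge_solve(M, H.T @ T)
    return ELMModel(W, b, B_hat, C, classes, seed, mu, sd)


@dataclass
class KELMModel:
    """Kernel ELM: stored training inputs and dual solution alpha."""

    X_train: np.ndarray
    alpha: np.ndarray        # N x M
    kernel: str
    gamma: float
    C: float
    classes: np.ndarray
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise InvalidArgumentError(
                f"query dimension {X.shape[1]} != trained "
                f"{self.X_train.shape[1]}")
        if self.mu is not None:
            X = (X - self.mu) / self.sd
        K = KERNELS[self.kernel](X, self.X_train, self.gamma)
        return K @ self.alpha

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class per row; exact ties resolve to the lowest index."""
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def train_kelm(X: np.ndarray, labels, C: float, gamma: float,
               kernel: str = "rbf",
               standardize_features: bool = False) -> KELMModel:
    """Fit a kernel ELM by one SPD solve of (I/C + Omega) alpha = T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if C <= 0:
        raise InvalidArgumentError("C must be positive")
    if kernel not in KERNELS:
        raise InvalidArgumentError(f"unknown kernel {kernel!r}")
    if not np.all(np.isfinite(X)):
        raise NumericalError("non-finite entries in training inputs")
    mu = sd = None
    if standardize_features:
        mu = X.mean(axis=0)
        sd_raw = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        sd = np.where(sd_raw > 0, sd_raw, 1.0)
        X = (X - mu) / sd
    classes = np.unique(labels)
    T = one_hot(labels, classes)
    omega = KERNELS[kernel](X, X, gamma)
    alpha = _ridge_solve(np.eye(X.shape[0]) / C + omega, T)
    return KELMModel(X, alpha, kernel, gamma, C, classes, mu, sd)


# ---------------------------------------------------------------------------
# Serialization: JSON with base64-encoded little-endian float64 arrays.

def _enc(a: np.ndarray):
    a = np.ascontiguousarray(a, dtype="<f8")
    return {"shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode()}


def _dec(d) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]),
                         dtype="<f8").reshape(d["shape"]).copy()


def save_model(model: KELMModel, path) -> None:
    obj = {"format": "stresskit-kelm-v1", "kernel": model.kernel,
           "gamma": model.gamma, "C": model.C,
           "classes": [str(c) for c in model.classes],
           "X_train": _enc(model.X_train), "alpha": _enc(model.alpha)}
    if model.mu is not None:
        obj["mu"] = _enc(model.mu)
        obj["sd"] = _enc(model.sd)
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model(path) -> KELMModel:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format") != "stresskit-kelm-v1":
        raise InvalidArgumentError("not a stresskit K-ELM model file")
    return KELMModel(_dec(obj["X_train"]), _dec(obj["alpha"]), obj["kernel"],
                     obj["gamma"], obj["C"], np.asarray(obj["classes"]),
                     _dec(obj["mu"]) if "mu" in obj else None,
                     _dec(obj["sd"]) if "sd" in obj else None)
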
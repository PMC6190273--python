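"""Multilayer-perceptron baseline classifier.

A single-hidden-layer network (4 inputs, 36 log-sigmoid hidden units,
3 linear outputs) trained by Levenberg-Marquardt on one-hot targets, the
classic MATLAB-style configuration for small tabular problems.  It serves
as the comparison point for the ECOC-SVM: same features, same evaluation
protocol, different learner.

The LM damping loop is standard: solve (J'J + mu*I) step = -J'r on the
flattened residuals, accept a step only if the sum-of-squares error
decreases (dividing mu by 10), otherwise raise mu by 10 and retry.
Training stops when the gradient infinity-norm falls below ``grad_tol``,
mu exceeds ``mu_max``, or ``max_epochs`` is reached.  The accepted-error
sequence is therefore non-increasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["MLPNModel", "mlpn_forward", "mlpn_train", "mlpn_predict", "multi_start"]


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPNModel:
    """Weights of a 4-h-3 perceptron with log-sigmoid hidden units."""

    W1: np.ndarray  # (hidden, in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (out, hidden)
    b2: np.ndarray  # (out,)
    classes: tuple = (1, 2, 3)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def output_dim(self) -> int:
        return self.W2.shape[0]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return _logsig(X @ self.W1.T + self.b1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "W1": self.W1.tolist(),
                    "b1": self.b1.tolist(),
                    "W2": self.W2.tolist(),
                    "b2": self.b2.tolist(),
                    "classes": list(self.classes),
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "MLPNModel":
        d = json.loads(Path(path).read_text())
        return cls(
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            classes=tuple(d["classes"]),
        )


def _init_model(
    input_dim: int, hidden_dim: int, output_dim: int, rng: np.random.Generator
) -> MLPNModel:
    # Glorot-style uniform fan-in/fan-out initialization.
    def u(fan_in: int, fan_out: int, shape) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    return MLPNModel(
        W1=u(input_dim, hidden_dim, (hidden_dim, input_dim)),
        b1=np.zeros(hidden_dim),
        W2=u(hidden_dim, output_dim, (output_dim, hidden_dim)),
        b2=np.zeros(output_dim),
    )


def mlpn_forward(model: MLPNModel, X: np.ndarray) -> np.ndarray:
    """Linear output scores, one row of length ``output_dim`` per input row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"expected {model.input_dim} input columns, got {X.shape[1]}"
        )
    return model.hidden(X) @ model.W2.T + model.b2


def _pack(model: MLPNModel) -> np.ndarray:
    return np.concatenate(
        [model.W1.ravel(), model.b1, model.W2.ravel(), model.b2]
    )


def _unpack(theta: np.ndarray, shape: tuple[int, int, int], classes: tuple) -> MLPNModel:
    i, h, o = shape
    k = 0
    W1 = theta[k : k + h * i].reshape(h, i); k += h * i
    b1 = theta[k : k + h]; k += h
    W2 = theta[k : k + o * h].reshape(o, h); k += o * h
    b2 = theta[k : k + o]
    return MLPNModel(W1=W1, b1=b1, W2=W2, b2=b2, classes=classes)


def _residuals_and_jacobian(
    model: MLPNModel, X: np.ndarray, T: np.ndarray, with_jacobian: bool = True
) -> tuple[np.ndarray, np.ndarray | None]:
    """Flattened residuals (Y - T) and their Jacobian w.r.t. the packed
    parameters, ordered (W1, b1, W2, b2)."""
    m = X.shape[0]
    i_dim, h_dim, o_dim = model.input_dim, model.hidden_dim, model.output_dim
    H = model.hidden(X)  # (m, h)
    Y = H @ model.W2.T + model.b2
    r = (Y - T).ravel()  # row-major: sample-major, output-minor
    if not with_jacobian:
        return r, None
    dH = H * (1.0 - H)  # (m, h)
    p = h_dim * i_dim + h_dim + o_dim * h_dim + o_dim
    J = np.zeros((m * o_dim, p))
    for o in range(o_dim):
        rows = slice(o, m * o_dim, o_dim)  # residual rows of output o
        # dW1[j, k]: W2[o, j] * H'(j) * x_k
        g = dH * model.W2[o]  # (m, h)
        J[rows, : h_dim * i_dim] = (g[:, :, None] * X[:, None, :]).reshape(m, -1)
        J[rows, h_dim * i_dim : h_dim * i_dim + h_dim] = g
        off = h_dim * i_dim + h_dim
        J[rows, off + o * h_dim : off + (o + 1) * h_dim] = H
        J[rows, off + o_dim * h_dim + o] = 1.0
    return r, J


def mlpn_train(
    X: np.ndarray,
    labels: Sequence[int],
    seed: int = 0,
    max_epochs: int = 200,
    hidden_dim: int = 36,
    classes: tuple = (1, 2, 3),
    mu0: float = 1e-3,
    mu_max: float = 1e10,
    grad_tol: float = 1e-7,
    history: list | None = None,
) -> MLPNModel:
    """Train the perceptron by Levenberg-Marquardt on one-hot targets.

    Deterministic under a fixed seed; distinct seeds may reach different
    local optima (see :func:`multi_start`).  When a list is passed as
    ``history`` the sum-of-squares error after each accepted step is
    appended to it (non-increasing by construction).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    labels = np.asarray(labels, dtype=int)
    if not set(labels.tolist()) <= set(classes):
        raise ValueError(f"labels must be drawn from {classes}")
    if len(set(labels.tolist())) < len(classes):
        raise ValueError("all classes must be present in the training labels")
    T = np.zeros((len(labels), len(classes)))
    for row, lab in enumerate(labels):
        T[row, classes.index(lab)] = 1.0

    rng = np.random.default_rng(seed)
    model = _init_model(X.shape[1], hidden_dim, len(classes), rng)
    shape = (X.shape[1], hidden_dim, len(classes))
    theta = _pack(model)
    mu = mu0

    r, J = _residuals_and_jacobian(model, X, T)
    sse = float(r @ r)
    if history is not None:
        history.append(sse)
    for _ in range(max_epochs):
        g = J.T @ r
        if np.max(np.abs(g)) < grad_tol:
            break
        A = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                step = np.linalg.solve(A + mu * np.eye(len(theta)), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = _unpack(theta + step, shape, classes)
            r_new, _ = _residuals_and_jacobian(cand, X, T, with_jacobian=False)
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                theta = theta + step
                model = cand
                sse = sse_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                if history is not None:
                    history.append(sse)
                break
            mu *= 10.0
        if not accepted:
            break  # mu exhausted: local minimum within damping range
        r, J = _residuals_and_jacobian(model, X, T)
    return model


def mlpn_predict(model: MLPNModel, X: np.ndarray) -> np.ndarray:
    """Class per row: argmax of the linear outputs, ties to lowest index."""
    scores = mlpn_forward(model, X)
    return np.asarray([model.classes[i] for i in np.argmax(scores, axis=1)], dtype=int)


def multi_start(
    X: np.ndarray,
    labels: Sequence[int],
    n_starts: int = 5,
    seed: int = 0,
    **train_kwargs,
) -> MLPNModel:
    """Train from ``n_starts`` seeds and keep the lowest-error network."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    best_model, best_sse = None, np.inf
    for k in range(n_starts):
        model = mlpn_train(X, labels, seed=seed + k, **train_kwargs)
        classes = model.classes
        T = np.zeros((len(labels), len(classes)))
        for row, lab in enumerate(labels):
            T[row, classes.index(lab)] = 1.0
        r, _ = _residuals_and_jacobian(model, X, T, with_jacobian=False)
        sse = float(r @ r)
        if sse < best_sse:
            best_model, best_sse = model, sse
    return best_model
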
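"""Soft-margin kernel SVMs combined by error-correcting output codes.

Three binary SVMs are trained, one per column of a fixed 3x3 code matrix

    class 1 -> (1, 1, 1)
    class 2 -> (0, 1, 0)
    class 3 -> (0, 0, 1)

so learner k separates the classes whose bit k is 1 from the rest (the
one-versus-rest reading of the code).  A test pattern's three decision
signs form an output code that is decoded to the class with the smallest
Hamming distance; ties (possible for the output code (0, 0, 0)) fall back
to margin-weighted decoding and then to the lowest class index.  For
n = 3 classes the learner count 3 respects the 2**(n-1) - 1 bound on
useful columns.

Each binary learner solves the standard soft-margin dual

    max  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t. 0 <= a_i <= C,   sum_i a_i y_i = 0

by sequential minimal optimization (pairwise analytic updates with
Platt's working-set heuristics and an error cache).  The decision
function is f(x) = sgn(sum_i a_i y_i K(x_i, x) + b), with the bias
averaged over margin support vectors (0 < a_i < C).

Kernels: linear x.z, quadratic (x.z + gamma)**2 and Gaussian RBF
exp(-gamma * ||x - z||**2).  An alternative RBF form with ``x + z`` in
place of the difference (occasionally seen in print, almost certainly a
typo for the Gaussian) is selectable via ``KernelSpec.plus_form`` for
fidelity experiments only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "SVMModel",
    "CodeMatrix",
    "ECOCEnsemble",
    "kernel_eval",
    "kernel_matrix",
    "svm_train",
    "svm_decision",
    "ecoc_fit",
    "ecoc_predict",
    "ecoc_predict_batch",
    "hamming_decode",
    "grid_search",
]

KERNEL_FAMILIES = ("linear", "quadratic", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its single shape parameter.

    ``gamma`` is the additive offset of the quadratic kernel and the
    inverse-width of the RBF; ``gamma=None`` for RBF resolves to
    1/n_features at training time.  ``plus_form`` switches the RBF to
    exp(-gamma*||x + z||^2) (not positive definite; experiments only).
    """

    family: str = "quadratic"
    gamma: float | None = 1.0
    plus_form: bool = False

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf" and self.gamma is not None and self.gamma <= 0:
            raise ValueError("RBF kernel requires gamma > 0")
        if self.family == "quadratic" and self.gamma is None:
            raise ValueError("quadratic kernel requires a finite gamma offset")

    def resolve(self, n_features: int) -> "KernelSpec":
        if self.family == "rbf" and self.gamma is None:
            return KernelSpec("rbf", 1.0 / n_features, self.plus_form)
        return self


def kernel_eval(spec: KernelSpec, x: np.ndarray, z: np.ndarray) -> float:
    """Evaluate K(x, z) for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    return float(kernel_matrix(spec, x[None, :], z[None, :])[0, 0])


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    spec = spec.resolve(X.shape[1])
    if spec.family == "linear":
        return X @ Z.T
    if spec.family == "quadratic":
        return (X @ Z.T + spec.gamma) ** 2
    # rbf
    if spec.plus_form:
        sq = (
            np.sum(X * X, axis=1)[:, None]
            + np.sum(Z * Z, axis=1)[None, :]
            + 2.0 * (X @ Z.T)
        )
    else:
        sq = (
            np.sum(X * X, axis=1)[:, None]
            + np.sum(Z * Z, axis=1)[None, :]
            - 2.0 * (X @ Z.T)
        )
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


@dataclass
class SVMModel:
    """A trained binary soft-margin SVM in dual form.

    Only vectors with a_i > 0 (the support vectors) are retained;
    invariants 0 <= a_i <= C and |sum a_i y_i| < 1e-6 hold on return
    from :func:`svm_train`.
    """

    support_vectors: np.ndarray
    labels: np.ndarray  # +-1 per support vector
    alphas: np.ndarray
    bias: float
    kernel: KernelSpec
    C: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = kernel_matrix(self.kernel, X, self.support_vectors)
        return K @ (self.alphas * self.labels) + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "labels": self.labels.tolist(),
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "kernel": {
                "family": self.kernel.family,
                "gamma": self.kernel.gamma,
                "plus_form": self.kernel.plus_form,
            },
            "C": self.C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMModel":
        k = d["kernel"]
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            labels=np.asarray(d["labels"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            bias=float(d["bias"]),
            kernel=KernelSpec(k["family"], k["gamma"], k.get("plus_form", False)),
            C=float(d["C"]),
        )


def svm_decision(model: SVMModel, X: np.ndarray) -> np.ndarray:
    return model.decision_function(X)


def _smo(
    K: np.ndarray, y: np.ndarray, C: float, tol: float, max_passes: int
) -> tuple[np.ndarray, float]:
    """Platt-style SMO on a precomputed Gram matrix.

    Alternates full sweeps with sweeps over non-bound multipliers; the
    second multiplier is chosen to maximize |E_i - E_j|.  Returns the dual
    variables and a provisional bias.
    """
    n = len(y)
    alpha = np.zeros(n)
    b = 0.0
    eps = 1e-12

    def f(i: int) -> float:
        return float(np.dot(alpha * y, K[:, i]) + b)

    def take_step(i: int, j: int) -> bool:
        nonlocal b
        if i == j:
            return False
        ai_old, aj_old = alpha[i], alpha[j]
        Ei = f(i) - y[i]
        Ej = f(j) - y[j]
        s = y[i] * y[j]
        if s > 0:
            L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
        else:
            L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
        if H - L < eps:
            return False
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= eps:
            return False  # degenerate curvature; skip pair
        aj_new = aj_old + y[j] * (Ei - Ej) / eta
        aj_new = min(H, max(L, aj_new))
        if abs(aj_new - aj_old) < eps * (aj_new + aj_old + eps):
            return False
        ai_new = ai_old + s * (aj_old - aj_new)
        # Bias update keeping KKT on the updated pair.
        b1 = b - Ei - y[i] * (ai_new - ai_old) * K[i, i] - y[j] * (aj_new - aj_old) * K[i, j]
        b2 = b - Ej - y[i] * (ai_new - ai_old) * K[i, j] - y[j] * (aj_new - aj_old) * K[j, j]
        alpha[i], alpha[j] = ai_new, aj_new
        if 0.0 < ai_new < C:
            b = b1
        elif 0.0 < aj_new < C:
            b = b2
        else:
            b = 0.5 * (b1 + b2)
        return True

    def examine(j: int) -> int:
        Ej = f(j) - y[j]
        rj = Ej * y[j]
        if (rj < -tol and alpha[j] < C) or (rj > tol and alpha[j] > 0):
            errors = np.array([f(k) - y[k] for k in range(n)])
            order = np.argsort(-np.abs(errors - Ej))
            for i in order:
                if take_step(int(i), j):
                    return 1
        return 0

    passes = 0
    examine_all = True
    while passes < max_passes:
        changed = 0
        idx = range(n) if examine_all else np.where((alpha > 0) & (alpha < C))[0]
        for j in idx:
            changed += examine(int(j))
        passes += 1
        if examine_all:
            if changed == 0:
                break
            examine_all = False
        elif changed == 0:
            examine_all = True
    return alpha, b


def svm_train(
    X: np.ndarray,
    y: Sequence[int],
    spec: KernelSpec = KernelSpec(),
    C: float = 10.0,
    tol: float = 1e-3,
    max_passes: int = 200,
) -> SVMModel:
    """Train a binary soft-margin SVM by SMO.

    ``y`` must contain both +1 and -1.  The returned model satisfies the
    dual box constraints exactly and the KKT conditions within ``tol``;
    the bias is recomputed as the average over margin support vectors.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must contain both +1 and -1")
    if C <= 0:
        raise ValueError("C must be > 0")
    spec = spec.resolve(X.shape[1])
    K = kernel_matrix(spec, X, X)
    alpha, b = _smo(K, y, C, tol, max_passes)

    # Recompute the bias from margin support vectors (0 < a < C), averaged.
    g = K @ (alpha * y)  # decision values without bias
    on_margin = (alpha > 1e-8) & (alpha < C - 1e-8)
    if np.any(on_margin):
        b = float(np.mean(y[on_margin] - g[on_margin]))
    sv = alpha > 1e-8
    if not np.any(sv):
        raise RuntimeError("SMO returned no support vectors; data may be degenerate")
    return SVMModel(
        support_vectors=X[sv].copy(),
        labels=y[sv].copy(),
        alphas=alpha[sv].copy(),
        bias=float(b),
        kernel=spec,
        C=float(C),
    )


def kkt_violation(model: SVMModel, X: np.ndarray, y: np.ndarray) -> float:
    """Largest KKT violation of a trained model over the training set.

    For a_i = 0 require y_i f(x_i) >= 1, for a_i = C require <= 1, for
    margin vectors require = 1; returns the worst signed slack.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    yf = y * model.decision_function(X)
    # Map each training point to its multiplier (0 for non-SVs).
    alphas = np.zeros(len(y))
    for i, x in enumerate(X):
        d = np.sum((model.support_vectors - x) ** 2, axis=1)
        j = int(np.argmin(d))
        if d[j] < 1e-18:
            alphas[i] = model.alphas[j]
    worst = 0.0
    for a, m in zip(alphas, yf):
        if a < 1e-8:
            worst = max(worst, 1.0 - m)
        elif a > model.C - 1e-8:
            worst = max(worst, m - 1.0)
        else:
            worst = max(worst, abs(m - 1.0))
    return worst


# --- ECOC ----------------------------------------------------------------

DEFAULT_CODE_ROWS = ((1, 1, 1), (0, 1, 0), (0, 0, 1))


@dataclass(frozen=True)
class CodeMatrix:
    """Rows are per-class codewords; columns define the binary learners."""

    rows: tuple = DEFAULT_CODE_ROWS

    def __post_init__(self) -> None:
        arr = np.asarray(self.rows)
        if arr.ndim != 2 or not np.isin(arr, (0, 1)).all():
            raise ValueError("code matrix must be a 2-D 0/1 array")
        if len({tuple(r) for r in self.rows}) != len(self.rows):
            raise ValueError("codewords must be distinct")
        n = self.n_classes
        if n >= 2 and self.code_length > 2 ** (n - 1) - 1 and n > 2:
            raise ValueError(
                f"code length {self.code_length} exceeds the 2^(n-1)-1 bound"
            )

    @property
    def n_classes(self) -> int:
        return len(self.rows)

    @property
    def code_length(self) -> int:
        return len(self.rows[0])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rows, dtype=int)


def hamming_decode(bits: Sequence[int], code: CodeMatrix = CodeMatrix()) -> np.ndarray:
    """Per-class Hamming distances of an output code to the codewords."""
    bits = np.asarray(bits, dtype=int)
    if bits.shape != (code.code_length,):
        raise ValueError(f"output code must have length {code.code_length}")
    return np.sum(code.as_array() != bits[None, :], axis=1)


@dataclass
class ECOCEnsemble:
    """Code matrix plus one trained binary SVM per code column."""

    code: CodeMatrix
    models: list[SVMModel]
    classes: tuple = (1, 2, 3)

    def save(self, path: str | Path) -> None:
        payload = {
            "code_rows": [list(r) for r in self.code.rows],
            "classes": list(self.classes),
            "models": [m.to_dict() for m in self.models],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ECOCEnsemble":
        d = json.loads(Path(path).read_text())
        return cls(
            code=CodeMatrix(tuple(tuple(r) for r in d["code_rows"])),
            models=[SVMModel.from_dict(m) for m in d["models"]],
            classes=tuple(d["classes"]),
        )


def ecoc_fit(
    X: np.ndarray,
    labels: Sequence[int],
    spec: KernelSpec = KernelSpec(),
    C: float = 10.0,
    code: CodeMatrix = CodeMatrix(),
    classes: tuple = (1, 2, 3),
) -> ECOCEnsemble:
    """Train one binary SVM per code-matrix column.

    Learner k's positive set is the union of classes whose codeword bit k
    is 1 (for the default matrix: {1}, {1, 2} and {1, 3}).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    present = set(labels.tolist())
    if not set(classes) <= present:
        raise ValueError(f"all classes {classes} must be present, got {sorted(present)}")
    arr = code.as_array()
    class_index = {c: i for i, c in enumerate(classes)}
    models = []
    for k in range(code.code_length):
        bits = arr[:, k]
        y = np.array([1.0 if bits[class_index[c]] == 1 else -1.0 for c in labels])
        models.append(svm_train(X, y, spec=spec, C=C))
    return ECOCEnsemble(code=code, models=models, classes=tuple(classes))


def ecoc_predict(
    ensemble: ECOCEnsemble, x: np.ndarray
) -> tuple[int, np.ndarray, np.ndarray]:
    """Classify one pattern.

    Returns (class, output code bits, per-class Hamming distances).  The
    bit convention maps a non-negative margin to 1.  Hamming ties are
    broken by margin-weighted decoding (sum of |margin| over mismatched
    bits), then by the lowest class index.
    """
    x = np.asarray(x, dtype=float)
    margins = np.array([float(m.decision_function(x[None, :])[0]) for m in ensemble.models])
    bits = (margins >= 0.0).astype(int)
    dists = hamming_decode(bits, ensemble.code)
    best = np.flatnonzero(dists == dists.min())
    if len(best) > 1:
        arr = ensemble.code.as_array()
        costs = np.array(
            [np.sum(np.abs(margins) * (arr[i] != bits)) for i in best]
        )
        best = best[np.flatnonzero(costs == costs.min())]
    return int(ensemble.classes[int(best[0])]), bits, dists


def ecoc_predict_batch(ensemble: ECOCEnsemble, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([ecoc_predict(ensemble, x)[0] for x in X], dtype=int)


def grid_search(
    X: np.ndarray,
    labels: Sequence[int],
    family: str = "quadratic",
    Cs: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    gammas: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[KernelSpec, float, float]:
    """Small cross-validated grid search over C (and gamma).

    Returns (best KernelSpec, best C, best CV accuracy).  Linear kernels
    ignore the gamma grid.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(labels))
    folds = np.array_split(idx, n_folds)
    gamma_grid: Sequence[float | None] = gammas if family != "linear" else (None,)
    best = (KernelSpec("linear", None), Cs[0], -1.0)
    for g in gamma_grid:
        spec = KernelSpec(family, g if family != "linear" else None)
        for C in Cs:
            correct = total = 0
            for f in range(n_folds):
                test = folds[f]
                train = np.concatenate([folds[i] for i in range(n_folds) if i != f])
                if len(set(labels[train].tolist())) < 3:
                    continue
                ens = ecoc_fit(X[train], labels[train], spec=spec, C=C)
                pred = ecoc_predict_batch(ens, X[test])
                correct += int(np.sum(pred == labels[test]))
                total += len(test)
            acc = correct / total if total else 0.0
            if acc > best[2]:
                best = (spec, C, acc)
    return best
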
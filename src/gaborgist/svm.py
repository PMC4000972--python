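"""Soft-margin support vector machine solved through its Wolfe dual.

The binary classifier separates feature vectors x with labels y in {+1, -1}
by the hyperplane w.x + b = 0 that maximizes the geometric margin 2/||w||,
tolerating violations through slack variables penalized by the constant C:

    min_{w,b,xi}  ||w||^2 / 2 + C sum_i xi_i
    s.t.          y_i (w.x_i + b) >= 1 - xi_i,   xi_i >= 0.

The dual is the box-constrained quadratic program

    max_alpha  Q(alpha) = sum_i alpha_i
                          - 1/2 sum_{ij} alpha_i alpha_j y_i y_j K(x_i, x_j)
    s.t.       0 <= alpha_i <= C,   sum_i alpha_i y_i = 0,

with K a linear, polynomial or Gaussian RBF kernel.  It is solved here by
sequential minimal optimization (SMO): repeatedly pick the maximal-violating
pair of coefficients and solve their two-variable subproblem analytically,
until the KKT conditions hold to tolerance.  Examples with alpha_i > 0 are
the support vectors; the decision function is
f(x) = sum_sv alpha_i y_i K(x_i, x) + b and the predicted label sgn(f(x)),
with sgn(0) fixed to +1 for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "TrainingSet",
    "SVMModel",
    "kernel_eval",
    "kernel_matrix",
    "solve_dual",
    "decision_function",
    "predict",
    "select_C",
    "save_model",
    "load_model",
    "dual_objective",
    "primal_objective",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters: linear; polynomial (x.x' + c)^d; RBF."""

    family: str = "linear"
    c: float = 0.0       # polynomial offset
    d: int = 2           # polynomial degree
    sigma: float = 1.0   # RBF width

    def __post_init__(self) -> None:
        if self.family not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial" and (self.d < 1 or int(self.d) != self.d):
            raise ValueError(f"polynomial degree must be an integer >= 1, got {self.d}")
        if self.family == "rbf" and not (self.sigma > 0):
            raise ValueError(f"rbf sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class TrainingSet:
    """N feature vectors of dimension L with labels y in {+1, -1}^N."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"features must be 2-D (N, L), got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("labels must be a vector of length N")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training examples")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be +1 or -1")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class SVMModel:
    """Fitted classifier: support vectors, dual coefficients, bias, kernel."""

    support_vectors: np.ndarray
    alphas: np.ndarray          # alpha_i > 0 for the retained vectors
    labels: np.ndarray          # y_i of the support vectors
    bias: float
    kernel: KernelSpec
    C: float
    weights: Optional[np.ndarray] = None  # cached w for linear kernels

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]


def kernel_eval(spec: KernelSpec, xi: np.ndarray, xj: np.ndarray) -> float:
    """Evaluate K(xi, xj) for one pair of vectors."""
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    if spec.family == "linear":
        return float(xi @ xj)
    if spec.family == "polynomial":
        return float((xi @ xj + spec.c) ** spec.d)
    diff = xi - xj
    return float(np.exp(-(diff @ diff) / (2.0 * spec.sigma ** 2)))


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = K(A[i], B[j])."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    G = A @ B.T
    if spec.family == "linear":
        return G
    if spec.family == "polynomial":
        return (G + spec.c) ** spec.d
    sq = (A * A).sum(axis=1)[:, None] + (B * B).sum(axis=1)[None, :] - 2.0 * G
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * spec.sigma ** 2))


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int):
    """Maximal-violating-pair SMO on the dual; returns (alpha, rho).

    Minimizes 1/2 a^T Q a - e^T a with Q = y y^T * K subject to the box and
    equality constraints.  The pair selection follows the classic
    maximal-violating-pair rule, which is deterministic for fixed input.
    """
    n = y.size
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    grad = -np.ones(n)  # Q @ alpha - e at alpha = 0

    for _ in range(max_iter):
        yg = -y * grad
        up = (y > 0) & (alpha < C - 1e-12) | (y < 0) & (alpha > 1e-12)
        low = (y > 0) & (alpha > 1e-12) | (y < 0) & (alpha < C - 1e-12)
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(yg[low])])
        if yg[i] - yg[j] < tol:
            break

        # two-variable subproblem along the feasible direction
        quad = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        quad = max(quad, 1e-12)
        delta = (yg[i] - yg[j]) / quad
        # clip to the box for both coordinates
        if y[i] > 0:
            delta = min(delta, C - alpha[i])
        else:
            delta = min(delta, alpha[i])
        if y[j] > 0:
            delta = min(delta, alpha[j])
        else:
            delta = min(delta, C - alpha[j])
        if delta <= 0:
            break
        ai_new = alpha[i] + y[i] * delta
        aj_new = alpha[j] - y[j] * delta
        grad += Q[:, i] * (ai_new - alpha[i]) + Q[:, j] * (aj_new - alpha[j])
        alpha[i], alpha[j] = ai_new, aj_new

    # bias from the KKT conditions: rho = (max_up + min_low)/2 of y*grad
    yg = -y * grad
    up = (y > 0) & (alpha < C - 1e-12) | (y < 0) & (alpha > 1e-12)
    low = (y > 0) & (alpha > 1e-12) | (y < 0) & (alpha < C - 1e-12)
    free = (alpha > 1e-12) & (alpha < C - 1e-12)
    if free.any():
        rho = float(np.mean(yg[free]))
    elif up.any() and low.any():
        rho = float((yg[up].max() + yg[low].min()) / 2.0)
    else:
        rho = 0.0
    return alpha, rho


def solve_dual(
    train: TrainingSet,
    C: float = 1.0,
    spec: KernelSpec = KernelSpec(),
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> SVMModel:
    """Fit the soft-margin SVM by maximizing the kernelized Wolfe dual.

    The returned model retains only the support vectors (alpha_i > 0) and
    satisfies 0 <= alpha_i <= C and sum_i alpha_i y_i = 0 to solver
    tolerance.  The bias is the mean, over unbounded support vectors
    (0 < alpha < C), of y_i - sum_j alpha_j y_j K(x_j, x_i); when none exist
    the KKT-interval midpoint rule is used.
    """
    if not (C > 0):
        raise ValueError(f"C must be > 0, got {C}")
    y = train.labels
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    X = train.features
    K = kernel_matrix(spec, X, X)
    alpha, b = _smo(K, y, C, tol, max_iter)

    sv = alpha > 1e-10 * C
    weights = None
    if spec.family == "linear":
        weights = (alpha * y) @ X
    return SVMModel(
        support_vectors=X[sv].copy(),
        alphas=alpha[sv].copy(),
        labels=y[sv].copy(),
        bias=float(b),
        kernel=spec,
        C=float(C),
        weights=weights,
    )


def decision_function(model: SVMModel, x: np.ndarray) -> np.ndarray | float:
    """f(x) = sum_sv alpha_i y_i K(x_i, x) + b (equals w.x + b when linear)."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.support_vectors.shape[1]}"
        )
    K = kernel_matrix(model.kernel, X, model.support_vectors)
    f = K @ (model.alphas * model.labels) + model.bias
    return float(f[0]) if single else f


def predict(model: SVMModel, x: np.ndarray) -> np.ndarray | int:
    """F(x) = sgn(f(x)) with the tie rule sgn(0) = +1."""
    f = decision_function(model, x)
    if np.isscalar(f):
        return 1 if f >= 0 else -1
    return np.where(np.asarray(f) >= 0, 1, -1)


def save_model(model: SVMModel, path) -> None:
    """Serialize a model: ``<path>.json`` metadata + ``<path>.csv`` vectors.

    The JSON carries the kernel spec, C, bias and (for linear kernels) the
    cached weight vector; the CSV holds one support vector per row with its
    dual coefficient and label (columns ``alpha,y,x0..xL``).
    """
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    meta = {
        "kernel": {"family": model.kernel.family, "c": model.kernel.c,
                   "d": model.kernel.d, "sigma": model.kernel.sigma},
        "C": model.C,
        "bias": model.bias,
        "n_support": model.n_support,
        "weights": None if model.weights is None else list(model.weights),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    L = model.support_vectors.shape[1]
    table = pd.DataFrame(model.support_vectors,
                         columns=[f"x{i}" for i in range(L)])
    table.insert(0, "alpha", model.alphas)
    table.insert(1, "y", model.labels)
    table.to_csv(path.with_suffix(".csv"), index=False)


def load_model(path) -> SVMModel:
    """Load a model written by :func:`save_model`."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    table = pd.read_csv(path.with_suffix(".csv"))
    xcols = [c for c in table.columns if c.startswith("x")]
    weights = meta.get("weights")
    return SVMModel(
        support_vectors=table[xcols].to_numpy(dtype=float),
        alphas=table["alpha"].to_numpy(dtype=float),
        labels=table["y"].to_numpy(dtype=float),
        bias=float(meta["bias"]),
        kernel=KernelSpec(**meta["kernel"]),
        C=float(meta["C"]),
        weights=None if weights is None else np.asarray(weights, dtype=float),
    )


def dual_objective(train: TrainingSet, alpha: np.ndarray, spec: KernelSpec) -> float:
    """Q(alpha) = sum alpha_i - 1/2 sum alpha_i alpha_j y_i y_j K_ij."""
    K = kernel_matrix(spec, train.features, train.features)
    ay = alpha * train.labels
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def model_dual_objective(model: SVMModel, train: TrainingSet) -> float:
    """Q(alpha) of a fitted model, with alpha expanded to the full set."""
    alpha = np.zeros(train.n)
    # match support vectors back to training rows
    used = np.zeros(train.n, dtype=bool)
    for a, yv, xv in zip(model.alphas, model.labels, model.support_vectors):
        for i in range(train.n):
            if not used[i] and train.labels[i] == yv and np.array_equal(train.features[i], xv):
                alpha[i] = a
                used[i] = True
                break
    return dual_objective(train, alpha, model.kernel)


def primal_objective(model: SVMModel, train: TrainingSet) -> float:
    """||w||^2/2 + C sum_i max(0, 1 - y_i f(x_i)) for linear kernels."""
    if model.weights is None:
        raise ValueError("primal objective is computed for linear kernels only")
    f = decision_function(model, train.features)
    xi = np.maximum(0.0, 1.0 - train.labels * f)
    return float(0.5 * model.weights @ model.weights + model.C * xi.sum())


def select_C(
    train: TrainingSet,
    grid: Sequence[float] = DEFAULT_C_GRID,
    k: int = 5,
    spec: KernelSpec = KernelSpec(),
    seed: int = 0,
) -> float:
    """Choose C by stratified k-fold cross-validation on the training set.

    Returns the grid value with the highest mean fold accuracy; ties break
    toward the smaller C.  Folds are seeded and therefore deterministic.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("C grid must be non-empty")
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if len(grid) == 1:
        return float(grid[0])

    from sklearn.model_selection import StratifiedKFold

    y = train.labels
    n_min = int(min((y > 0).sum(), (y < 0).sum()))
    k_eff = min(k, n_min)
    if k_eff < 2:
        raise ValueError("too few examples of one class for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)

    best_C, best_acc = None, -1.0
    for C in sorted(grid):
        accs = []
        for tr_idx, te_idx in skf.split(train.features, y):
            if np.unique(y[tr_idx]).size < 2:
                continue
            sub = TrainingSet(train.features[tr_idx], y[tr_idx])
            model = solve_dual(sub, C=C, spec=spec)
            pred = predict(model, train.features[te_idx])
            accs.append(float(np.mean(pred == y[te_idx])))
        acc = float(np.mean(accs)) if accs else 0.0
        if acc > best_acc + 1e-12:  # strict improvement; ties keep smaller C
            best_acc, best_C = acc, float(C)
    return best_C
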
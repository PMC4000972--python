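"""Independent reference implementations used as test oracles.

These deliberately take the slow, obvious route (explicit loops, a generic
constrained optimizer) so they share no code path with the implementations
they check.
"""

import numpy as np

from gaborgist import KernelSpec, TrainingSet
from gaborgist.svm import kernel_matrix


def brute_force_correlate(data, taps, boundary="symmetric"):
    """Triple-loop same-size correlation (symmetric border extension)."""
    pads = tuple((k // 2, k // 2) for k in taps.shape)
    mode = "symmetric" if boundary == "symmetric" else "constant"
    padded = np.pad(data, pads, mode=mode)
    out = np.zeros_like(data, dtype=float)
    kh, kw, kt = taps.shape
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                out[i, j, k] = np.sum(
                    padded[i : i + kh, j : j + kw, k : k + kt] * taps
                )
    return out


def brute_force_pool(response, grid=(4, 4, 4)):
    """Per-block means via explicit edge arithmetic."""
    out = []
    d0, d1, d2 = response.shape
    g0, g1, g2 = grid
    for a in range(g0):
        for b in range(g1):
            for c in range(g2):
                block = response[
                    (a * d0) // g0 : ((a + 1) * d0) // g0,
                    (b * d1) // g1 : ((b + 1) * d1) // g1,
                    (c * d2) // g2 : ((c + 1) * d2) // g2,
                ]
                out.append(block.mean())
    return np.array(out)


def qp_oracle(train, C, spec):
    """Maximize the SVM Wolfe dual with SLSQP — independent of the SMO route."""
    from scipy.optimize import minimize

    X, y = train.features, train.labels
    n = y.size
    K = kernel_matrix(spec, X, X)
    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.x, -res.fun


def oracle_predictions(train, alpha, spec, X_test, C):
    """Labels implied by an oracle dual solution (bias from free vectors)."""
    y = train.labels
    K = kernel_matrix(spec, train.features, train.features)
    f_tr = K @ (alpha * y)
    free = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    if free.any():
        b = float(np.mean(y[free] - f_tr[free]))
    else:
        b = float(np.mean(y - f_tr))
    f = kernel_matrix(spec, X_test, train.features) @ (alpha * y) + b
    return np.where(f >= 0, 1, -1)


def random_instance(rng, spec):
    """A small random 2-D binary training set (n <= 12, both classes)."""
    n = int(rng.integers(4, 13))
    X = rng.normal(size=(n, 2))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if np.unique(y).size < 2:
        y[0] = -y[1]
    return TrainingSet(X, y)
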
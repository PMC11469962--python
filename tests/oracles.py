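"""Independent slow solvers used to cross-check the NNLS implementation."""

import itertools

import numpy as np


def projected_gradient_nnls(A, b, n_iter=40000, tol=1e-12):
    """Independent NNLS solver: projected gradient with a 1/L step size."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    x = np.zeros(A.shape[1])
    L = np.linalg.eigvalsh(A.T @ A).max()
    if L == 0:
        return x
    step = 1.0 / L
    AtA, Atb = A.T @ A, A.T @ b
    for _ in range(n_iter):
        g = AtA @ x - Atb
        x_new = np.clip(x - step * g, 0.0, None)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x


def active_set_bruteforce_nnls(A, b):
    """Enumerate all active sets; return the feasible optimum (small n only)."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    n = A.shape[1]
    best_x, best_obj = np.zeros(n), np.inf
    for k in range(n + 1):
        for subset in itertools.combinations(range(n), k):
            x = np.zeros(n)
            if subset:
                sub = A[:, list(subset)]
                coef, *_ = np.linalg.lstsq(sub, b, rcond=None)
                if (coef < -1e-10).any():
                    continue
                x[list(subset)] = np.clip(coef, 0, None)
            obj = np.sum((A @ x - b) ** 2)
            if obj < best_obj - 1e-12:
                best_obj, best_x = obj, x
    return best_x
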
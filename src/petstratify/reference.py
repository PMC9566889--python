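"""Dense quadratic-programming reference solver for the soft-margin SVM dual.

A deliberately simple, solver-independent implementation used to verify the
production training path: the dual

    max_α  Σα − ½ Σᵢⱼ αᵢαⱼ yᵢyⱼ k(xᵢ, xⱼ)
    s.t.   0 ≤ αᵢ ≤ Cᵢ,   Σ αᵢyᵢ = 0

is handed to SciPy's SLSQP with exact gradients, and the bias is read off
the KKT conditions: the mean of yᵢ − f(xᵢ) over free support vectors when
any exist, otherwise the midpoint of the feasible KKT interval (the standard
convention, which also pins down degenerate instances where the bias is only
determined up to an interval). Only suitable for small instances (tens of
points); it shares no code with the production solver.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .svm import SvmParams

__all__ = ["qp_reference_svm", "qp_reference_scores"]


def qp_reference_svm(X: np.ndarray, y: np.ndarray, params: SvmParams):
    """Solve the dual by dense QP; return (weights, bias).

    ``outlier_fraction`` is ignored (callers verifying the trimming path
    must apply it themselves); intended for ``outlier_fraction = 0``
    comparisons.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n = len(y)
    y_pm = (2 * y - 1).astype(np.float64)
    K = X @ X.T / params.kernel_scale**2 + params.kernel_offset
    Q = (y_pm[:, None] * y_pm[None, :]) * K
    Q = 0.5 * (Q + Q.T)
    cw = params.class_weights
    C = params.box_constraint * np.where(y == 0, cw[0], cw[1]).astype(np.float64)

    def objective(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    constraints = [{"type": "eq", "fun": lambda a: a @ y_pm, "jac": lambda a: y_pm}]
    bounds = [(0.0, float(c)) for c in C]
    res = minimize(objective, np.zeros(n), jac=grad, bounds=bounds,
                   constraints=constraints, method="SLSQP",
                   options={"maxiter": 5000, "ftol": 1e-16})
    if not res.success and res.status != 8:  # 8: positive directional derivative (flat)
        raise RuntimeError(f"reference QP failed: {res.message}")
    alpha = np.clip(res.x, 0.0, C)
    w = ((alpha * y_pm) @ X) / params.kernel_scale**2

    # bias from the KKT conditions on the kernel decision function
    f_nobias = (alpha * y_pm) @ K
    tol = 1e-6 * max(1.0, C.max())
    free = (alpha > tol) & (alpha < C - tol)
    if np.any(free):
        b = float(np.mean(y_pm[free] - f_nobias[free]))
    else:
        # no free SVs: b only constrained to an interval; take its midpoint.
        # y=+1, alpha<C: f(x)+b >= 1 -> b >= 1-f ;  y=+1, alpha>0: b <= 1-f
        # y=-1, alpha<C: f(x)+b <= -1 -> b <= -1-f;  y=-1, alpha>0: b >= -1-f
        lo, up = [], []
        for i in range(n):
            if y_pm[i] > 0:
                if alpha[i] < C[i] - tol:
                    lo.append(1.0 - f_nobias[i])
                if alpha[i] > tol:
                    up.append(1.0 - f_nobias[i])
            else:
                if alpha[i] < C[i] - tol:
                    up.append(-1.0 - f_nobias[i])
                if alpha[i] > tol:
                    lo.append(-1.0 - f_nobias[i])
        b = float((max(lo) + min(up)) / 2.0)
    return w, b


def qp_reference_scores(X_train, y_train, X_eval, params: SvmParams) -> np.ndarray:
    """Decision values of the reference solution on evaluation points."""
    w, b = qp_reference_svm(X_train, y_train, params)
    return np.asarray(X_eval, dtype=np.float64) @ w + b
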
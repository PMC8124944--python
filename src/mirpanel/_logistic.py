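"""Ridge-penalized logistic regression via Newton iterations.

Tuned for the panel-search inner loop: many fits on small (n x <=8)
standardized design matrices. The small ridge penalty keeps the Hessian
positive definite and the fit finite under complete separation.
"""

from __future__ import annotations

import numpy as np

DEFAULT_RIDGE = 1e-4


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 30,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Fit P(y=1|x) = sigmoid(b0 + x @ beta); returns (intercept, beta).

    The penalty applies to the slope coefficients only (features are
    expected to be standardized upstream).
    """
    n, p = X.shape
    Xb = np.empty((n, p + 1))
    Xb[:, 0] = 1.0
    Xb[:, 1:] = X
    y = np.asarray(y, dtype=float)
    beta = np.zeros(p + 1)
    beta[0] = _logit(min(max(y.mean(), 1e-6), 1.0 - 1e-6))
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    pen_diag = pen + 1e-12
    for _ in range(max_iter):
        eta = Xb @ beta
        np.clip(eta, -35.0, 35.0, out=eta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xb.T @ (y - mu) - pen * beta
        w = mu * (1.0 - mu)
        w += 1e-10
        H = (Xb * w[:, None]).T @ Xb
        H.flat[:: p + 2] += pen_diag
        step = np.linalg.solve(H, grad)
        # damp huge steps that arise under near-separation
        m = np.max(np.abs(step))
        if m > 10.0:
            step *= 10.0 / m
        beta += step
        if m < tol:
            break
    return float(beta[0]), beta[1:]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def predict_logit(intercept: float, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return intercept + X @ beta


def predict_proba(intercept: float, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.clip(predict_logit(intercept, beta, X), -35.0, 35.0)
    return 1.0 / (1.0 + np.exp(-eta))
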
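"""Minimal pooled-regression solvers used by the sequential covariate models.

Logistic fits use Newton/IRLS with a tiny ridge penalty on the non-intercept
terms and step-halving.  The ridge keeps the solver well defined under the
quasi-separation that is structural in this data: absorbing components reach
near-complete coverage, so late-wave at-risk sets can have all-0 or all-1
responses, where the unpenalised MLE diverges.  The penalty is small enough
(1e-4) that coefficients on well-identified terms agree with the exact MLE to
~1e-4 while separated terms settle at large finite values whose fitted
probabilities are numerically 0 or 1 -- the correct simulation behaviour.
"""

from __future__ import annotations

import numpy as np

RIDGE = 1e-4


class NonConvergenceError(RuntimeError):
    pass


def fit_linear(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and residual SD (ddof = n - rank, SD 0 if saturated)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - rank
    sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return coef, sd


def _loglik(X, y, beta, pen):
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (pen * beta * beta).sum())


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = RIDGE,
                 max_iter: int = 60, tol: float = 1e-9) -> np.ndarray:
    """Ridge-stabilised Newton fit of a pooled logistic model.

    Assumes column 0 of ``X`` is the intercept (unpenalised).  Raises
    :class:`NonConvergenceError` if the gradient has not vanished after
    ``max_iter`` Newton steps.
    """
    n, k = X.shape
    pen = np.full(k, ridge)
    pen[0] = 0.0
    beta = np.zeros(k)
    pbar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    beta[0] = np.log(pbar / (1.0 - pbar))
    ll = _loglik(X, y, beta, pen)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35.0, 35.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p) - pen * beta
        if np.max(np.abs(grad)) < tol * max(n, 1):
            return beta
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen + 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search on the penalised log-likelihood
        for _ in range(30):
            cand = beta + step
            ll_new = _loglik(X, y, cand, pen)
            if ll_new >= ll - 1e-12:
                break
            step = 0.5 * step
        beta, ll = cand, ll_new
    eta = np.clip(X @ beta, -35.0, 35.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    if np.max(np.abs(X.T @ (y - p) - pen * beta)) < 1e-4 * max(n, 1):
        return beta  # close enough: flat penalised likelihood
    raise NonConvergenceError("logistic fit did not converge")


def predict_logistic(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = np.clip(X @ beta, -35.0, 35.0)
    return 1.0 / (1.0 + np.exp(-eta))
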
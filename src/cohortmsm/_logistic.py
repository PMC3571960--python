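"""Weighted logistic maximum likelihood by Newton-Raphson IRLS.

Shared solver for the treatment, censoring and outcome models: convergence
on the log-likelihood (absolute change < 1e-8), iteration cap 100, with
step-halving.  ``y`` may be a Bernoulli indicator or a binomial proportion
with ``weights`` carrying the trial counts (or arbitrary positive case
weights; the score equations are the weighted ones either way).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFitResult", "irls_logistic", "ConvergenceError", "SeparationError"]

MAX_ITER = 100
TOL = 1e-8
_BETA_LIMIT = 30.0  # |coefficient| beyond this signals (quasi-)separation


class ConvergenceError(RuntimeError):
    pass


class SeparationError(ConvergenceError):
    pass


@dataclass
class LogisticFitResult:
    params: np.ndarray
    cov: np.ndarray  # inverse observed information (model-based)
    loglik: float
    n_iter: int
    converged: bool


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # w * (y*eta - log(1 + e^eta)), numerically stable
    return float(w @ (y * eta - np.logaddexp(0.0, eta)))


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogisticFitResult:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    beta = np.zeros(p)
    # intercept warm start assuming column 0 is constant
    ybar = float(np.clip((w * y).sum() / w.sum(), 1e-10, 1 - 1e-10))
    if np.allclose(X[:, 0], 1.0):
        beta[0] = np.log(ybar / (1.0 - ybar))

    eta = X @ beta
    ll = _loglik(eta, y, w)
    converged = False
    H = None
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        wv = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        H = X.T @ (X * wv[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it} "
                "(collinear covariates or separation)"
            ) from exc
        # step-halving on likelihood decrease
        for _ in range(30):
            beta_new = beta + step
            eta_new = X @ beta_new
            ll_new = _loglik(eta_new, y, w)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta = beta_new, eta_new
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    if np.abs(beta).max() > _BETA_LIMIT:
        raise SeparationError(
            "diverging coefficients (max |beta| > "
            f"{_BETA_LIMIT:g}) — likely complete separation"
        )
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (loglik {ll:.6g})"
        )
    mu = expit(eta)
    wv = w * mu * (1.0 - mu)
    H = X.T @ (X * wv[:, None])
    cov = np.linalg.inv(H)
    return LogisticFitResult(beta, cov, ll, it, converged)
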
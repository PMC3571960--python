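"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths: the Poisson interval
is obtained by numerical CDF inversion, and the clustered covariance is
assembled from per-cluster scores computed by numerical differentiation of
cluster log-likelihoods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson


def exact_poisson_ci_by_cdf_inversion(k: int, alpha: float = 0.05):
    if k == 0:
        lo = 0.0
    else:
        lo = brentq(lambda lam: poisson.sf(k - 1, lam) - alpha / 2, 1e-10, 10 * k + 50)
    hi = brentq(lambda lam: poisson.cdf(k, lam) - alpha / 2, 1e-10, 10 * k + 100)
    return lo, hi


def numerical_cluster_covariance(X, y, w, cluster_ids, params):
    """Brute-force A^-1 B A^-1 (with G/(G-1)) from numerically differentiated
    per-cluster weighted logistic log-likelihoods."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)

    def cluster_loglik(beta, mask):
        eta = X[mask] @ beta
        return float(w[mask] @ (y[mask] * eta - np.logaddexp(0.0, eta)))

    def num_grad(f, beta, eps=1e-6):
        g = np.zeros(len(beta))
        for j in range(len(beta)):
            e = np.zeros(len(beta)); e[j] = eps
            g[j] = (f(beta + e) - f(beta - e)) / (2 * eps)
        return g

    groups = pd.unique(cluster_ids)
    G = len(groups)
    scores = np.array([
        num_grad(lambda b, m=(cluster_ids == g): cluster_loglik(b, m), params)
        for g in groups
    ])
    B = scores.T @ scores
    # information = -Hessian by second-order central differences
    p = len(params)
    A = np.zeros((p, p))
    eps = 1e-4
    full = np.ones(len(y), dtype=bool)
    f = lambda b: cluster_loglik(b, full)
    for j in range(p):
        for k in range(j, p):
            ej = np.zeros(p); ej[j] = eps
            ek = np.zeros(p); ek[k] = eps
            h = (
                f(params + ej + ek) - f(params + ej - ek)
                - f(params - ej + ek) + f(params - ej - ek)
            ) / (4 * eps * eps)
            A[j, k] = A[k, j] = -h
    return np.linalg.inv(A) @ B @ np.linalg.inv(A) * G / (G - 1)
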
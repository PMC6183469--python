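"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: a vectorized Newton
IRLS for the intercept-only logit GLM, adaptive Gauss-Hermite quadrature for
single-random-factor marginal likelihoods, a dense-matrix Laplace evaluation
for the crossed model, and plain numpy quadrature for logit-normal means.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, roots_hermite


def irls_intercept_sweep(k: np.ndarray, n: np.ndarray, n_iter: int = 60):
    """Newton/IRLS fit of eta in Bernoulli(expit(eta)) for many (k, n) at once.

    Returns (eta_hat, se_eta). Requires 0 < k < n.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.zeros_like(k)
    for _ in range(n_iter):
        mu = expit(eta)
        score = k - n * mu
        info = n * mu * (1.0 - mu)
        eta = eta + score / info
    mu = expit(eta)
    se = 1.0 / np.sqrt(n * mu * (1.0 - mu))
    return eta, se


def aghq_loglik_single_factor(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    var: float,
    n_nodes: int = 21,
) -> float:
    """Adaptive GH marginal loglik for one random intercept factor.

    Groups are independent, so the marginal likelihood factorizes into
    one-dimensional integrals, each centered and scaled at its own mode.
    """
    nodes, weights = roots_hermite(n_nodes)
    total = 0.0
    for g in np.unique(groups):
        idx = groups == g
        yg = y[idx]
        eta0 = X[idx] @ beta
        u = 0.0
        for _ in range(200):
            mu = expit(eta0 + u)
            grad = np.sum(yg - mu) - u / var
            hess = -np.sum(mu * (1.0 - mu)) - 1.0 / var
            step = -grad / hess
            u += step
            if abs(step) < 1e-13:
                break
        mu = expit(eta0 + u)
        tau = 1.0 / np.sqrt(np.sum(mu * (1.0 - mu)) + 1.0 / var)
        z = u + np.sqrt(2.0) * tau * nodes
        ll_z = np.array(
            [np.sum(yg * (eta0 + zz) - np.logaddexp(0.0, eta0 + zz)) for zz in z]
        )
        log_prior = -0.5 * z**2 / var - 0.5 * np.log(2.0 * np.pi * var)
        vals = weights * np.exp(ll_z + log_prior + nodes**2) * np.sqrt(2.0) * tau
        total += np.log(np.sum(vals))
    return float(total)


def dense_laplace_loglik(
    y: np.ndarray,
    X: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    beta: np.ndarray,
    v1: float,
    v2: float,
) -> float:
    """Naive dense-matrix Laplace log-likelihood for the crossed model.

    Builds the full random-effect design Z, finds the penalized mode with a
    dense Newton iteration, and evaluates the Laplace formula with a dense
    log-determinant. Mirrors none of the package's sparse/Schur machinery.
    """
    q1 = int(g1.max()) + 1
    q2 = int(g2.max()) + 1
    n = len(y)
    Z = np.zeros((n, q1 + q2))
    Z[np.arange(n), g1] = 1.0
    Z[np.arange(n), q1 + g2] = 1.0
    d_inv = np.concatenate([np.full(q1, 1.0 / v1), np.full(q2, 1.0 / v2)])
    u = np.zeros(q1 + q2)
    eta0 = X @ beta
    for _ in range(200):
        eta = eta0 + Z @ u
        mu = expit(eta)
        grad = Z.T @ (y - mu) - d_inv * u
        H = (Z * (mu * (1 - mu))[:, None]).T @ Z + np.diag(d_inv)
        step = np.linalg.solve(H, grad)
        u = u + step
        if np.max(np.abs(step)) < 1e-13:
            break
    eta = eta0 + Z @ u
    mu = expit(eta)
    H = (Z * (mu * (1 - mu))[:, None]).T @ Z + np.diag(d_inv)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll -= 0.5 * float(u @ (d_inv * u))
    ll -= 0.5 * (q1 * np.log(v1) + q2 * np.log(v2))
    ll -= 0.5 * float(np.linalg.slogdet(H)[1])
    return ll


def logit_normal_mean(eta: float, var: float, n_nodes: int = 201) -> float:
    """E[expit(eta + Z)], Z ~ N(0, var), by dense trapezoid quadrature."""
    if var == 0:
        return float(expit(eta))
    sd = np.sqrt(var)
    z = np.linspace(-9 * sd, 9 * sd, n_nodes)
    dens = np.exp(-0.5 * (z / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return float(np.trapezoid(expit(eta + z) * dens, z))
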
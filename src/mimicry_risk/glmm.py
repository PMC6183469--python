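"""Laplace-approximate ML fitting of logit models with crossed random intercepts.

Model
-----
``y_k ~ Bernoulli(invlogit(x_k' beta + a[g1_k] + b[g2_k]))`` with
``a_j ~ N(0, v1)`` i.i.d. and ``b_i ~ N(0, v2)`` i.i.d., the two grouping
factors fully crossed.

The marginal likelihood integrates over ``u = (a, b)``. We approximate it by
Laplace expansion around the joint penalized mode ``u*``::

    loglik(beta, v1, v2) =  sum_k [ y_k eta_k - log(1 + exp(eta_k)) ]
                          - u*' D^{-1} u* / 2  - log|D| / 2 - log|H| / 2

where ``D = blockdiag(v1 I_q1, v2 I_q2)`` and ``H = Z' W Z + D^{-1}`` is the
negative Hessian of the penalized log-likelihood at the mode (the ``2*pi``
factors of the Gaussian integral and of the random-effect density cancel).

The inner mode search is penalized Newton/IRLS. The outer problem maximizes
the Laplace log-likelihood over ``(beta, log sigma1, log sigma2)`` with
L-BFGS-B (ML, not REML). Factor 1 is assumed small (pictures); solves use a
Schur complement on its block, so the cost is linear in the size of factor 2
(respondents).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

LOG_SIGMA_MIN = math.log(1e-5)  # variance floor 1e-10
LOG_SIGMA_MAX = math.log(30.0)
INNER_TOL = 1e-8
OUTER_GTOL = 1e-6
MAX_OUTER_ITER = 200
SEPARATION_LOGIT = 15.0


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def fit_logistic_irls(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """Plain Bernoulli logit GLM by Newton/IRLS.

    Returns ``(beta, vcov, loglik)``. Used for starting values and as the
    exact zero-variance limit of the mixed model.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    vcov = np.linalg.inv(info)
    ll = float(np.sum(y * eta - _log1pexp(eta)))
    return beta, vcov, ll


@dataclass
class LaplaceFitResult:
    beta: np.ndarray
    vcov_beta: np.ndarray
    var1: float
    var2: float
    loglik: float
    converged: bool
    n_obs: int
    boundary_flags: list[str] = field(default_factory=list)
    u1: np.ndarray | None = None
    u2: np.ndarray | None = None
    n_outer_evals: int = 0


class CrossedLogitLaplace:
    """Laplace machinery bound to one design.

    Parameters
    ----------
    y : (n,) 0/1 response
    X : (n, p) fixed-effect design
    g1 : (n,) int codes of the small factor (or None to omit it)
    g2 : (n,) int codes of the large factor (or None)
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        g1: np.ndarray | None,
        g2: np.ndarray | None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.g1 = None if g1 is None else np.asarray(g1, dtype=np.intp)
        self.g2 = None if g2 is None else np.asarray(g2, dtype=np.intp)
        self.q1 = 0 if self.g1 is None else int(self.g1.max()) + 1
        self.q2 = 0 if self.g2 is None else int(self.g2.max()) + 1
        self._u1 = np.zeros(self.q1)
        self._u2 = np.zeros(self.q2)

    # -- inner problem ----------------------------------------------------

    def _eta(self, beta, u1, u2):
        eta = self.X @ beta
        if self.g1 is not None:
            eta = eta + u1[self.g1]
        if self.g2 is not None:
            eta = eta + u2[self.g2]
        return eta

    def _penalized_ll(self, beta, u1, u2, v1, v2):
        eta = self._eta(beta, u1, u2)
        ll = float(np.sum(self.y * eta - _log1pexp(eta)))
        if self.q1:
            ll -= 0.5 * float(u1 @ u1) / v1
        if self.q2:
            ll -= 0.5 * float(u2 @ u2) / v2
        return ll

    def _mode(self, beta, v1, v2, max_iter=200):
        """Penalized Newton over u; returns (u1, u2, logdetH, converged)."""
        y, g1, g2 = self.y, self.g1, self.g2
        u1, u2 = self._u1.copy(), self._u2.copy()
        f_cur = self._penalized_ll(beta, u1, u2, v1, v2)
        converged = False
        logdet_h = 0.0
        for _ in range(max_iter):
            eta = self._eta(beta, u1, u2)
            mu = expit(eta)
            w = mu * (1.0 - mu)
            resid = y - mu

            if self.q1 and self.q2:
                r1 = np.bincount(g1, resid, minlength=self.q1) - u1 / v1
                r2 = np.bincount(g2, resid, minlength=self.q2) - u2 / v2
                da = np.bincount(g1, w, minlength=self.q1) + 1.0 / v1
                db = np.bincount(g2, w, minlength=self.q2) + 1.0 / v2
                C = np.zeros((self.q1, self.q2))
                np.add.at(C, (g1, g2), w)
                CdB = C / db[None, :]
                S = np.diag(da) - CdB @ C.T
                d1 = np.linalg.solve(S, r1 - CdB @ r2)
                d2 = (r2 - C.T @ d1) / db
                grad_norm = max(np.max(np.abs(r1)), np.max(np.abs(r2)))
                logdet_h = float(np.sum(np.log(db)) + np.linalg.slogdet(S)[1])
            elif self.q1:
                r1 = np.bincount(g1, resid, minlength=self.q1) - u1 / v1
                da = np.bincount(g1, w, minlength=self.q1) + 1.0 / v1
                d1, d2 = r1 / da, None
                grad_norm = np.max(np.abs(r1))
                logdet_h = float(np.sum(np.log(da)))
            elif self.q2:
                r2 = np.bincount(g2, resid, minlength=self.q2) - u2 / v2
                db = np.bincount(g2, w, minlength=self.q2) + 1.0 / v2
                d1, d2 = None, r2 / db
                grad_norm = np.max(np.abs(r2))
                logdet_h = float(np.sum(np.log(db)))
            else:
                return u1, u2, 0.0, True

            if grad_norm < INNER_TOL:
                converged = True
                break

            step = 1.0
            for _ in range(30):
                n1 = u1 + step * d1 if d1 is not None else u1
                n2 = u2 + step * d2 if d2 is not None else u2
                f_new = self._penalized_ll(beta, n1, n2, v1, v2)
                if f_new >= f_cur:
                    break
                step *= 0.5
            if f_new >= f_cur:
                progress = f_new - f_cur
                u1, u2, f_cur = n1, n2, f_new
                if progress < 1e-13:  # floating-point plateau at the mode
                    converged = grad_norm < 1e-5
                    break
            else:  # no uphill step found: already at the mode numerically
                converged = grad_norm < 1e-5
                break
        self._u1, self._u2 = u1, u2  # warm start for the next evaluation
        return u1, u2, logdet_h, converged

    # -- marginal log-likelihood ------------------------------------------

    def loglik(self, beta, v1, v2) -> tuple[float, bool]:
        """Laplace-approximate marginal log-likelihood at given parameters."""
        u1, u2, logdet_h, inner_ok = self._mode(beta, v1, v2)
        eta = self._eta(beta, u1, u2)
        ll = float(np.sum(self.y * eta - _log1pexp(eta)))
        if self.q1:
            ll -= 0.5 * float(u1 @ u1) / v1 + 0.5 * self.q1 * math.log(v1)
        if self.q2:
            ll -= 0.5 * float(u2 @ u2) / v2 + 0.5 * self.q2 * math.log(v2)
        ll -= 0.5 * logdet_h
        return ll, inner_ok

    # -- outer problem ----------------------------------------------------

    def fit(
        self,
        var1_fixed: float | None = None,
        var2_fixed: float | None = None,
        beta_start: np.ndarray | None = None,
        var_start: float = 0.5,
    ) -> LaplaceFitResult:
        """Maximize the Laplace log-likelihood over (beta, log sigmas).

        ``var*_fixed`` pins a variance component (0 removes the factor and,
        with both pinned at 0, reduces exactly to the plain logistic GLM).
        """
        if beta_start is None:
            beta_start, _, _ = fit_logistic_irls(self.y, self.X)

        est1 = self.q1 > 0 and var1_fixed is None
        est2 = self.q2 > 0 and var2_fixed is None
        v1_fix = 0.0 if self.q1 == 0 else var1_fixed
        v2_fix = 0.0 if self.q2 == 0 else var2_fixed

        if v1_fix == 0.0:
            self.g1, self.q1, self._u1 = None, 0, np.zeros(0)
            est1 = False
        if v2_fix == 0.0:
            self.g2, self.q2, self._u2 = None, 0, np.zeros(0)
            est2 = False

        if not self.q1 and not self.q2:
            beta, vcov, ll = fit_logistic_irls(self.y, self.X)
            flags = _separation_flags(beta)
            return LaplaceFitResult(
                beta=beta, vcov_beta=vcov, var1=0.0, var2=0.0, loglik=ll,
                converged=True, n_obs=self.n, boundary_flags=flags,
                u1=np.zeros(0), u2=np.zeros(0),
            )

        s_start = 0.5 * math.log(var_start)
        x0 = list(beta_start)
        bounds: list[tuple[float | None, float | None]] = [(None, None)] * self.p
        if est1:
            x0.append(s_start)
            bounds.append((LOG_SIGMA_MIN, LOG_SIGMA_MAX))
        if est2:
            x0.append(s_start)
            bounds.append((LOG_SIGMA_MIN, LOG_SIGMA_MAX))
        x0 = np.array(x0)

        inner_ok_last = {"ok": True}
        n_evals = {"n": 0}

        def unpack(x):
            beta = x[: self.p]
            i = self.p
            if est1:
                v1 = math.exp(2.0 * x[i]); i += 1
            else:
                v1 = v1_fix if self.q1 else 0.0
            if est2:
                v2 = math.exp(2.0 * x[i]); i += 1
            else:
                v2 = v2_fix if self.q2 else 0.0
            return beta, v1, v2

        def objective(x):
            beta, v1, v2 = unpack(x)
            ll, ok = self.loglik(beta, v1, v2)
            inner_ok_last["ok"] = ok
            n_evals["n"] += 1
            return -ll

        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": MAX_OUTER_ITER,
                "ftol": 1e-12,
                "gtol": OUTER_GTOL,
                "eps": 1e-6,
            },
        )
        beta, v1, v2 = unpack(res.x)
        # polish the mode at the optimum (mode cache may lag the last step)
        ll, inner_ok = self.loglik(beta, v1, v2)

        flags = _separation_flags(beta)
        if est1 and res.x[self.p] <= LOG_SIGMA_MIN + 1e-8:
            flags.append("var_picture_at_zero_boundary")
        if est2 and res.x[-1] <= LOG_SIGMA_MIN + 1e-8:
            flags.append("var_respondent_at_zero_boundary")

        vcov = self._vcov_beta(beta, v1, v2)
        return LaplaceFitResult(
            beta=beta,
            vcov_beta=vcov,
            var1=float(v1),
            var2=float(v2),
            loglik=float(ll),
            converged=bool(res.success and inner_ok),
            n_obs=self.n,
            boundary_flags=flags,
            u1=self._u1.copy(),
            u2=self._u2.copy(),
            n_outer_evals=n_evals["n"],
        )

    def _vcov_beta(self, beta, v1, v2) -> np.ndarray:
        """Fixed-effect covariance conditional on the variance components.

        ``(X'WX - X'WZ H^{-1} Z'WX)^{-1}`` at the joint mode — the standard
        GLMM Wald covariance for beta.
        """
        u1, u2, _, _ = self._mode(beta, v1, v2)
        eta = self._eta(beta, u1, u2)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        X = self.X
        xtwx = (X * w[:, None]).T @ X
        if not self.q1 and not self.q2:
            return np.linalg.inv(xtwx)

        # M = X'WZ, applied through the block solve of H
        M1 = np.zeros((self.p, self.q1))
        M2 = np.zeros((self.p, self.q2))
        for j in range(self.p):
            wx = w * X[:, j]
            if self.q1:
                M1[j] = np.bincount(self.g1, wx, minlength=self.q1)
            if self.q2:
                M2[j] = np.bincount(self.g2, wx, minlength=self.q2)

        if self.q1 and self.q2:
            da = np.bincount(self.g1, w, minlength=self.q1) + 1.0 / v1
            db = np.bincount(self.g2, w, minlength=self.q2) + 1.0 / v2
            C = np.zeros((self.q1, self.q2))
            np.add.at(C, (self.g1, self.g2), w)
            CdB = C / db[None, :]
            S = np.diag(da) - CdB @ C.T
            # solve H [t1; t2] = [M1'; M2'] column-block-wise
            rhs1 = M1.T - CdB @ M2.T            # (q1, p)
            t1 = np.linalg.solve(S, rhs1)       # (q1, p)
            t2 = (M2.T - C.T @ t1) / db[:, None]
            correction = M1 @ t1 + M2 @ t2
        elif self.q1:
            da = np.bincount(self.g1, w, minlength=self.q1) + 1.0 / v1
            correction = (M1 / da[None, :]) @ M1.T
        else:
            db = np.bincount(self.g2, w, minlength=self.q2) + 1.0 / v2
            correction = (M2 / db[None, :]) @ M2.T
        return np.linalg.inv(xtwx - correction)


def _separation_flags(beta: np.ndarray) -> list[str]:
    if np.any(np.abs(beta) > SEPARATION_LOGIT):
        return ["possible_complete_separation"]
    return []
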
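"""Minimal binomial-logistic GLM fitted by IRLS.

Kept in-house (rather than delegating to a general GLM package) so that the
response-type classifier and the GLMM boundary refit can be validated against
an independent general-purpose implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, xlogy


@dataclass
class GLMResult:
    coefficients: np.ndarray
    vcov: np.ndarray
    deviance: float
    log_likelihood: float
    converged: bool
    n_iter: int

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def binomial_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial log likelihood including the combinatorial constant."""
    from scipy.special import gammaln

    p = np.clip(p, 1e-12, 1 - 1e-12)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + xlogy(k, p) + xlogy(n - k, 1 - p)))


def _deviance(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = xlogy(k, k / n) + xlogy(n - k, 1 - k / n)
    mod = xlogy(k, p) + xlogy(n - k, 1 - p)
    return float(2.0 * np.sum(sat - mod))


def fit_binomial_glm(
    x: np.ndarray,
    killed: np.ndarray,
    offered: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GLMResult:
    """Logit-link binomial regression of killed-out-of-offered on X via IRLS.

    Iterates reweighted least squares until the deviance changes by less
    than ``tol``.  Non-convergence (including quasi-separation driving
    weights to zero) is reported through the ``converged`` flag rather than
    an exception.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(killed, dtype=float)
    n = np.asarray(offered, dtype=float)
    n_obs, n_par = x.shape

    # start at the empirical-logit intercept, other coefficients 0
    p_bar = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta = np.zeros(n_par)
    beta[0] = np.log(p_bar / (1 - p_bar))

    dev = np.inf
    converged = False
    it = 0
    xtwx = np.eye(n_par)
    for it in range(1, max_iter + 1):
        eta = x @ beta
        p = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = n * p * (1 - p)
        z = eta + (k - n * p) / w
        xtwx = x.T @ (w[:, None] * x)
        try:
            beta_new = np.linalg.solve(xtwx, x.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        dev_new = _deviance(k, n, np.clip(expit(x @ beta_new), 1e-10, 1 - 1e-10))
        beta = beta_new
        if np.isfinite(dev_new) and abs(dev - dev_new) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
        converged = False

    p = np.clip(expit(x @ beta), 1e-12, 1 - 1e-12)
    try:
        vcov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        vcov = np.full((n_par, n_par), np.nan)
    return GLMResult(
        coefficients=beta,
        vcov=vcov,
        deviance=dev if np.isfinite(dev) else _deviance(k, n, p),
        log_likelihood=binomial_loglik(k, n, p),
        converged=converged,
        n_iter=it,
    )
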
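"""Maximum-likelihood fitting of the Rogers random-predator equation.

Observation model: each cage is an independent trial in which every one of
the N0 prey is killed with probability Ne(N0; a, Th)/N0, so

    killed_i ~ Binomial(N0_i, Ne(N0_i)/N0_i)

with Ne the depletion-aware type II expectation.  The likelihood is
maximized over (log a, log Th), which enforces positivity without
constrained optimization and matches how standard functional-response
fitting tools parameterize the problem.  The binomial kernel depends on the
data only through per-density totals of prey offered and killed, and the
gradient follows from implicit differentiation of the Rogers root, so each
fit is a cheap quasi-Newton solve.  Wald standard errors come from the
inverse finite-difference Hessian on the log scale, mapped back through the
delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, xlogy

from .core import FRParams, rogers_expected
from .errors import DegenerateDataError, InvalidDesignError
from .tables import ExperimentTable

__all__ = ["FitResult", "negative_log_likelihood", "fit_rogers"]

_P_EPS = 1e-12
_LOG_JITTER = 1.0  # half-width of the log-uniform multi-start jitter


@dataclass(frozen=True)
class FitResult:
    """ML estimates of (a, Th) with Wald inference and convergence metadata."""

    attack_rate_hat: float
    handling_time_hat: float
    standard_errors: tuple[float, float]
    z_values: tuple[float, float]
    p_values: tuple[float, float]
    log_likelihood: float
    vcov: np.ndarray  # 2x2, natural (a, Th) scale
    converged: bool
    n_trials: int
    duration: float

    @property
    def params(self) -> FRParams:
        return FRParams(self.attack_rate_hat, self.handling_time_hat, self.duration)

    def report(self) -> list[dict]:
        rows = []
        for name, est, se, z, p in zip(
            ("attack_rate", "handling_time"),
            (self.attack_rate_hat, self.handling_time_hat),
            self.standard_errors,
            self.z_values,
            self.p_values,
        ):
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - 1.959963984540054 * se,
                    "ci_high": est + 1.959963984540054 * se,
                    "z": z,
                    "p": p,
                }
            )
        return rows


def _suffstats(n0: np.ndarray, killed: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-unique-density totals (densities, killed, offered).

    The binomial kernel (up to constants) depends on the trials only through
    these totals, which keeps likelihood evaluations O(#densities).
    """
    uniq, inv = np.unique(n0, return_inverse=True)
    k_tot = np.bincount(inv, weights=killed, minlength=len(uniq))
    n_tot = np.bincount(inv, weights=n0, minlength=len(uniq))
    return uniq.astype(float), k_tot, n_tot


def _kernel_and_grad(
    x: np.ndarray, uniq: np.ndarray, k_tot: np.ndarray, n_tot: np.ndarray, duration: float
) -> tuple[float, np.ndarray]:
    """Negative binomial log-kernel and its gradient in (log a, log Th).

    dNe/da and dNe/dTh follow from implicit differentiation of
    Ne = N0*(1 - E), E = exp(a*Th*Ne - a*T):

        dNe/da  =  N0*E*(T - Th*Ne) / (1 + a*Th*N0*E)
        dNe/dTh = -N0*E*a*Ne        / (1 + a*Th*N0*E)
    """
    if not np.all(np.isfinite(x)):
        return np.inf, np.zeros(2)
    a, th = np.exp(x)
    ne = rogers_expected(a, th, duration, uniq)
    p = np.clip(ne / uniq, _P_EPS, 1.0 - _P_EPS)
    nll = -float(np.sum(xlogy(k_tot, p) + xlogy(n_tot - k_tot, 1.0 - p)))
    if not np.isfinite(nll):
        return np.inf, np.zeros(2)
    e = 1.0 - ne / uniq
    denom = 1.0 + a * th * uniq * e
    dne_da = uniq * e * (duration - th * ne) / denom
    dne_dth = -uniq * e * a * ne / denom
    w = (k_tot / p - (n_tot - k_tot) / (1.0 - p)) / uniq
    grad = np.array([-np.sum(w * dne_da) * a, -np.sum(w * dne_dth) * th])
    return nll, grad


def _optimize_kernel(
    x0: np.ndarray, uniq: np.ndarray, k_tot: np.ndarray, n_tot: np.ndarray, duration: float
) -> optimize.OptimizeResult:
    return optimize.minimize(
        _kernel_and_grad,
        x0,
        args=(uniq, k_tot, n_tot, duration),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
    )


def negative_log_likelihood(params: FRParams, table: ExperimentTable) -> float:
    """Binomial negative log likelihood of a trial table under given parameters.

    Includes the combinatorial constants, so the value is the exact negative
    log of the product of binomial masses (with kill probabilities clipped
    away from 0 and 1 for boundary safety).
    """
    n0 = table.densities.astype(float)
    killed = table.killed.astype(float)
    ne = rogers_expected(params.attack_rate, params.handling_time, params.duration, n0)
    p = np.clip(ne / n0, _P_EPS, 1.0 - _P_EPS)
    kernel = -float(np.sum(xlogy(killed, p) + xlogy(n0 - killed, 1.0 - p)))
    const = float(np.sum(gammaln(n0 + 1) - gammaln(killed + 1) - gammaln(n0 - killed + 1)))
    return kernel - const


def _initial_guess(n0: np.ndarray, killed: np.ndarray, duration: float) -> tuple[float, float]:
    """Moment-style starting values from the no-depletion disc equation.

    The saturation level of mean kills approximates T/Th, and the kill
    proportion at the lowest density approximates 1 - exp(-a*T).
    """
    dens = np.unique(n0)
    means = np.array([killed[n0 == d].mean() for d in dens])
    ne_max = max(means.max(), 1e-6)
    th0 = duration / ne_max
    p_low = np.clip(means[0] / dens[0], 1e-4, 1.0 - 1e-4)
    a0 = -np.log1p(-p_low) / duration
    return float(max(a0, 1e-6)), float(max(th0, 1e-9))


def fit_rogers(
    table: ExperimentTable,
    init: FRParams | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit (a, Th) by maximizing the binomial likelihood over (log a, log Th).

    A moment-based start (or ``init``) is followed by ``n_starts`` log-uniform
    jittered restarts; the best converged optimum wins.
    """
    n0 = table.densities.astype(float)
    killed = table.killed.astype(float)
    if len(np.unique(n0)) < 2:
        raise InvalidDesignError("fit requires at least two distinct densities")
    if killed.sum() == 0:
        raise DegenerateDataError("total killed is zero; attack rate is not identifiable")
    duration = table.duration
    uniq, k_tot, n_tot = _suffstats(n0, killed)

    if init is not None:
        a0, th0 = max(init.attack_rate, 1e-9), max(init.handling_time, 1e-9)
    else:
        a0, th0 = _initial_guess(n0, killed, duration)
    x0 = np.array([np.log(a0), np.log(th0)])

    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.uniform(-_LOG_JITTER, _LOG_JITTER, size=2) for _ in range(int(n_starts))]

    best = None
    any_success = False
    for x_start in starts:
        res = _optimize_kernel(x_start, uniq, k_tot, n_tot, duration)
        any_success = any_success or bool(res.success and np.isfinite(res.fun))
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    converged = bool(any_success and np.isfinite(best.fun))

    log_a, log_th = best.x
    a_hat, th_hat = float(np.exp(log_a)), float(np.exp(log_th))

    def obj(x: np.ndarray) -> float:
        return _kernel_and_grad(x, uniq, k_tot, n_tot, duration)[0]

    # Hessian of the NLL in (log a, log Th) by central differences
    vcov_nat = np.full((2, 2), np.nan)
    se = (np.nan, np.nan)
    h = 1e-4
    hess = np.empty((2, 2))
    f0 = best.fun
    for i in range(2):
        ei = np.eye(2)[i] * h
        hess[i, i] = (obj(best.x + ei) - 2 * f0 + obj(best.x - ei)) / h**2
    e0, e1 = np.eye(2) * h
    hess[0, 1] = hess[1, 0] = (
        obj(best.x + e0 + e1) - obj(best.x + e0 - e1) - obj(best.x - e0 + e1) + obj(best.x - e0 - e1)
    ) / (4 * h**2)
    try:
        vcov_log = np.linalg.inv(hess)
        if np.all(np.isfinite(vcov_log)) and vcov_log[0, 0] > 0 and vcov_log[1, 1] > 0:
            jac = np.diag([a_hat, th_hat])  # delta method: d(a)/d(log a) = a
            vcov_nat = jac @ vcov_log @ jac
            se = (float(np.sqrt(vcov_nat[0, 0])), float(np.sqrt(vcov_nat[1, 1])))
        else:
            converged = False  # optimum sits where curvature is not positive definite
    except np.linalg.LinAlgError:
        converged = False

    z = tuple(est / s if (np.isfinite(s) and s > 0) else np.nan for est, s in zip((a_hat, th_hat), se))
    p = tuple(2.0 * stats.norm.sf(abs(zz)) if np.isfinite(zz) else np.nan for zz in z)

    const = float(np.sum(gammaln(n0 + 1) - gammaln(killed + 1) - gammaln(n0 - killed + 1)))
    return FitResult(
        attack_rate_hat=a_hat,
        handling_time_hat=th_hat,
        standard_errors=se,
        z_values=z,
        p_values=p,
        log_likelihood=-(best.fun - const),
        vcov=vcov_nat,
        converged=converged,
        n_trials=len(n0),
        duration=duration,
    )
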
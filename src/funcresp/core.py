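"""Deterministic type II functional-response predictions.

The central object is the Rogers random-predator equation, the implicit
type II model that accounts for prey depletion over the exposure period
(prey are not replaced as they are killed):

    Ne = N0 * (1 - exp(a*Th*Ne - a*T))

where ``Ne`` is the expected number of prey killed, ``N0`` the initial
prey density, ``a`` the instantaneous attack (search) rate, ``Th`` the
handling time per prey, and ``T`` the total exposure duration.  The
equation has a unique root in [0, N0], available in closed form through
the principal branch of the Lambert W function:

    Ne = N0 - W0(a*Th*N0 * exp(-a*(T - Th*N0))) / (a*Th)

All quantities are unit-agnostic: ``a``, ``Th`` and ``T`` need only share
a time unit (the model depends on the dimensionless products ``a*T`` and
``a*Th*N0``).  Published cage-study estimates in this domain are
conventionally expressed per exposure period, i.e. T = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .errors import InvalidParameterError, NumericalDomainError

__all__ = [
    "FRParams",
    "Prediction",
    "solve_rogers_closed_form",
    "solve_rogers_fixed_point",
    "holling_disc",
    "rogers_expected",
]


@dataclass(frozen=True)
class FRParams:
    """Type II functional-response parameters.

    Attributes
    ----------
    attack_rate : float
        Instantaneous rate of successful search, per unit time (a >= 0).
    handling_time : float
        Time spent handling each captured prey, during which no searching
        occurs (Th >= 0).
    duration : float
        Total exposure duration T (> 0), in the same time unit as the
        other two parameters.
    """

    attack_rate: float
    handling_time: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        for name in ("attack_rate", "handling_time", "duration"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.attack_rate < 0:
            raise InvalidParameterError(f"attack_rate must be >= 0, got {self.attack_rate}")
        if self.handling_time < 0:
            raise InvalidParameterError(f"handling_time must be >= 0, got {self.handling_time}")
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class Prediction:
    """Expected kill at one initial prey density."""

    initial_density: int
    expected_eaten: float


def _check_density(initial_density: int) -> int:
    n0 = int(initial_density)
    if n0 < 1 or n0 != initial_density:
        raise InvalidParameterError(f"initial_density must be a positive integer, got {initial_density!r}")
    return n0


def _lambertw_exp(y: np.ndarray) -> np.ndarray:
    """W0(exp(y)) for real y, stable when exp(y) would overflow.

    For large y the defining relation W + log W = y is solved by Newton
    iteration; otherwise scipy's lambertw is evaluated directly.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y < 700.0  # exp(700) still finite in double precision
    if np.any(small):
        z = np.exp(y[small])
        w = np.real(lambertw(z))
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise NumericalDomainError(f"Lambert-W evaluation failed for argument(s) {z}")
        out[small] = w
    if np.any(~small):
        yy = y[~small]
        w = yy - np.log(yy)
        for _ in range(6):  # quadratic convergence; 6 steps is far beyond need
            w = w - (w + np.log(w) - yy) / (1.0 + 1.0 / w)
        out[~small] = w
    return out


def rogers_expected(
    attack_rate: float,
    handling_time: float,
    duration: float,
    densities: np.ndarray,
) -> np.ndarray:
    """Vectorized root of the random-predator equation for an array of N0.

    Broadcasts over ``attack_rate``/``handling_time`` arrays as well, which
    the bootstrap band evaluation relies on.  Degenerate products a*Th = 0
    dispatch to the explicit limit forms (a = 0 kills nothing; Th = 0 is the
    pure random-search model N0*(1 - exp(-a*T))).
    """
    a = np.asarray(attack_rate, dtype=float)
    th = np.asarray(handling_time, dtype=float)
    n0 = np.asarray(densities, dtype=float)
    a, th, n0 = np.broadcast_arrays(a, th, n0)
    shape = a.shape
    a, th, n0 = a.ravel(), th.ravel(), n0.ravel()
    ne = np.zeros(a.shape, dtype=float)

    pos = a > 0
    # a*Th*N0 underflowing to zero is numerically the Th -> 0 limit
    th0 = pos & (a * th * n0 == 0)
    if np.any(th0):
        ne[th0] = n0[th0] * (-np.expm1(-a[th0] * duration))
    gen = pos & ~th0
    if np.any(gen):
        ag, tg, ng = a[gen], th[gen], n0[gen]
        prod = ag * tg * ng
        y = np.log(prod) + prod - ag * duration
        val = np.empty_like(y)
        tiny = y < -36.0  # W(e^y) ~ e^y: evaluate the deficit e^y/(a*Th) in log space
        if np.any(tiny):
            val[tiny] = ng[tiny] * (-np.expm1(prod[tiny] - ag[tiny] * duration))
        if np.any(~tiny):
            nt = ~tiny
            val[nt] = ng[nt] - _lambertw_exp(y[nt]) / (ag[nt] * tg[nt])
        ne[gen] = val
    # guard rounding just outside [0, N0]
    return np.clip(ne, 0.0, n0).reshape(shape)


def solve_rogers_closed_form(params: FRParams, initial_density: int) -> Prediction:
    """Expected prey killed under prey depletion, via the Lambert-W closed form.

    Returns the unique root Ne in [0, N0] of
    Ne = N0*(1 - exp(a*Th*Ne - a*T)).
    """
    n0 = _check_density(initial_density)
    ne = float(rogers_expected(params.attack_rate, params.handling_time, params.duration, np.array(float(n0))))
    return Prediction(initial_density=n0, expected_eaten=ne)


def solve_rogers_fixed_point(params: FRParams, initial_density: int, tol: float = 1e-10) -> Prediction:
    """Root of the random-predator equation by bracketed bisection on [0, N0].

    Independent of the Lambert-W path; used as a numerical oracle for
    :func:`solve_rogers_closed_form`.
    """
    if not tol > 0:
        raise InvalidParameterError(f"tol must be > 0, got {tol}")
    n0 = _check_density(initial_density)
    a, th, t = params.attack_rate, params.handling_time, params.duration
    if a == 0:
        return Prediction(n0, 0.0)

    def f(ne: float) -> float:
        return n0 * -math.expm1(min(a * th * ne - a * t, 0.0)) - ne

    lo, hi = 0.0, float(n0)
    flo = f(lo)
    if flo < 0:  # f(0) = N0*(1-exp(-aT)) >= 0 always; anything else is a bug
        raise NumericalDomainError(f"no sign change on [0, N0] for params={params}, N0={n0}")
    if f(hi) > 0:
        return Prediction(n0, float(n0))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return Prediction(n0, 0.5 * (lo + hi))


def holling_disc(params: FRParams, initial_density: int) -> Prediction:
    """Holling disc (no-depletion) prediction Ne = a*N0*T / (1 + a*Th*N0), capped at N0.

    Ignores prey depletion, so it upper-bounds the random-predator
    prediction; used for initial values and limit checks.
    """
    n0 = _check_density(initial_density)
    a, th, t = params.attack_rate, params.handling_time, params.duration
    ne = a * n0 * t / (1.0 + a * th * n0)
    return Prediction(n0, min(ne, float(n0)))
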
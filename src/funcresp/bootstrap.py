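"""Nonparametric bootstrap of functional-response fits and band comparison.

Whole trials (cages) are resampled with replacement, each resample refitted
by maximum likelihood warm-started at the original estimates, and percentile
intervals taken across the successful refits — both for the parameters and,
pointwise on a density grid, for the predicted curve.  Two treatments are
compared by marking the densities at which their 95% curve bands are
disjoint: where the bands overlap, the functional responses (and/or their
parameters) are not distinguished at that density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import rogers_expected
from .errors import InvalidComparisonError, NoDrawsError
from .fit import FitResult, _optimize_kernel, fit_rogers
from .tables import ExperimentTable

__all__ = ["BootstrapResult", "OverlapReport", "bootstrap_fit", "curve_band", "compare_bands"]

UNSTABLE_FAILURE_FRACTION = 0.2


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap draws, percentile parameter CIs, and a default curve band."""

    draws: np.ndarray  # (n_success, 2) columns (attack_rate, handling_time)
    n_requested: int
    n_failed: int
    attack_rate_ci: tuple[float, float]
    handling_time_ci: tuple[float, float]
    point: FitResult
    grid: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    density_range: tuple[int, int]
    duration: float
    unstable: bool

    @property
    def n_success(self) -> int:
        return self.n_requested - self.n_failed


@dataclass(frozen=True)
class OverlapReport:
    """Density intervals on which two treatments' 95% bands are disjoint."""

    intervals: tuple[tuple[float, float], ...]
    grid_step: float
    grid_range: tuple[float, float]

    @property
    def any_difference(self) -> bool:
        return len(self.intervals) > 0


def _refit_draws(
    n0: np.ndarray, killed: np.ndarray, duration: float, x_init: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(n0, return_inverse=True)
    uniq = uniq.astype(float)
    draws = np.empty((n_boot, 2))
    n_failed = 0
    n = len(n0)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        k_tot = np.bincount(inv[idx], weights=killed[idx], minlength=len(uniq))
        n_tot = np.bincount(inv[idx], weights=n0[idx], minlength=len(uniq))
        if k_tot.sum() == 0 or np.count_nonzero(n_tot) < 2:
            n_failed += 1
            continue
        res = _optimize_kernel(x_init, uniq, k_tot, n_tot, duration)
        if res.success and np.isfinite(res.fun):
            draws[kept] = np.exp(res.x)
            kept += 1
        else:
            n_failed += 1
    return draws[:kept], n_failed


def bootstrap_fit(
    table: ExperimentTable,
    n_boot: int = 2000,
    seed: int = 0,
    fit: FitResult | None = None,
) -> BootstrapResult:
    """Bootstrap the (a, Th) fit of one treatment's trial table.

    The resampling unit is the whole trial.  Resamples whose refit does not
    converge (or that are degenerate: no kills, a single density) are dropped
    and counted; more than 20% failures flags the result as unstable with a
    warning rather than an error.
    """
    if n_boot < 1:
        raise NoDrawsError(f"n_boot must be >= 1, got {n_boot}")
    if fit is None:
        fit = fit_rogers(table, seed=seed)
    if not fit.converged:
        raise NoDrawsError("bootstrap requires a converged point fit")

    n0 = table.densities.astype(float)
    killed = table.killed.astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    x_init = np.log([fit.attack_rate_hat, fit.handling_time_hat])
    draws, n_failed = _refit_draws(n0, killed, table.duration, x_init, int(n_boot), rng)
    if len(draws) == 0:
        raise NoDrawsError("all bootstrap resamples failed to refit")

    unstable = n_failed > UNSTABLE_FAILURE_FRACTION * n_boot
    if unstable:
        warnings.warn(
            f"bootstrap unstable: {n_failed}/{n_boot} resamples failed to converge", RuntimeWarning
        )
    a_ci = tuple(np.quantile(draws[:, 0], [0.025, 0.975]))
    th_ci = tuple(np.quantile(draws[:, 1], [0.025, 0.975]))
    d_min, d_max = int(n0.min()), int(n0.max())
    grid = np.arange(d_min, d_max + 1, dtype=float)
    band_low, band_high = _band_from_draws(draws, grid, table.duration)
    return BootstrapResult(
        draws=draws,
        n_requested=int(n_boot),
        n_failed=n_failed,
        attack_rate_ci=a_ci,
        handling_time_ci=th_ci,
        point=fit,
        grid=grid,
        band_low=band_low,
        band_high=band_high,
        density_range=(d_min, d_max),
        duration=table.duration,
        unstable=unstable,
    )


def _band_from_draws(draws: np.ndarray, grid: np.ndarray, duration: float) -> tuple[np.ndarray, np.ndarray]:
    curves = rogers_expected(draws[:, 0][:, None], draws[:, 1][:, None], duration, grid[None, :])
    low, high = np.quantile(curves, [0.025, 0.975], axis=0)
    return low, high


def curve_band(result: BootstrapResult, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise 95% percentile band of the predicted curve on ``grid``.

    Every bootstrap draw's curve is evaluated at each grid density and the
    2.5%/97.5% quantiles taken pointwise.
    """
    if len(result.draws) == 0:
        raise NoDrawsError("bootstrap result contains no successful draws")
    grid = np.asarray(grid, dtype=float)
    lo, hi = result.density_range
    if grid.min() < lo or grid.max() > hi:
        raise InvalidComparisonError(
            f"grid [{grid.min()}, {grid.max()}] outside experimental density range [{lo}, {hi}]"
        )
    return _band_from_draws(result.draws, grid, result.duration)


def compare_bands(a: BootstrapResult, b: BootstrapResult, grid_step: float = 1.0) -> OverlapReport:
    """Locate density intervals where two treatments' 95% bands are disjoint.

    Both bands are evaluated on a shared grid covering the intersection of
    the two experimental density ranges; consecutive disjoint grid points are
    merged into closed intervals.  An empty interval list means the bands
    overlap everywhere, i.e. no density at which the responses separate.
    """
    if grid_step <= 0:
        raise InvalidComparisonError(f"grid_step must be > 0, got {grid_step}")
    lo = max(a.density_range[0], b.density_range[0])
    hi = min(a.density_range[1], b.density_range[1])
    if lo > hi:
        raise InvalidComparisonError(
            f"experimental density ranges {a.density_range} and {b.density_range} do not overlap"
        )
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step, dtype=float)
    low_a, high_a = curve_band(a, grid)
    low_b, high_b = curve_band(b, grid)
    disjoint = (low_a > high_b) | (low_b > high_a)

    intervals: list[tuple[float, float]] = []
    start = None
    for g, d in zip(grid, disjoint):
        if d and start is None:
            start = g
        elif not d and start is not None:
            intervals.append((start, prev))
            start = None
        prev = g
    if start is not None:
        intervals.append((start, float(grid[-1])))
    return OverlapReport(intervals=tuple(intervals), grid_step=float(grid_step), grid_range=(float(lo), float(hi)))
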
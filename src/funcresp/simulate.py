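"""Synthetic functional-response experiments.

Two generators with different roles:

* :func:`generate_trials` draws binomial observation noise around the
  deterministic random-predator expectation — exactly the observation model
  the maximum-likelihood fit assumes, so parameter-recovery tests are
  unconfounded by model misspecification.
* :func:`simulate_foraging_process` is an independent mechanistic oracle: a
  continuous-time renewal process in which a forager searches at rate a*n
  (n = prey remaining), removes one prey per capture, and is occupied for a
  fixed handling time Th after each capture until the clock reaches T.  Its
  mean tracks the Rogers solution and it doubles as a misspecification
  stressor.

Additional generators produce sigmoidal (type III) data for exercising the
response-type classifier, and logistic-normal binomial data for the
observation-level random-effect GLMM.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FRParams, rogers_expected
from .errors import InvalidDesignError, InvalidParameterError
from .tables import ExperimentTable

__all__ = [
    "generate_trials",
    "simulate_foraging_process",
    "generate_type3_trials",
    "generate_glmm_data",
    "cell_rng",
]


def cell_rng(seed: int, *labels: str) -> np.random.Generator:
    """Child RNG stream for one treatment cell, independent of other cells.

    The stream is derived from the master seed plus a stable hash of the
    labels, so adding or removing a cell never perturbs the draws of the
    others.
    """
    digest = hashlib.sha256("|".join(labels).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _check_densities(densities: Sequence[int]) -> list[int]:
    densities = list(densities)
    if not densities:
        raise InvalidDesignError("densities must be non-empty")
    if any(int(d) < 1 or int(d) != d for d in densities):
        raise InvalidDesignError(f"densities must be positive integers, got {densities}")
    return [int(d) for d in densities]


def generate_trials(
    params_by_cell: Mapping[tuple[str, str], FRParams],
    densities: Sequence[int],
    replicates: int,
    seed: int,
) -> ExperimentTable:
    """Simulate a full factorial cage experiment.

    For every (distribution, enemy) cell, density and replicate, the kill
    count is drawn as Binomial(N0, Ne(N0)/N0) with Ne the random-predator
    expectation under that cell's parameters.  Reproducible given ``seed``.
    """
    if not params_by_cell:
        raise InvalidDesignError("params_by_cell must contain at least one treatment cell")
    densities = _check_densities(densities)
    if replicates < 1:
        raise InvalidDesignError(f"replicates must be >= 1, got {replicates}")
    durations = {p.duration for p in params_by_cell.values()}
    if len(durations) != 1:
        raise InvalidDesignError(f"all cells must share one exposure duration, got {sorted(durations)}")
    duration = durations.pop()

    frames = []
    n0 = np.asarray(densities, dtype=float)
    for (distribution, enemy), params in params_by_cell.items():
        rng = cell_rng(seed, distribution, enemy)
        p = rogers_expected(params.attack_rate, params.handling_time, duration, n0) / n0
        killed = rng.binomial(np.asarray(densities)[None, :], p[None, :], size=(replicates, len(densities)))
        frames.append(
            pd.DataFrame(
                {
                    "density": np.tile(densities, replicates),
                    "killed": killed.ravel(),
                    "distribution": distribution,
                    "enemy": enemy,
                    "replicate": np.repeat(np.arange(1, replicates + 1), len(densities)),
                }
            )
        )
    return ExperimentTable(pd.concat(frames, ignore_index=True), duration)


def simulate_foraging_process(
    params: FRParams,
    initial_density: int,
    seed: int,
    size: int | None = None,
    max_captures: int | None = None,
) -> int | np.ndarray:
    """Mechanistic renewal-process simulation of one forager.

    Search times are exponential with rate a*n where n is the number of prey
    still alive; each capture removes one prey and occupies the forager for
    the handling time Th.  A capture counts if its search completes within
    the exposure duration T, even when the subsequent handling runs past the
    clock, so at most 1 + floor(T/Th) captures are possible.

    With ``size=None`` a single integer kill count is returned; otherwise an
    array of ``size`` independent runs.
    """
    n0 = int(initial_density)
    if n0 < 1:
        raise InvalidParameterError(f"initial_density must be positive, got {initial_density}")
    a, th, t_total = params.attack_rate, params.handling_time, params.duration
    if th == 0 and max_captures is None:
        max_captures = n0
    cap = n0 if th == 0 else min(n0, 1 + int(np.floor(t_total / th)))
    if max_captures is not None:
        cap = min(cap, int(max_captures))

    n_runs = 1 if size is None else int(size)
    rng = np.random.default_rng(seed)
    n = np.full(n_runs, n0, dtype=np.int64)
    t = np.zeros(n_runs)
    killed = np.zeros(n_runs, dtype=np.int64)
    if a > 0:
        while True:
            active = (n > 0) & (t < t_total) & (killed < cap)
            if not active.any():
                break
            s = rng.exponential(1.0 / (a * n[active]))
            t_hit = t[active] + s
            caught = t_hit <= t_total
            idx = np.flatnonzero(active)
            hit = idx[caught]
            killed[hit] += 1
            n[hit] -= 1
            t[hit] = t_hit[caught] + th
            t[idx[~caught]] = np.inf
    return int(killed[0]) if size is None else killed


def generate_type3_trials(
    base_rate_slope: float,
    handling_time: float,
    duration: float,
    densities: Sequence[int],
    replicates: int,
    seed: int,
    distribution: str = "aggregate",
    enemy: str = "predator_single",
) -> ExperimentTable:
    """Sigmoidal (type III) data: attack rate rises linearly with density.

    Substituting a(N0) = slope * N0 into the random-predator expectation
    makes the kill proportion first rise with density, producing the positive
    linear logistic coefficient diagnostic of a type III response.
    """
    if base_rate_slope < 0:
        raise InvalidDesignError(f"base_rate_slope must be >= 0, got {base_rate_slope}")
    densities = _check_densities(densities)
    if replicates < 1:
        raise InvalidDesignError(f"replicates must be >= 1, got {replicates}")
    rng = cell_rng(seed, "type3", distribution, enemy)
    n0 = np.asarray(densities, dtype=float)
    a = base_rate_slope * n0
    p = rogers_expected(a, handling_time, duration, n0) / n0
    killed = rng.binomial(np.asarray(densities)[None, :], p[None, :], size=(replicates, len(densities)))
    df = pd.DataFrame(
        {
            "density": np.tile(densities, replicates),
            "killed": killed.ravel(),
            "distribution": distribution,
            "enemy": enemy,
            "replicate": np.repeat(np.arange(1, replicates + 1), len(densities)),
        }
    )
    return ExperimentTable(df, duration)


def generate_glmm_data(
    fixed_coefficients: Iterable[float],
    olre_sd: float,
    design: ExperimentTable,
    seed: int,
) -> ExperimentTable:
    """Logistic-normal binomial data on an existing design skeleton.

    Per trial, logit(p) = x'beta + u with u ~ Normal(0, olre_sd^2) drawn
    independently per observation (the observation-level random effect), and
    killed ~ Binomial(N0, p).  The design matrix is (intercept, density,
    uniform-distribution indicator, density x indicator), matching the GLMM
    fit.
    """
    from .glmm import glmm_design_matrix

    if olre_sd < 0:
        raise InvalidDesignError(f"olre_sd must be >= 0, got {olre_sd}")
    beta = np.asarray(list(fixed_coefficients), dtype=float)
    x = glmm_design_matrix(design.trials)
    if x.shape[1] != beta.size:
        raise InvalidDesignError(f"design matrix has {x.shape[1]} columns but {beta.size} coefficients given")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6C6D6D]))
    u = rng.normal(0.0, olre_sd, size=len(design.trials))
    eta = x @ beta + u
    p = 1.0 / (1.0 + np.exp(-eta))
    df = design.trials.copy()
    df["killed"] = rng.binomial(df["density"].to_numpy(), p)
    return ExperimentTable(df, design.duration)
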
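"""Maximum-likelihood fitting: likelihood correctness and estimator behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from funcresp import (
    ExperimentTable,
    FRParams,
    fit_rogers,
    generate_trials,
    negative_log_likelihood,
    solve_rogers_closed_form,
)
from funcresp.core import rogers_expected
from funcresp.errors import DegenerateDataError, InvalidDesignError
from funcresp.study import STUDY_DENSITIES


def _table(densities, killed, duration=1.0):
    df = pd.DataFrame(
        {
            "density": densities,
            "killed": killed,
            "distribution": "aggregate",
            "enemy": "predator_single",
            "replicate": 1,
        }
    )
    return ExperimentTable(df, duration)


def _noiseless_table(params, densities=STUDY_DENSITIES, reps=10):
    # apportion floor/ceil counts across replicates so each density's total
    # matches the continuous expectation to within one prey
    dens, killed = [], []
    for d in densities:
        ne = solve_rogers_closed_form(params, d).expected_eaten
        n_ceil = round((ne - np.floor(ne)) * reps)
        for r in range(reps):
            dens.append(d)
            killed.append(int(np.floor(ne)) + (1 if r < n_ceil else 0))
    return _table(dens, killed, params.duration)


class TestNegativeLogLikelihood:
    def test_matches_direct_binomial_sum(self, predator_cell_table):
        params = FRParams(1.4, 0.008, 1.0)
        n0 = predator_cell_table.densities
        ne = rogers_expected(params.attack_rate, params.handling_time, 1.0, n0.astype(float))
        direct = -stats.binom.logpmf(predator_cell_table.killed, n0, ne / n0).sum()
        assert negative_log_likelihood(params, predator_cell_table) == pytest.approx(direct, rel=1e-10)

    def test_likelihood_peaks_near_truth(self):
        truth = FRParams(1.0, 0.02, 1.0)
        table = _table([64], [round(solve_rogers_closed_form(truth, 64).expected_eaten)])
        nll_truth = negative_log_likelihood(truth, table)
        for off in (FRParams(0.3, 0.02, 1.0), FRParams(1.0, 0.08, 1.0)):
            shift = abs(
                solve_rogers_closed_form(off, 64).expected_eaten
                - solve_rogers_closed_form(truth, 64).expected_eaten
            )
            assert shift >= 2
            assert negative_log_likelihood(off, table) > nll_truth

    def test_saturated_probability_still_finite(self):
        # attack rate so large every prey dies: p clips to 1 - eps
        table = _table([16, 32], [16, 32], duration=24.0)
        val = negative_log_likelihood(FRParams(50.0, 1e-6, 24.0), table)
        assert np.isfinite(val)


class TestFitRogers:
    def test_noiseless_recovery_within_2_percent(self):
        truth = FRParams(0.5, 0.05, 1.0)
        fit = fit_rogers(_noiseless_table(truth), seed=0)
        assert fit.converged
        assert fit.attack_rate_hat == pytest.approx(0.5, rel=0.02)
        assert fit.handling_time_hat == pytest.approx(0.05, rel=0.02)

    def test_optimum_matches_grid_search(self):
        truth = FRParams(1.59, 0.006, 1.0)
        table = generate_trials(
            {("aggregate", "predator_single"): truth}, STUDY_DENSITIES, 2, seed=4
        )
        fit = fit_rogers(table, seed=0)
        la = np.linspace(np.log(1.59) - 0.7, np.log(1.59) + 0.7, 200)
        lt = np.linspace(np.log(0.006) - 0.7, np.log(0.006) + 0.7, 200)
        dens = table.densities.astype(float)
        ne = rogers_expected(
            np.exp(la)[:, None, None], np.exp(lt)[None, :, None], 1.0, dens[None, None, :]
        )
        p = np.clip(ne / dens, 1e-12, 1 - 1e-12)
        k = table.killed
        nll = -(k * np.log(p) + (dens - k) * np.log1p(-p)).sum(axis=2)
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        step_a, step_t = la[1] - la[0], lt[1] - lt[0]
        assert abs(np.log(fit.attack_rate_hat) - la[i]) <= step_a
        assert abs(np.log(fit.handling_time_hat) - lt[j]) <= step_t

    def test_order_and_duplication_invariance(self, predator_cell_table):
        base = fit_rogers(predator_cell_table, seed=0)
        shuffled = ExperimentTable(
            predator_cell_table.trials.sample(frac=1.0, random_state=9).reset_index(drop=True), 1.0
        )
        assert fit_rogers(shuffled, seed=0).attack_rate_hat == pytest.approx(
            base.attack_rate_hat, rel=1e-6
        )
        doubled = ExperimentTable(
            pd.concat([predator_cell_table.trials] * 2, ignore_index=True), 1.0
        )
        dup = fit_rogers(doubled, seed=0)
        assert dup.attack_rate_hat == pytest.approx(base.attack_rate_hat, rel=1e-6)
        assert dup.standard_errors[0] == pytest.approx(base.standard_errors[0] / np.sqrt(2), rel=0.01)

    def test_log_and_box_constrained_parameterizations_agree(self, predator_cell_table):
        fit = fit_rogers(predator_cell_table, seed=0)

        def nll_natural(theta):
            return negative_log_likelihood(FRParams(theta[0], theta[1], 1.0), predator_cell_table)

        res = optimize.minimize(
            nll_natural,
            x0=[1.0, 0.01],
            method="L-BFGS-B",
            bounds=[(1e-8, None), (1e-8, None)],
            options={"ftol": 1e-15, "gtol": 1e-10},
        )
        assert res.x[0] == pytest.approx(fit.attack_rate_hat, rel=1e-3)
        assert res.x[1] == pytest.approx(fit.handling_time_hat, rel=1e-3)

    def test_bias_shrinks_with_replication(self, predator_aggregate_params):
        truth = predator_aggregate_params
        errs = []
        for reps in (10, 100):
            est = []
            for seed in range(5):
                table = generate_trials(
                    {("aggregate", "predator_single"): truth}, STUDY_DENSITIES, reps, seed=seed
                )
                est.append(fit_rogers(table, seed=seed, n_starts=2).attack_rate_hat)
            errs.append(abs(np.mean(est) - truth.attack_rate))
        assert errs[1] < max(errs[0], 0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidDesignError):
            fit_rogers(_table([8, 8, 8], [2, 3, 1]))
        with pytest.raises(DegenerateDataError):
            fit_rogers(_table([8, 16], [0, 0]))

    def test_wald_inference_finite_and_positive(self, predator_cell_table):
        fit = fit_rogers(predator_cell_table, seed=0)
        assert fit.converged
        assert all(se > 0 for se in fit.standard_errors)
        assert fit.vcov[0, 1] == pytest.approx(fit.vcov[1, 0])
        assert all(0 <= p <= 1 for p in fit.p_values)
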
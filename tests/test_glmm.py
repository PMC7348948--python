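"""OLRE binomial GLMM: quadrature accuracy, boundary collapse, recovery."""

import subprocess

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from funcresp import fit_olre_binomial, generate_glmm_data, marginal_loglik, wald_table
from funcresp.errors import InvalidDesignError
from funcresp.glmm import GLMMFit, _binom_logkernel, glmm_design_matrix

BETA = np.array([-2.0, 0.01, 0.5, -0.005])


def _arrays(table):
    x = glmm_design_matrix(table.trials)
    k = table.trials["killed"].to_numpy(float)
    n = table.trials["density"].to_numpy(float)
    return x, k, n


class TestMarginalLikelihood:
    def test_quadrature_matches_brute_force_integration(self, glmm_design):
        table = generate_glmm_data(BETA, 0.8, glmm_design, seed=3)
        x, k, n = _arrays(table)
        sigma = 0.8
        ll_quad = marginal_loglik(BETA, sigma, x, k, n, quadrature_nodes=15)
        z = np.linspace(-10.0, 10.0, 20001)
        fj = _binom_logkernel(k[:, None], n[:, None], (x @ BETA)[:, None] + sigma * z[None, :])
        fj = fj - 0.5 * z[None, :] ** 2
        ll_brute = float(
            np.sum(logsumexp(fj, axis=1) + np.log(z[1] - z[0]) - 0.5 * np.log(2 * np.pi))
            + np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
        )
        assert abs(ll_quad - ll_brute) / len(k) < 1e-6

    def test_sigma_zero_equals_plain_binomial(self, glmm_design):
        table = generate_glmm_data(BETA, 0.5, glmm_design, seed=4)
        x, k, n = _arrays(table)
        direct = float(
            np.sum(_binom_logkernel(k, n, x @ BETA))
            + np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
        )
        assert marginal_loglik(BETA, 0.0, x, k, n) == pytest.approx(direct, rel=1e-12)


class TestFitOlre:
    def test_sigma_zero_data_collapse_to_glm(self, glmm_design):
        table = generate_glmm_data(BETA, 0.0, glmm_design, seed=4)
        fit = fit_olre_binomial(table, quadrature_nodes=15)
        assert fit.boundary
        assert fit.olre_sd == 0.0
        x, k, n = _arrays(table)
        ref = sm.GLM(np.column_stack([k, n - k]), x, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.fixed_estimates, ref.params, rtol=0, atol=1e-4)

    def test_recovers_generating_parameters(self, glmm_design):
        # quick 6-seed smoke check; the full 50-seed recovery protocol lives
        # in the acceptance suite
        fits = [
            fit_olre_binomial(generate_glmm_data(BETA, 0.8, glmm_design, seed=s), 15)
            for s in range(6)
        ]
        mean_beta = np.mean([f.fixed_estimates for f in fits], axis=0)
        mean_sigma = np.mean([f.olre_sd for f in fits])
        assert mean_beta[1] == pytest.approx(BETA[1], rel=0.15)
        assert mean_beta[3] == pytest.approx(BETA[3], abs=2e-3)
        assert mean_sigma == pytest.approx(0.8, rel=0.2)

    def test_quadrature_node_stability(self, glmm_design):
        table = generate_glmm_data(BETA, 0.8, glmm_design, seed=5)
        f11 = fit_olre_binomial(table, quadrature_nodes=11)
        f31 = fit_olre_binomial(table, quadrature_nodes=31)
        np.testing.assert_allclose(f11.fixed_estimates, f31.fixed_estimates, atol=1e-4)
        assert f11.olre_sd == pytest.approx(f31.olre_sd, abs=1e-4)

    def test_matches_lme4_glmer(self, glmm_design, tmp_path):
        table = generate_glmm_data(BETA, 0.8, glmm_design, seed=11)
        csv = tmp_path / "glmm.csv"
        table.trials.to_csv(csv, index=False)
        script = f'''
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$obs <- factor(seq_len(nrow(d)))
        d$uniform <- as.integer(d$distribution == "uniform")
        m <- glmer(cbind(killed, density - killed) ~ density * uniform + (1 | obs),
                   data = d, family = binomial, nAGQ = 25)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), sep = "\\n")
        '''
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = np.array([float(v) for v in out.stdout.split()])
        fit = fit_olre_binomial(table, quadrature_nodes=25)
        np.testing.assert_allclose(fit.fixed_estimates, vals[:4], rtol=1e-3, atol=1e-5)
        assert fit.olre_sd == pytest.approx(vals[4], rel=1e-3)

    def test_invalid_inputs_rejected(self, glmm_design):
        table = generate_glmm_data(BETA, 0.3, glmm_design, seed=0)
        with pytest.raises(InvalidDesignError):
            fit_olre_binomial(table, quadrature_nodes=10)
        with pytest.raises(InvalidDesignError):
            fit_olre_binomial(table.subset(distribution="aggregate"), quadrature_nodes=15)


class TestWaldTable:
    def _fit(self, est, se):
        est, se = np.asarray(est, float), np.asarray(se, float)
        z = est / se
        from scipy import stats

        return GLMMFit(
            terms=("intercept", "density", "distribution", "density:distribution"),
            fixed_estimates=est,
            standard_errors=se,
            test_statistics=z,
            p_values=2 * stats.norm.sf(np.abs(z)),
            olre_sd=0.5,
            log_likelihood=-10.0,
            converged=True,
            boundary=False,
            n_obs=140,
            quadrature_nodes=15,
        )

    def test_zero_estimate_gives_zero_statistic_p_one(self):
        rows = wald_table(self._fit([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0]))
        assert rows[0]["t"] == 0.0
        assert rows[0]["p"] == 1.0

    def test_rows_follow_design_order(self):
        rows = wald_table(self._fit([0.1, 0.2, 0.3, 0.4], [1.0, 1.0, 1.0, 1.0]))
        assert [r["factor"] for r in rows] == [
            "intercept",
            "density",
            "distribution",
            "density:distribution",
        ]

    def test_p_monotone_decreasing_in_abs_statistic(self):
        rows = wald_table(self._fit([0.5, -1.0, 2.0, -4.0], [1.0, 1.0, 1.0, 1.0]))
        stats_abs = [abs(r["t"]) for r in rows]
        ps = [r["p"] for r in rows]
        order = np.argsort(stats_abs)
        assert all(ps[order[i]] >= ps[order[i + 1]] for i in range(len(order) - 1))
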
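# Methods

`funcresp` implements the statistical workflow used to compare type II
functional responses of aphid natural enemies (a coccinellid predator and an
aphidiine parasitoid attacking green peach aphid) across prey-distribution
treatments: response-type diagnosis, maximum-likelihood fitting of the
depletion-aware type II model, bootstrap confidence bands with a curve-overlap
comparison, and a binomial GLMM with an observation-level random effect.  This
note records the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## The random-predator model

A single forager searches an arena stocked with `N0` prey for a total
exposure `T`.  Search is random with instantaneous attack rate `a`; each
capture removes one prey (no replacement) and occupies the forager for a
handling time `Th`.  The expected kill `Ne` then satisfies Rogers'
random-predator equation

    Ne = N0 * (1 - exp(a*Th*Ne - a*T)),

an implicit equation whose unique root in `[0, N0]` has the closed form

    Ne = N0 - W0(a*Th*N0 * exp(-a*(T - Th*N0))) / (a*Th)

with `W0` the principal Lambert W branch.  The argument of `W0` is positive
for all valid parameters, so the branch choice is unambiguous.  Two
degenerate regimes bypass the closed form: `a = 0` gives `Ne = 0`, and
`Th = 0` (or an `a*Th*N0` product that underflows) gives the pure
random-search limit `Ne = N0*(1 - exp(-a*T))`.  Two further numerical guards
matter in the tails: when the `W0` argument overflows `exp`, the defining
relation `w + log w = y` is solved by Newton iteration on the log scale, and
when it underflows, the kill deficit `N0 - Ne` is evaluated directly in log
space via `W0(z) ~ z`.  A bracketed-bisection solver of the same equation is
kept as an independent oracle; the two agree to better than 1e-8 across the
tested parameter grid.

### Units

The model depends on its parameters only through the dimensionless products
`a*T` and `a*Th*N0`, so the solvers are unit-agnostic.  Following the
convention of standard functional-response fitting tools, estimates for the
emulated cage study are expressed **per exposure period** (`T = 1`, one 24-h
exposure): an attack rate of 1.59 means 1.59 arena-sweeps per 24 h, and a
handling time of 0.006 means 0.6% of the exposure per prey, i.e. a maximum
of about 167 prey per period — the saturation level visible in that study's
response curves.  This is the only scaling under which the published
estimates are internally consistent with their own saturation levels and
overlap thresholds; the package therefore treats the exposure period as the
time unit throughout its defaults.

## Synthetic experiments

`generate_trials` reproduces the emulated study design: densities
{4, 8, 16, 32, 64, 128, 256}, 10 replicate cages per treatment cell, one
exposure period, with each cell defined by its own `(a, Th)`.  Kill counts
are drawn as `Binomial(N0, Ne/N0)` — exactly the observation model the ML
fit assumes — so parameter-recovery tests are unconfounded by
misspecification.  Treatment cells differ only in `(a, Th)`; no spatial
patch geometry is simulated, because none of the downstream statistics use
it.  Each cell draws from its own child RNG stream (master seed plus a
stable hash of the cell labels), so adding or removing a cell never perturbs
the others.

Three deliberate departures of this generator from real cage data:

* **No overdispersion.**  Real cages show extra-binomial variation
  (individual foragers differ; that is why the study's GLMM carries an
  observation-level random effect).  Binomial noise therefore *understates*
  the real trial-to-trial variance, and every interval produced from
  simulated data is narrower than its real-data counterpart at the same
  design.  Passing recovery tests show the estimator chain is correct, not
  that real experiments of this size would pin the parameters this tightly.
* **No behavioral mechanism.**  A separate renewal-process simulator
  (`simulate_foraging_process`: exponential search times at rate `a*n`,
  fixed handling `Th`, prey depleted at each capture, clock stopped at `T`)
  provides a mechanistic cross-check — its mean tracks the Rogers root
  within a few percent — and serves as a misspecification stressor.
* **Type III data are manufactured**, not observed: `generate_type3_trials`
  substitutes a density-dependent attack rate `a(N0) = slope*N0`, which is
  sufficient to produce the rising kill proportion the classifier must
  detect, and nothing more.

`generate_glmm_data` draws logistic-normal binomial data
(`logit p = X*beta + u`, `u ~ N(0, sigma^2)` per trial) on an existing design
skeleton, mirroring the GLMM exactly.

## Response-type selection

Following the standard polynomial-logistic diagnosis, the kill proportion is
regressed on polynomial terms of `N0` with a logit link, fitted by in-house
IRLS to a deviance change below 1e-8 (columns are rescaled internally; raw
`N0^3` reaches 1.7e7).  A significant negative linear coefficient (Wald test
at `alpha = 0.05`) indicates type II; significant positive linear with a
significant negative next-order term indicates type III; anything else —
including non-convergence or separation — is reported as inconclusive
rather than raised.  The polynomial degree actually used by the original
analysis is not stated in that literature's tables; the default here is 2,
with 1 and 3 available, and the cubic option matching the classical
recommendation.  Wald p-values are the default (matching how linear-term
significance is conventionally tabulated); the fit object retains the
deviance so likelihood-ratio comparisons remain possible.

## Maximum-likelihood fitting

The likelihood treats each cage as `killed ~ Binomial(N0, Ne(N0)/N0)`.
Whether the original analysis used a binomial or approximate-normal
likelihood is not stated; binomial is the only choice consistent with the
discrete data and with the binomial GLMM fitted alongside, and is used
throughout.  The NLL is minimized over `(log a, log Th)` — positivity
without constraints — with kill probabilities clipped to
`[1e-12, 1 - 1e-12]` for boundary safety.  The kernel depends on the data
only through per-density totals of offered and killed prey, and the gradient
comes from implicit differentiation of the Rogers root, so one fit costs
about a millisecond.  Starting values come from disc-equation moments
(saturation level approximates `T/Th`; the lowest-density kill fraction
approximates `1 - exp(-a*T)`), followed by 10 log-uniform jittered restarts
(half-width 1 on the log scale, deterministic given the seed).  Standard
errors are Wald: central finite-difference Hessian on the log scale
(step 1e-4), inverted and mapped through the delta method; z and p values
are reported per parameter.  Fits with non-positive-definite curvature at
the optimum are flagged unconverged.

## Bootstrap bands and overlap comparison

The resampling unit is the whole cage: trials are resampled with
replacement (default `n = 2000`), each resample refitted with the original
estimates as starting values, and non-converged or degenerate resamples
(no kills, or a single distinct density) dropped and counted — more than
20% failures flags the result unstable.  Parameter intervals are 2.5%/97.5%
percentiles of the successful draws; BCa refinements are deliberately not
used, matching the conventional workflow in this literature.  Curve bands
evaluate every draw's predicted curve on a density grid and take pointwise
percentile quantiles.  Two treatments are compared on a shared unit-step
grid (integer densities, matching the integer thresholds conventionally
reported); grid points where the two 95% bands are disjoint are merged into
closed intervals.  No multiplicity correction is applied across grid points
— the comparison is deliberately the operational reading of "the bands
overlap here, so the responses are not distinguished here".

Because the synthetic generator is exactly binomial, its bands are
materially narrower than real-data bands (see above).  One practical
consequence, verified over independent seeds: simulated single-predator
aggregate-vs-uniform comparisons at the published parameter values produce
bands that are disjoint across the *entire* density range, whereas the real
study saw overlap at both extremes.  Reproducing that tri-phase pattern
requires the real data's extra-binomial noise, not just its point estimates.

## OLRE binomial GLMM

The model is `killed_i ~ Binomial(N0_i, p_i)` with
`logit(p_i) = x_i'beta + u_i`, `u_i ~ N(0, sigma^2)` independent per cage,
and `x_i = (1, density, I[uniform], density*I[uniform])`; the aggregate
treatment is the reference level and density enters in raw prey counts (a
centered/scaled variant is a one-line change on the design matrix).  With an
observation-level random intercept the marginal likelihood factorizes into
independent one-dimensional integrals, each computed by adaptive
Gauss–Hermite quadrature: damped Newton locates the conditional mode of each
integrand (strictly concave, so globally convergent), the curvature there
sets the scale, and an odd number of Hermite nodes (default 15) is laid over
the mode.  This was chosen over a Laplace-only approximation because it can
be validated against brute-force numerical integration, and it agrees with
that oracle to ~1e-10 per observation and with `lme4::glmer` (nAGQ = 25) to
~5e-6 on all parameters.  The likelihood is maximized over
`(beta, log sigma)` by L-BFGS-B, started at the plain-GLM fit with a
Pearson-dispersion-based sigma guess.

**Boundary handling.**  Under a true `sigma = 0`, the ML estimate of the
variance component is exactly zero only about half the time; the rest of the
time chance overdispersion leaves a small positive estimate.  The package
therefore collapses to the plain GLM (reporting `olre_sd = 0` with a
boundary flag) whenever the integrated likelihood fails to beat the GLM by
the 5% critical value of the boundary-corrected likelihood-ratio test
(`2*dLL < 2.7055`, the 95% point of the 50:50 chi-square mixture).  The rule
cleanly separates the regimes it matters for: simulated `sigma = 0` data
give `2*dLL <= 0.2`, while data at the study design with `sigma = 0.8` give
`2*dLL` in the hundreds.  Wald statistics for the fixed effects come from
the finite-difference Hessian over `(beta, log sigma)`; they are
asymptotically standard normal, and the report column is labeled `t` only to
match the conventional presentation of mixed-model coefficient tables.

## Problem sizes and determinism

Default analysis sizes follow the emulated study: 70 trials per cell,
`n_boot = 2000`, unit density grid.  The validation suite scales simulations
to what each question needs: 20 seeds for parameter-recovery means, 200
simulations for classification rates and bootstrap coverage (with
`n_boot = 500` for the coverage study), 50 seeds for GLMM recovery, and
10,000 runs for renewal-simulator means.  Every random stage takes an
explicit integer seed; per-cell child streams are derived by stable hashing,
and a fixed seed makes full pipeline reports byte-identical.

## Known limitations

* Single-forager model only: paired-enemy treatments are analyzed per enemy
  with their own parameters; no interference (Beddington–DeAngelis) or
  intraguild-predation term is fitted.
* Type III responses are diagnosed but not fitted; the ML stage is type II
  only.
* Percentile intervals can undercover slightly at `n = 70` (the coverage
  study sits near 92–93% for a nominal 95%); bootstrap-t or BCa would
  improve this at the cost of departing from the conventional workflow.
* The GLMM supports exactly one random-effect structure (observation-level
  intercept) and one family (binomial); nested or crossed designs are out of
  scope.
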
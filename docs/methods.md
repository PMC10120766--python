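# Methods

## Models

`trajmix` fits nonlinear mixed-effects models for a continuous longitudinal
outcome `y_ij` of subject `i` at time `t_ij`,

    y_ij = f(t_ij, psi_i) + e_ij,     e_ij ~ N(0, sigma^2),

with subject-specific structural parameters linked to population fixed
effects, subject-constant covariates and Gaussian random effects,

    psi_ik = alpha_k + beta_k' X_ki + eta_ik,    eta_i ~ MVN(0, B).

Three structural mean functions are implemented.

**Model 1 — sigmoidal (four-parameter logistic).** On the positive
time-before-zero scale `s` (for retrospective data aligned at death, `s = -t`),

    f(s) = initial + (last - initial) / (1 + (s / midpoint)^hill).

`last` is the outcome level at the alignment point (s = 0), `initial` the
asymptotic level long before it, `midpoint > 0` the time of half decline,
and `hill > 0` the shape (steepness/asymmetry) of the decline. Random
effects sit on the two level parameters only (B is a full 2x2 block); the
midpoint and Hill slope are kept marginal, which stabilises estimation of a
parameter pair that is only weakly identified per subject. Input times of
any sign are mapped internally to `s >= 0` (negative times are negated; a
mixed-sign axis is shifted by `max(t)`, reported as `time_shift`), so the
midpoint is always reported in positive time-before-zero units.

**Model 2 — piecewise linear, abrupt changepoint (broken stick).** On the raw
timescale,

    f(t) = intercept + slope2 * t                                 for t >= cp
    f(t) = intercept + slope2 * cp + slope1 * (t - cp)            for t <  cp

`intercept` is the level at t = 0; `slope2` is the slope of the segment
containing t = 0 (the terminal slope for retrospective data); `slope1` the
slope of the other segment; `cp` the subject-specific changepoint. The
naming fixes a genuine ambiguity: "slope1" is always the slope of the
segment *away from* time zero (the early slope), "slope2" the slope
*adjacent to* time zero, regardless of the sign convention of the timescale.
All four parameters carry random effects; B is diagonal except for the
(slope1, slope2) covariance.

**Model 3 — piecewise linear with smooth cubic transition.** The two lines
of model 2 are joined by a cubic `g(t)` on the window `[cp, cp + v]`; `cp`
is the *onset* of the transition. The cubic is the unique solution of the
4x4 linear system pinning `g` and `g'` at both window edges to the two
lines, under the constraint

    lambda = intercept + (slope2 - slope1)(cp + v/2),

which makes the extended lines intersect at the middle of the window, so
the model reduces exactly to model 2 as `v -> 0`. Two consequences worth
noting: the constrained "cubic" always has a vanishing cubic coefficient
(the boundary data are compatible with a quadratic), and the curve clears
the corner of the broken stick by `(slope2 - slope1) * v / 8` at the window
midpoint — it cannot pass through the corner and stay C1. The window length
`v` defaults to 2.0 timescale units and is user-settable; it is a modelling
choice, not an estimated parameter.

## Estimation: SAEM

Maximum-likelihood estimation uses the Stochastic Approximation EM
algorithm. Each iteration:

1. **Simulation step.** For each subject (and each of L parallel chains),
   the random-effect vector is updated by one Metropolis-Hastings sweep of
   three kernels targeting `p(eta_i | y_i; theta)`: an independence proposal
   from the prior `MVN(0, B)`, a componentwise random walk, and a joint
   random walk along the Cholesky factor of B. Random-walk scales are
   *per subject and per component*, adapted toward a 0.35 acceptance rate
   during burn-in only. Per-subject scales matter here: the conditional for
   a changepoint effect is sharp when the changepoint falls inside a
   subject's follow-up and nearly as wide as the prior when it does not, so
   no single scale serves both groups.
2. **Stochastic approximation.** Complete-data sufficient statistics
   (per-subject parameter draws, their second moments, the residual sum of
   squares) are averaged over chains and smoothed with step `gamma_k = 1`
   during the K1 burn-in iterations and `(k - K1)^(-a)` afterwards,
   `a = 1` by default (`a` must lie in (0.5, 1]).
3. **M-step.** Fixed effects of random parameters: closed-form GLS of the
   smoothed subject parameters on the covariate designs, weighted by
   `B^{-1}`. `B`: smoothed second moments, masked to the model's sparsity
   and projected block-wise to positive semi-definite (eigenvalue floor
   1e-12) if an update leaves the cone; a projection is recorded as a fit
   warning. `sigma^2`: smoothed residual sum of squares over the
   observation count, floored at 1e-10. Parameters without random effects
   (the sigmoid midpoint and Hill slope, with their covariate
   coefficients): one damped Gauss-Newton step per iteration on the
   complete-data residual sum of squares, with step halving (up to 5) if
   the step does not decrease it; the step is scaled by `gamma_k` during
   the SA phase.

**Simulated annealing.** During the first half of burn-in, variance
parameters (diagonal of B, and `sigma^2`) may grow freely but can shrink by
at most a factor 0.97 per iteration. This keeps the likelihood flat early
so the mean parameters explore globally before the fit sharpens; without
it, piecewise fits settle in a local attractor where inflated slope
variances absorb a misplaced population changepoint, and the
noise-free limit freezes mean parameters at their initial values as soon
as the variances collapse. Diagonal scaling is applied as a congruence
transform, so the annealed B stays positive semi-definite.

**Defaults.** K1 = 800 burn-in and K2 = 400 SA iterations,
`ceil(400 / N)` chains (so small samples still yield stable statistics),
one MH sweep per iteration. The schedule is deliberately long: the
per-iteration update of a parameter is `gamma_k` times the Monte-Carlo
fluctuation of its sufficient statistic, and the schedule must run until
those updates fall below the convergence tolerance. A fit of n = 200
subjects (about 2,200 observations) takes a few seconds on one core.

**Convergence flag.** The fit is declared converged when every
per-iteration relative parameter change over the trailing 50 SA iterations
is below 1e-3 and all estimates are finite. Relative scale: `|theta|`
floored at 0.1; covariance entries are measured on the correlation scale
`sqrt(B_ii B_jj)`, since a covariance near zero has no scale of its own.
The per-iteration reading (rather than total drift across the window) is
the one consistent with Robbins-Monro averaging: step sizes contract like
`gamma_k` once the chain stops drifting, while total window drift is
dominated by Monte-Carlo noise that decays only as the window position
grows and would require an impractically long schedule to clear the same
tolerance.

**Standard errors.** Reported SEs come from the classical *linearized*
Fisher information: the structural model is linearized around each
subject's empirical-Bayes random-effect estimate, giving the marginal
normal model `V_i = Z_i B Z_i' + sigma^2 I`; fixed-effect information is
`sum_i A_i' V_i^{-1} A_i` and variance-parameter information is
`0.5 tr(V^{-1} dV_a V^{-1} dV_b)` (the blocks are orthogonal under
normality). A singular block yields missing SEs with a warning — never
fabricated values. This choice is deliberate: a Louis-identity stochastic
approximation of the observed information is implemented
(`estimate_standard_errors`, numerical score/Hessian in a log-variance
parametrisation, averaged over stored SA-phase draws), but for these
models the missing-information fraction is around 0.98, so the observed
information is the small difference of two huge Monte-Carlo expectations;
at any draw count a fit can afford, the Louis estimate oscillates between
non-positive-definite and substantially over-tight (checked against the
exact information of a linear mixed model). The linearized FIM is exact in
that linear special case and is the standard report for nonlinear
mixed models of this kind. CV% = 100 SE / |estimate|; Wald p-values
`2(1 - Phi(|est|/SE))` are provided for *all* fixed effects, main
parameters included.

**Marginal log-likelihood.** Importance sampling per subject with a
Gaussian proposal built from conditional MH draws at the fixed estimates
(mean and 1.5x-inflated covariance of the draws). Proposals derived from
draw moments are robust to the kinked likelihood surfaces of the piecewise
models, where Laplace/Hessian proposals fail at non-smooth points.
Components of B with numerically zero variance are pinned at zero; if all
are degenerate the integral collapses to the closed-form Gaussian residual
log-likelihood. The estimator returns its own Monte-Carlo SE (delta method
on normalised weights). AIC = -2 logL + 2p and BIC = -2 logL + log(N) p
count p = all fixed effects + free entries of B + sigma^2, with N the
number of subjects.

## Automated initial values

*Sigmoid.* Level starts are band means of the outcome: observations whose
time-before-zero percentile rank lies within +/-2.5 of the 5th (last level)
and 95th (initial level) percentile. The midpoint start is 300 when the
pooled trend is "nearly linear" — pooled OLS R^2 >= 0.99, or the mid-band
mean within 5% of the level range from the chord through the extreme band
means — and 2 otherwise; a distant midpoint makes the logistic locally
linear, so a linear-looking sample is started there. The Hill start is
whichever of {0.5, 1.05} gives the smaller pooled residual sum of squares
(ties keep 1.05). All thresholds are overridable arguments.

*Piecewise.* The intercept start is the band mean at the 95th time
percentile. The time axis is cut at the 20/40/60/80th percentiles; a slope
is estimated in each band; the changepoint start is the lower bound of the
band with the largest absolute slope, slope ties resolved to the earliest
tied band (the changepoint is where the fast phase *begins*) excluding the
first band unless it is the only candidate, and the result is kept strictly
inside the observed time range. Slope starts are the pooled trends on the
data before and after that approximate changepoint. Empty or degenerate
quintile bands trigger a tertile fallback with a warning.

Band and segment slopes are *within-subject* (demeaned) OLS estimates
pooled across subjects, i.e. the fixed-effects estimator. A naive pooled
trend is dominated by between-subject level variance (the bundled piecewise
scenario has a level SD of 1.7 against a residual SD of 0.28) and
mislocates the changepoint by tens of percentile ranks; demeaning recovers
the slope a random-intercept mixed model would estimate at a fraction of
the cost.

Variance seeds are method-of-moments: with v the variance of the residuals
around the structural curve at the starting values, `sigma^2` and level
random effects start at v/2, slope random effects at 0.1 v / var(t), and a
changepoint random effect at var(t) — the observed time spread is the
natural prior scale for a changepoint location. User-supplied `start`
vectors bypass the heuristics verbatim (order checked per model; a sigmoid
start must have a positive midpoint).

## Synthetic data

The simulator emulates retrospective decedent cohorts with annual visits:
per-subject follow-up drawn from a normal (SD 5) truncated to [4, 24]
years, whose location is calibrated so the *observed* mean follow-up (the
floor of the span, since visits sit on the annual grid 0..floor(span))
equals the stated target; visits at integer years before death, each
jittered uniformly within +/-2 months and clipped to [-24, 0]; at least 4
observations per subject.

Two stock generative scenarios drive validation. Sigmoid: last level
-1.03, initial level 0.37, midpoint 4.0 (positive time-before-death scale),
Hill slope 1.69; level random-effect SDs 1.46 and 0.51, uncorrelated;
residual SD 0.28. Piecewise: intercept -1.21, early slope -0.03, terminal
slope -0.32, changepoint -3 years; random-effect SDs 1.70, 0.01, 0.05 and
6.91 with correlation -0.07 between the two slopes; residual SD 0.28.
Optional covariates are standard normal with coefficient 0.1 on every
parameter. The demo cohort (`make_example_dataset`) is a synthetic
stand-in: 1200 decedents, mean follow-up 7 years (SD 5), piecewise decline
with age at death (N(90, 6), truncated to [65, 108]) linked negatively to
the last level (-0.02 per year) and the changepoint (-0.05 per year).

What the simulator does *not* emulate — and hence what passing tests do not
establish about real cohort data: informative dropout and mortality
selection beyond the death alignment itself, practice/retest effects,
floor and ceiling effects of cognitive composites, non-Gaussian or
heteroscedastic residuals, time-varying covariates, and measurement
batch effects.

The piecewise scenario's changepoint dispersion (SD 6.91 years around a
mean of -3) deserves a flag: it places roughly a third of subjects'
changepoints after the alignment point and another large share before
their observation window, so the population changepoint is weakly
identified and recovery of `alpha_changepoint` at n = 200 shows visible
Monte-Carlo scatter. The scenario is kept as specified; the validation
study measures recovery under exactly these conditions.

## Validation studies and problem sizes

The package's own replicated study (also what `scripts/acceptance.py` and
the heavy tests run) uses 20 replicate datasets per scenario: n = 100
subjects per dataset for the convergence-rate and trajectory-MSE study
(all three models, automated initials), and n = 200 for parameter
recovery (models 1 and 2), with recovery assessed as the replicate mean
against the generative value within 3 Monte-Carlo standard errors.
Trajectory error is the MSE between the replicate-averaged fitted marginal
trajectory and the generative population curve on the annual grid
[-24, 0].

## Numerical choices and degenerate inputs

- Structural-domain guards: the sigmoid midpoint is floored at 1e-6 and the
  Hill slope at 1e-3 per subject; a non-positive user midpoint is a
  configuration error.
- `sigma^2` floor 1e-10, variance floor 1e-12 (keeps MH targets proper).
- `ParameterLink` accepts `sigma = 0` as the noise-free simulation limit;
  the engine never produces it.
- Listwise deletion of rows missing id/time/outcome, with logged counts;
  duplicate (subject, time) rows are retained and flagged; time-varying
  covariates are rejected.
- Warnings: small sample below 50 subjects; total fixed-effect count above
  N/10; both thresholds overridable.
- Percentiles everywhere use the linear-interpolation (type-7) convention.
- "Most common covariate profile" for marginal trajectories: mode for
  covariates with at most 10 distinct values, median otherwise.
- Reproducibility: every stochastic routine takes an explicit seed;
  a seeded fit is bit-reproducible run to run.

## Known limitations

- Gaussian residuals with a single variance; no autocorrelation, no
  heteroscedasticity, no non-Gaussian outcomes.
- Random-effect structures are fixed per model (levels-only for the
  sigmoid; diagonal + slope covariance for the piecewise models).
- The smooth model's window length v is fixed by the user, not estimated.
- Louis standard errors use numerical derivatives; for the smooth model the
  structural Jacobian is itself numerical, so SEs there carry extra
  differencing error.
- Model 3 is several times slower than model 2 (batched 4x4 solves for the
  transition cubic inside every MH proposal).
- No Bacon-Watts transition, no >2-phase trajectories, no 5-parameter
  logistic, no wide-format input, no date parsing.
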
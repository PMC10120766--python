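# trajmix

Sigmoidal and random-changepoint mixed models for longitudinal outcomes,
estimated by SAEM.

Many longitudinal processes are not linear in time: late-life cognition
declines gently for years and then accelerates sharply in the years before
death; dose-response curves, growth curves and adoption curves show the
same "two regimes" or saturating shapes. `trajmix` fits three interpretable
nonlinear mixed-effects models to long-format repeated-measures data, with
covariates allowed on **all four** structural parameters, automated
data-driven starting values, and one-line fitting with annotated output:

1. **SMM** — sigmoidal (four-parameter logistic) mixed model on the
   time-before-zero scale `s`:
   `f(s) = psi_init + (psi_last - psi_init) / (1 + (s/psi_mid)^psi_hill)`,
   random effects on the two levels;
2. **PMM-abrupt** — broken-stick model with a subject-specific random
   changepoint: intercept at time 0, early slope, terminal slope,
   changepoint, all with random effects (B diagonal except the
   slope1-slope2 covariance);
3. **PMM-smooth** — the broken stick with a cubic C1 transition window of
   length `v` starting at the changepoint; `v = 0` reduces exactly to the
   abrupt model.

Estimation is a from-scratch Stochastic Approximation EM (SAEM):
Metropolis-Hastings simulation of the subject random effects,
Robbins-Monro smoothing of the complete-data sufficient statistics,
closed-form M-steps, a simulated-annealing variance phase, Louis-identity
standard errors, importance-sampling marginal log-likelihood, and Wald
p-values for every fixed effect (main parameters included). A bundled
simulator generates decedent-cohort-style datasets (annual visits jittered
within +/-2 months, truncated-normal follow-up, at least 4 visits) for
testing and validation. See `docs/methods.md` for the full model and
algorithm account.

Intended users: biostatisticians and quantitative aging researchers who
want changepoint/sigmoid trajectory models without writing structural
models, initial values and covariance structures by hand.

## Worked example

Fit the abrupt changepoint model to the bundled synthetic demo cohort
(1200 decedents, annual cognition scores, age at death as a covariate on
all four parameters):

```python
import trajmix

data = trajmix.make_example_dataset(seed=123)
data = trajmix.derive_centered_covariate(data, "ageDeath", 90, "ageDeath90")

spec = trajmix.ModelSpec(model_id=2, predictors=(("ageDeath90",),) * 4)
res = trajmix.fit(data, spec, trajmix.SAEMSettings(seed=1))
print(trajmix.render_summary(res))
```

Key lines of the output (abridged):

```
Fixed effects
Parameter                             Estimate          SE   CV(%)     p-value
alpha.last.level                       -1.1854    0.030497     2.6           0
beta.ageDeath90(last.level)          -0.025293   0.0050837    20.1   6.514e-07
alpha.slope1                         -0.029043   0.0022953     7.9   1.071e-36
alpha.slope2                          -0.32871    0.007089     2.2           0
alpha.changepoint                      -2.9057    0.044924     1.5           0
beta.ageDeath90(changepoint)         -0.063303   0.0074757    11.8   2.499e-17

Variance of random effects
Parameter                             Estimate          SE   CV(%)
omega2.last.level                       1.0544    0.044845     4.3
omega2.slope1                        8.083e-04   1.553e-04    19.2
cov.slope1.slope2                    0.0035162   4.975e-04    14.1
omega2.slope2                         0.033538   0.0020799     6.2
omega2.changepoint                     0.73721    0.073586    10.0

Statistical criteria
  Log-likelihood (importance sampling): -5503.7
  AIC: 11035   BIC: 11107
  Convergence: yes (max relative change 0.00024 over trailing window)

The program took 5.81 seconds
```

Reading it: close to death the cohort declines at -0.33 units/year versus
-0.029 units/year earlier, the switch occurring on average 2.9 years before
death; each extra year of age at death lowers the terminal cognitive level
by 0.025 units (p = 7e-7) and moves the onset of accelerated decline 0.063
years earlier (p = 2e-17), while neither slope is credibly age-related.
CV(%) is 100 SE/|estimate|. The same model is a
one-liner from the shell, including a spaghetti plot and marginal
trajectory plots contrasted at the 10th/90th percentile of a covariate:

```sh
trajmix fit --model 2 --dataset demo.csv --id ID --outcome cognition \
    --time time --predictor-all ageDeath90 --traj-marg \
    --traj-marg-group ageDeath90 --output-dir out/
```

`trajmix simulate` writes synthetic datasets from a scenario file, and
`trajmix benchmark` runs the replicated simulation study.

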
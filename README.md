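# sinesurv

Fully parametric proportional-hazards (PH) survival regression with **Sine-G
baseline hazards**, for biostatisticians modelling right-censored
time-to-event data (clinical trials, cohort studies) whose hazard shapes —
increasing, decreasing, unimodal, bathtub — outrun the classical parametric
baselines.

## The model

The Sine-G construction wraps any baseline lifetime CDF G(t; θ) into

    F_sin(t; θ) = sin( (π/2) · G(t; θ) ),

adding **no new parameters** while reshaping the hazard geometry.  Five
baselines are provided, each with positive scale λ (and shape α where
applicable): exponential, Weibull `1 − exp(−(λt)^α)`, Lomax
`1 − (1+λt)^{−α}`, exponentiated exponential `(1 − e^{−λt})^α`, and
Gompertz `1 − exp(−α(e^{λt} − 1))`.

Covariates enter proportionally, without an intercept (identifiability):

    h(t | x) = h₀(t; θ) · exp(x'β),     H(t | x) = H₀(t; θ) · exp(x'β),

and the right-censored log-likelihood for observations (tᵢ, δᵢ, xᵢ) is

    ℓ(θ, β) = Σᵢ δᵢ [log h₀(tᵢ; θ) + xᵢ'β] − Σᵢ H₀(tᵢ; θ) exp(xᵢ'β).

Estimation is by maximum likelihood (BFGS on the unconstrained scale,
observed-information standard errors) or Bayesian MCMC (Hamiltonian Monte
Carlo with leapfrog integration and a Metropolis acceptance step;
Gamma(10, 10) priors on λ, α and Normal(0, 10²) priors on β).  Convergence
is monitored with split R-hat, effective sample size and Monte-Carlo SE.
Competing baselines are ranked by **WAIC** `= −2(lppd − p_WAIC)` and
**LOOIC** `= −2·elpd_loo` (importance-sampling leave-one-out with a Pareto
tail diagnostic); lower is better.

Lifetimes are simulated by inverting the cumulative hazard:
`T = H₀⁻¹(−log(1−U) · e^{−x'β})` with U ~ Uniform(0, 1).

## Worked example

```python
import sinesurv as sv

# a synthetic 90-patient two-arm trial with a known sine-Weibull truth
dataset, truth = sv.generate_synthetic_trial("gastric-like", seed=3)
print(truth["lam"], truth["alpha"], truth["beta"])   # 0.34 0.95 [-0.06]

model = sv.SineGPH.from_dataset(dataset, family="weibull")
fit = model.fit_bayes(mcmc=sv.McmcConfig(chains=4, iterations=1200,
                                         warmup=600, seed=11))
print(fit.summary().round(3))
```

Output (posterior summary, Table-style schema):

```
                Estimate     SE     SD   2.5%  Medium  97.5%    N_eff   Rhat
lam                0.413  0.002  0.054  0.310   0.411  0.527  550.257  1.006
alpha              1.005  0.003  0.083  0.852   1.004  1.164  841.653  1.007
beta_treatment    -0.350  0.009  0.210 -0.751  -0.352  0.072  577.608  1.003
```

`Estimate` is the posterior mean, `SE` the Monte-Carlo standard error, the
quantile columns give a 95% credible interval, and `N_eff`/`Rhat` are the
convergence diagnostics (here R-hat ≤ 1.01 and N_eff > 400, so the chains
have mixed).  The generating values (λ=0.34, α=0.95, β=−0.06) sit inside
the credible intervals.  Model comparison:

```python
print(fit.waic(), fit.looic())   # 263.96 264.16 — lower is better
```

A command-line interface mirrors the library:

```bash
sinesurv simulate --preset gastric-like --seed 3 --out trial.csv
sinesurv fit --data trial.csv --family weibull --method bayes --seed 11 \
         --out fit.json --loglik-out ll_sw.csv
sinesurv compare --model sw=ll_sw.csv --model sl=ll_sl.csv --out ranking.csv
sinesurv ttt --data trial.csv --events-only --out ttt.csv
```

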
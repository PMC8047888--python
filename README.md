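# removalopt

Spatially explicit Bayesian modelling of invasive-species **removal
records** (catch counts + trap effort) and **optimal spatial allocation of
capture effort**.

Long-running control programs — the motivating case is snapping-turtle
removal along a branching river system — accumulate years of per-section
capture and trap-day records.  `removalopt` turns those routine records
into management decisions:

1. estimate the population dynamics (growth, density dependence,
   removal-effort effect, environmental effects, spatial structure) with a
   state-space model that handles observation error and missing
   unit-years;
2. allocate a fixed total trapping effort across river sections so the
   whole-area equilibrium population density is minimized;
3. simulate forward to ask how many years until the management target
   (e.g. catch-per-unit-effort below 0.03) is reached.

It is intended for quantitative ecologists and wildlife-management
analysts; everything is driven from plain CSV files or the Python API.

## Model

The log relative density `mu[i,t]` (log expected CPUE of unit `i` in year
`t`) follows a Gompertz autoregression with spatial structure, and
captures are Poisson in effort:

    C[i,t]    ~ Poisson(E[i,t] exp(mu[i,t]))
    mu[i,t+1] = alpha + lambda mu[i,t] + sum_k beta_k H[k,i]
                + beta6 E[i,t]/100 + rho_i + omega_t + e[i,t]
    rho       ~ proper CAR(gamma, sigma_rho^2) on the river graph
    omega_t   ~ N(0, sigma_omega^2),   e[i,t] ~ N(0, sigma_e^2)
    mu[i,1]   ~ N(0, sigma_1^2)

Fitting is by MCMC (a built-in Metropolis-within-Gibbs sampler, 4 chains
by default) with split R-hat convergence checks and posterior-predictive
Bayesian P-values.  For `|lambda| < 1` each posterior draw implies
per-unit equilibrium densities; the management objective

    U(E) = mean over draws of sum_i 100 exp(mu*_i(E_i)),
    mu*_i = (alpha + sum_k beta_k H_ki + beta6 E_i/100 + rho_i)/(1 - lambda)

is minimized over allocations `sum_i E_i = E_total` by simulated
annealing on a softmax reparameterization, with a greedy heuristic and an
exact KKT water-filling solver as cross-checks.  See `docs/methods.md`
for the full account.

## Worked example

```python
import numpy as np
import removalopt as ro

# 1. synthetic removal study: 75 river sections, 9 trapping seasons
sim = ro.generate_dataset(seed=42)
ds = sim.dataset

# 2. fit the spatial Gompertz state-space model
samples = ro.fit_mcmc(ds, ro.MCMCConfig(n_chains=4, iterations=2000,
                                        warmup=1000, thin=4, seed=7))

# 3. optimize the spatial allocation of the current total effort
base = ro.Allocation.from_effort(np.nanmean(ds.effort, axis=1))
rows = ro.scenario_table(samples, base, [1, 4], network=ds.network,
                         sa_config=ro.SAConfig(n_steps=20_000, seed=3))

# 4. will the optimal 4x allocation reach the target CPUE < 0.03?
ens = ro.forward_simulate(samples, ds.network, rows[1].optimal_allocation,
                          horizon=20, seed=5)
_, median_years, frac = ro.time_to_threshold(ens, threshold=0.03)
```

This prints (formatting elided):

```
units=75 years=9 missing unit-years=65
alpha  posterior mean   2.061 (95% CI   1.831,   2.273)
lambda posterior mean  -0.159 (95% CI  -0.175,  -0.143)
beta6  posterior mean  -0.263 (95% CI  -0.267,  -0.259)
worst split R-hat: 1.046
x1: U_uniform=  489.99 U_actual=  487.52 U_optimal=  450.55 improvement vs actual  7.58%
x4: U_uniform=    0.00 U_actual=    0.00 U_optimal=    0.00 improvement vs actual 29.39%
median years to CPUE < 0.03 under optimal 4x effort: 1 (reached in 100% of draws)
```

Reading the output: the generating values (`alpha=1.9, lambda=-0.16,
beta6=-0.26`) are recovered inside tight credible intervals; negative
`lambda` means strong density-dependent regulation, and negative `beta6`
means trapping suppresses the growth rate.  `U` is the posterior-mean
summed equilibrium density (per 100 trap-days): at the current total
effort, spatially optimizing the same budget lowers it by ~8% relative to
the historical pattern, while at 4x the budget the population is driven
essentially to zero and the target CPUE is met within a single year —
the fast response follows from the high growth rate combined with strong
density dependence.

The same workflow is available from the shell:

```sh
removalopt simulate-data --n-units 75 --n-years 9 --seed 1 --out-dir study/
removalopt fit --removal study/removals.csv --covariates study/covariates.csv \
    --adjacency study/adjacency.csv --seed 2 --out study/posterior.csv
removalopt diagnose ... ; removalopt optimize ... ; removalopt scenarios ... ;
removalopt forecast ...
```

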
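# Methods

`removalopt` estimates the population dynamics of an invasive species from
routine removal records (captures and trap effort on the spatial units of a
river network) and uses the fitted model to allocate a fixed total capture
effort across units so that the whole-area equilibrium population density is
minimized.

## The state-space model

Let `mu[i,t]` be the log relative density of unit `i` in year `t`: the log
of the expected catch per trap-day (CPUE), assumed proportional to true
density.  The observation process is Poisson,

    C[i,t] ~ Poisson(E[i,t] * exp(mu[i,t]))

with `E[i,t]` the effort in trap-days.  Unit-years without any trapping
record are treated as missing observations: the latent density still
evolves, but no observation term enters the likelihood.  A recorded zero
effort forces zero captures and likewise carries no information.

The state process is a stochastic Gompertz (log-linear autoregressive)
model:

    mu[i,t+1] = alpha + lambda * mu[i,t] + sum_k beta_k H[k,i]
                + beta6 * E[i,t]/100 + rho_i + omega_t + e[i,t]

* `alpha` — intercept (log growth rate at zero log density).
* `lambda` — density dependence; `|lambda| < 1` implies convergence to an
  equilibrium, `lambda = 1` no regulation.
* `beta_1..beta_5` — effects of five standardized environmental covariates
  (mean 0, SD 1, so each coefficient is the change in log growth rate per
  +1 SD).
* `beta6` — removal-effort effect per 100 trap-days.  Effort is stored in
  raw trap-days everywhere; the division by 100 happens at this single
  site.  In unit-years without trapping the effort term is zero.
* `omega_t ~ N(0, sigma_omega^2)` — year effect shared by all units;
  `e[i,t] ~ N(0, sigma_e^2)` — unit-year process noise.
* `rho_i` — spatially structured variation in growth rate, a proper CAR
  field on the river adjacency graph: conditionals
  `N(gamma * mean of neighbours * k_i scaling, sigma_rho^2 / k_i)`, joint
  precision `(D - gamma W)/sigma_rho^2`.  `gamma in (0,1)` keeps the
  precision positive definite on a connected graph; units with no
  neighbours are rejected at load time because the conditional divides by
  `k_i`.
* `mu[i,1] ~ N(0, sigma_1^2)` — initial state.

Priors: flat on `alpha, lambda, beta_k, beta6`; flat-positive on
`sigma_e, sigma_rho`; half-normal with scale 10 on `sigma_omega` and
`sigma_1` (we place the weakly informative half-normal on the standard
deviation, the common parameterization); Uniform(0,1) on `gamma`.
`lambda` is deliberately *not* constrained to (-1,1) during fitting —
finding its posterior inside that interval is a result, not an assumption.
Equilibrium computations exclude (and count) any draw with `|lambda| >= 1`.

## Posterior computation

The sampler is a purpose-built Metropolis-within-Gibbs scheme written
against this model's conditional structure:

* `(alpha, lambda, beta, beta6)` is a conjugate Gaussian block given the
  latent states (a linear regression across all transitions).
* `rho` is jointly Gaussian given everything else (CAR prior precision
  plus a diagonal likelihood precision); one dense Cholesky per iteration.
* `omega` has independent Gaussian conditionals.
* The latent matrix `mu` is updated by vectorized random-walk Metropolis
  on alternating even/odd year slices (each cell interacts only with its
  temporal neighbours, so the two-colour sweep is a valid blocked update).
  Per-cell step sizes adapt toward 44% acceptance during warmup only.
* `sigma_e, sigma_omega, sigma_1, sigma_rho` are slice-sampled on log
  scale; `gamma` is slice-sampled in (0,1) with the CAR log-determinant
  evaluated from precomputed eigenvalues of `D^{-1/2} W D^{-1/2}`.
* Because `alpha` is nearly confounded with the means of `rho` and
  `omega`, two ancillary translation moves shift mass between them
  (symmetric Gaussian proposals accepted on the prior ratio), which
  removes the main slow direction of the posterior.

The default run follows the standard configuration for this model: 4
chains, 10,000 iterations, 5,000 warmup, thinning 4 — 5,000 retained
draws.  Convergence is summarized by split R-hat per scalar parameter
with the usual `R-hat < 1.1` criterion; failure raises a warning flag,
never an error.  Model adequacy is checked with posterior-predictive
Bayesian P-values of annual total captures (ties counted half; values
near 0/1 flag misfit), and the contribution of measured covariates to
spatial heterogeneity is summarized by
`delta = Var_i(H beta) / (Var_i(H beta) + Var_i(rho))` per draw.

## Equilibrium objective and optimization

For `|lambda| < 1` the noise-free recursion has the per-unit fixed point

    mu*_i = (alpha + sum_k beta_k H_ki + beta6 E_i/100 + rho_i) / (1 - lambda)

Exactly this deterministic fixed point is used (no lognormal variance
correction).  The reported objective is
`K(E) = sum_i 100 exp(mu*_i)` (a per-100-trap-day scale) averaged over
retained draws: `U(E) = mean_n K_n(E)`.  The whole-area mean relative
density is `U/(100 I)`, compared against the management target CPUE
(default 0.03) with a strict inequality.

`U` is a posterior mean of sums of exponentials of affine functions of
`E`, hence convex and (for `beta6 < 0`) strictly decreasing in every
coordinate.  Three optimizers are provided:

* **Simulated annealing** on the softmax reparameterization: `I-1`
  unbounded auxiliaries map to a strictly positive allocation summing to
  the budget exactly (last unit takes the remainder).  Plain exponential
  cooling (T0 = 1.0, x0.995 per sweep), single-coordinate Gaussian
  proposals (SD 0.5), initialized at the greedy solution, 50,000 proposal
  steps by default.  Convexity makes the result insensitive to the
  schedule; the scenario table additionally never reports an "optimum"
  worse than the scaled reference pattern.
* **Greedy**: repeatedly assigns one increment (default `E_total/1000`)
  to the unit with the highest current posterior-mean equilibrium
  density; deterministic, ties to the lowest index.
* **KKT water-filling**: the exact global optimum of this separable
  convex program, found by equalizing marginal derivatives on the active
  set via nested bisection.  It exists as an independent oracle; tests
  require SA and greedy to land within 1% relative objective of it.

Per-draw coefficients (`log c_{i,n}` and `b_n = beta6_n/(100(1-lambda_n))`)
are precomputed, so one objective evaluation is a single
`(n_draws x I)` exp-sum.

## Forward simulation

Management scenarios are screened by simulating the process model forward
under a fixed allocation: each posterior draw starts from its own
final-year latent state and iterates the recursion with fresh
`omega_t` (shared within a year) and `e[i,t]` noise at that draw's
variance parameters.  Defaults: horizon 20 years, target CPUE 0.03.  The
time-to-target is the first year whose whole-area mean relative density
falls below the target, reported per draw with the ensemble median and
the fraction of draws that ever cross.

## Synthetic data generator

The generator produces studies with exactly the statistical structure the
model assumes, at conditions emulating the motivating snapping-turtle
removal program:

* 75 river sections over 9 annual seasons; the adjacency graph is a
  random chain-with-branches tree (200-m river sections form a
  near-linear network; `branching` controls the rate of confluences,
  default 0.15).
* Covariates iid standard normal, re-standardized so tests can assert
  exact mean-0/SD-1.
* Generating parameters default to `alpha=1.9, lambda=-0.16,
  beta6=-0.26, sigma_e=0.3, sigma_omega=0.2, sigma_rho=0.5, gamma=0.5,
  sigma_1=1.0`, with modest covariate effects.
* Effort per trapped unit-year is lognormal with median 2,000 trap-days
  (SD 0.15 on log scale): at these parameter values that puts the
  continuously trapped sections at an equilibrium CPUE of a few times
  10^-2 — the regime of a long-running control program — while the
  carrying capacity (zero effort) is about 5 CPUE.  About one unit-year
  in ten is missing (no trapping), with at least one observed year per
  unit.  A year without trapping lets the unit rebound toward carrying
  capacity within roughly one year; this is a genuine consequence of the
  high growth rate plus strong density dependence, and the weighted
  whole-dataset CPUE is therefore dominated by rebound years.
* One master seed; independent substreams for network, effort schedule,
  spatial field, process noise and observations, so each layer is
  reproducible on its own.

What the generator does *not* emulate: GIS-derived covariate structure
(covariates are spatially unstructured noise), sub-annual dynamics,
trap-level heterogeneity, and any observation process other than Poisson
counts.  Passing recovery and calibration tests therefore shows that the
estimation and optimization machinery is correct under the model's own
assumptions; it does not validate the model against field data.

## Problem sizes used in tests and the acceptance script

Recovery experiments fit five replicate studies (75 units, 9 years) with
4 chains x 2,000 iterations (1,000 warmup, thin 4; 1,000 retained
draws) — a reduced configuration whose posteriors are already
well-mixed (worst split R-hat typically < 1.05) because the conjugate
block updates mix quickly on data this informative.  The acceptance
script runs one such study end to end, uses 20,000 SA steps per
multiplier, and finishes in well under five minutes; the 95% credible
intervals for `alpha`, `lambda` and `beta6` are required to cover the
generating values in at least 13 of 15 parameter-dataset pairs, and
annual posterior-predictive P-values to fall in [0.1, 0.9] for at least
80% of years.

## Numerical choices and edge cases

* CAR sampling and density use the joint multivariate-normal form with
  precision `(D - gamma W)/sigma_rho^2` — mathematically identical to the
  stated conditionals and much cheaper inside MCMC.
* Degenerate R-hat input (all-constant chains) returns 1 by convention;
  chains too short to split are used unsplit.
* The softmax map computes the last unit as the budget remainder, so the
  constraint holds exactly; inputs are max-shifted against overflow.
* Greedy ties break to the lowest unit index for determinism.
* Draws with `|lambda| >= 1` are excluded from every equilibrium average
  and reported as a count, never silently included.
* Posterior CSVs round-trip at full precision (`%.17g` +
  `float_precision="round_trip"`).

## Known limitations

* The sampler is single-machine, sequential over chains; very long
  default runs take a few minutes on one core for 75 x 9 data.
* The equilibrium objective ignores process-noise variance (it is the
  deterministic fixed point); with noise the stationary mean density is
  higher by Jensen's inequality, which the forward simulator shows.
* Static allocations only: no re-optimization within the simulated
  horizon, no cost heterogeneity between units.
* A single-unit (non-spatial) model variant is not provided; the CAR
  prior requires every unit to have at least one neighbour.
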
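# Methods

## Model

A haploid wild-type population of size `N_W` lives under a hard carrying
capacity `K` imposed through the per-capita birth rate `b_W,alpha g(N/K)`;
the per-capita death rate `d_W` is density- and environment-independent.
Three density factors are supported: logistic `g(x) = 1 - x`, Gompertz
`g(x) = -log(x)` and Richards `g(x) = 1 - x^beta` (`beta > 0`). The
environment alternates between a favourable state F (`b_WF > d_W`) and a
harsh state H (`b_WH < d_W`), harsh first: the population starts at the
favourable-environment equilibrium `N*` (the root of `b_WF g(N*/K) = d_W`),
so the first change it experiences is the onset of stress. Phase durations
are i.i.d. draws from either a Dirac delta at `tau` (periodic switching) or
a normal with mean `tau` and standard deviation `sigma` truncated to
non-negative values (quasi-periodic switching); the truncated density is
normalized by `Z = (1/2)(1 + erf(tau/(sigma sqrt(2))))` so it integrates to
one on `[0, inf)`.

A generalist mutant (birth rate `b_M`, death rate `d_M`, both
environment-independent) arises at each wild-type birth event with
probability `mu`, one-directionally (no back-mutation). Optionally a single
mutant pre-exists at `t = 0` (standing genetic variation).

### Default parameters

| symbol | default | meaning |
| --- | --- | --- |
| `b_WF` | 1 / time | wild-type birth rate, favourable phase |
| `b_WH` | 0 | wild-type birth rate, harsh phase (0 = perfectly harsh) |
| `d_W`  | 0.1 | wild-type death rate |
| `b_M`, `d_M` | 1, 0.1 | mutant rates (environment-independent) |
| `mu`   | 1e-3 | mutation probability per wild-type birth (`K mu = 0.1`) |
| `K`    | 100 | carrying capacity (`N* = 90` logistic) |
| `tau`, `sigma` | run-specific | phase-duration law |

These defaults make the harsh-phase survival time
`tau_0H = log(N*)/d_W ~ 45` the natural unit for `tau`; the scientifically
interesting regime is `tau ~ tau_0H`, where rescue is neither certain nor
impossible. Time is measured in units of the inverse favourable birth rate.

## Stochastic simulation

`rescuekit.simulate` implements the exact Gillespie algorithm for the
four-reaction system (wild-type birth/death, mutant birth/death) with the
density factor evaluated at the **total** population `N_W + N_M` for both
genotypes (shared resources). Time-inhomogeneity is handled exactly: rates
are constant within a phase, so an exponential waiting time that would cross
the next switch epoch is discarded and the clock moved to the switch (valid
by memorylessness). Design choices:

- **Rescue declaration.** A realization is "rescued" once
  `N_M >= ceil(0.9 * N_M*)` with `N_M*` the mutant equilibrium (threshold 81
  at baseline). The residual loss probability from that size is of order
  `(d_M/b_M)^81 ~ 1e-81`, so the threshold choice is immaterial; the factor
  is configurable (`rescue_fraction`).
- **Lineage tracking.** Each mutation event opens a lineage; mutant
  birth/death events are attributed proportionally to lineage size. At
  rescue, the appearance time of the *oldest surviving* lineage is reported
  as the rescuing mutant's appearance time (ties between coexisting lineages
  are resolved in favour of age).
- **Reproducibility.** A root seed spawns per-replicate `SeedSequence`
  streams (numpy Philox-family spawning); schedule durations and the event
  kernel draw from separate streams, so ensembles are bit-identical for
  identical inputs. If a realization outlives its pre-generated schedule it
  is replayed on a longer schedule whose prefix is identical, which
  reproduces the trajectory exactly and then continues it.
- **Guards.** 1e9 events per realization, after which the run aborts with a
  diagnostic (only reachable for non-absorbing parameterizations, e.g.
  `mu = 0` with a growing "harsh" phase).
- The kernel is jitted with numba when importable; a pure-Python fallback
  keeps results identical (same generator), only slower.

## Extinction analytics

The rescue-free wild-type process is the birth–death chain on `{0..K}` with
rates `lambda_n = n b_W,alpha g(n/K)`, `mu_n = n d_W`, absorbing at 0.

- **Harsh phase.** For `b_WH = 0` the chain is pure death and the size
  marginal is exactly `Binomial(N0, e^{-d_W t})`; otherwise the master
  equation is propagated by matrix exponentials of the tridiagonal
  generator. `p0_H` averages the extinction mass over the duration law
  (Gauss–Legendre, 96 nodes on the mean ± 8 sigma support).
- **Favourable phase.** Survivors of a harsh phase start the favourable
  phase small; *rapid extinction* is the gambler's-ruin probability of
  hitting 0 before recovering to `ceil(N*)`, computed from the standard
  product recursion with state-dependent rates. `p0_F` mixes this over the
  survivor-size distribution and is **conditional on harsh-phase survival**
  (normalization by `1 - p0_H`): the cycle law below requires the
  conditional quantity. A sensitivity diagnostic reports the effect of
  moving the recovery barrier by ±10% of `N*` (the notion of "rapid" is a
  modelling choice).
- **Cycle law.** With per-cycle survival `s = (1 - p0_H)(1 - p0_F)`, the
  number of favourable phases completed before extinction is geometric,
  `P(q_F = k) = s^k (1 - s)`, mean `s/(1 - s)`; the mean total extinction
  time is `T0 = 2 <q_F> tau + (1 - omega_F) tau_0H + omega_F tau_0F` with
  `omega_F = p0_F/(p0_F + p0_H)`, `tau_0F = 1/d_W`.
- **Harsh survival time in T0.** The harsh term is the *conditional* mean
  extinction time `E[T | T <= tau]`, computed from the extinction-time CDF
  (`tau - int_0^tau P0(t) dt / P0(tau)`). It converges to the exact
  unconditional mean survival time as `tau` grows (`(1/d_W) H_{N*}` for pure
  death) and sits slightly below `tau` for short phases, with no ad-hoc cap.
  The familiar approximation `log(N*)/d_W` undershoots the exact mean by
  `~ gamma_Euler/d_W` (about 13% at baseline), which is visible in
  slow-fluctuation extinction times; the simpler quantities remain exposed
  (`pure_death_mean_extinction_time`, `mean_extinction_time_constant`, and
  `ModelParams.tau_0H` keeps the standard `log(N*)/d_W` convention used for
  scaling tau grids).

## Rescue analytics

A mutant appearing at cycle time `t0` is approximated by a time-inhomogeneous
linear birth–death lineage with per-capita birth rate
`beta(s) = b_M g(<N_W>(s)/K)` along the periodic mean-field wild-type orbit
and death rate `d_M`. Its escape-from-loss probability is
`pfix(t0) = 1/(1 + J(t0))`, `J(t0) = int_{t0}^inf d_M e^{rho(u)} du`,
`rho(u) = int_{t0}^u (d_M - beta)`, evaluated through the `2 tau`
periodicity of `beta` by geometric resummation across periods.

- **Conditioned background.** The harsh segment of the orbit starts at `N*`;
  the favourable segment starts at the *survival-conditioned* mean
  `E[N]/P(N > 0)` after a harsh phase of length `tau` (mean-field numerator,
  master-equation/binomial survival denominator). While `tau << tau_0H` this
  equals the plain mean-field value; once `tau ~ tau_0H` the unconditional
  mean (a fraction of an individual) badly misrepresents the cycles that
  actually occur and would overestimate both the mutant supply's early boost
  and `pfix` for favourable-phase mutants — with the conditioned start the
  analytic rescue probability tracks simulation across the whole transition.
- **Numerics.** `rho` can dive tens of units below zero within a harsh
  phase, so `J` is assembled by a backward recurrence over one period using
  only local increments of `rho` (a single global cumulative integral of
  `e^rho` loses those excursions to floating-point cancellation and returns
  `pfix = 1`). Grid: 4096 panels per period (trapezoid; relative error
  ~1e-7, checked against a 16x finer grid). The per-period net growth
  `-delta_rho` must be positive, otherwise `pfix = 0` (certain eventual
  loss, e.g. a neutral or deleterious mutant in a constant environment).
- **Supplies and rescue probability.** The per-cycle expected numbers of
  *fixing* mutants are
  `Sigma_H = mu b_WH int_0^tau <N_W>_H g(<N_W>_H/K) pfix(t) dt` and the
  favourable analogue with `pfix(t + tau)`; for non-logistic laws the
  density factor in the supply is the law's own `g`. The de novo rescue
  probability `sum_k P_qF(k) (1 - e^{-(k+1)Sigma_H - k Sigma_F})` has an
  exact geometric resummation,
  `1 - (1 - s) e^{-Sigma_H} / (1 - s e^{-(Sigma_H + Sigma_F)})`, which is
  used instead of a truncated series. Fixation of quantities under
  stochastic durations: `pfix` and the supplies are always computed in the
  mean-duration periodic environment; duration randomness enters only
  through `p0_H`, `p0_F` and the cycle law.
- **Standing variation.** `p_r_SGV = pfix(0)` (one mutant present at the
  onset of the first harsh phase); the total combines as
  `p_r = p_r_SGV + (1 - p_r_SGV) p_r_DN`.
- **Appearance time.** The mean index of the favourable environment in which
  the fixing mutant appears is
  `<q_af,F> = sum_k P_qF(k) sum_{q<=k} q e^{-(q-1)Sigma_F}(1 - e^{-Sigma_F}) / p_r_DN`
  (geometric-tail truncation at relative mass 1e-12; plain geometric limit
  `1/(1 - e^{-Sigma_F})` when extinction is beyond floating-point
  resolution). Within a favourable phase the appearance time `t_af` is the
  *fixation-weighted* mean of the supply density (weighting by `pfix` is a
  modelling choice; the unweighted mean would ignore that late-phase mutants
  fix more often at short `tau`). Then
  `tau_af = (2 <q_af,F> - 1) tau + t_af`. The normalization uses `p_r_DN`
  (conditioning on de novo rescue); with no pre-existing mutant this equals
  the total rescue probability.
- **Fast-fluctuation limit.** For `tau -> 0` the dynamics approach a
  constant environment with averaged birth rate
  `b~ = (b_WF + b_WH)/2`, effective equilibrium `N~*`, selection coefficient
  `s~ = b_M d_W/(b~ d_M) - 1` and fixing-mutant appearance time
  `tau~_af = 1/(mu N~* d_W s~)`; the corresponding mean extinction time
  `T~0` comes from the exact linear solve.

## Validation design and what it does (not) show

The simulator and the analytics are developed independently and validated
against each other plus closed forms: pure-death absorption (harmonic-sum
mean, binomial marginals), gambler's-ruin Monte-Carlo, a direct simulation
of the branching lineage (thinning algorithm against the same periodic
background — this checks the fixation *formula*, while the full-process
ensembles check the branching *approximation* itself), and Gillespie
ensembles across the fast/slow transition. Replicate counts are scaled to
desk size (10^3 ensemble replicates, 10^4 lineage replicates), with
agreement bands set accordingly (3 standard errors for matched quantities,
10% for the extinction time whose analytic form is itself approximate).

Because every input is generated by the model itself, these tests establish
internal consistency of theory and simulation, not realism: real populations
have structured environments with autocorrelation, environment-dependent
death rates, mutant fitness costs, and demographic detail (age structure,
diploidy) that the model deliberately omits.

Known approximation limits, visible in the cross-validation:

- At `tau < tau_0H` with stochastic durations the analytic `T0` runs a few
  percent high (~7% at `tau = 0.5 tau_0H`, `sigma = 0.1 tau`): the cycle law
  ignores the correlation between a phase's drawn duration and the
  population size handed to the next cycle.
- The branching approximation ignores mutant self-competition and wild-type
  background fluctuations; discrepancies grow with `mu` (mutant no longer
  rare) and are documented rather than corrected.
- The perfect/imperfect-harshness equivalence (`d_W/b_WH >= 10`) holds for
  the extinction time on the slow-fluctuation side (`tau >= 2 tau_0H`,
  within 5%); at `tau << tau_0H` the extinction time is exponentially
  sensitive to the harsh decay rate and the two parameterizations differ
  substantially even though the rescue probabilities remain nearly equal.

## Degenerate inputs and tie-breaks

`sigma = 0` is the exact Dirac case (no density; sampling returns `tau`).
Quantities conditioned on events of probability below 1e-12 (e.g. the
survivor distribution after an overwhelming harsh phase) raise rather than
return garbage. When per-cycle survival reaches 1 to machine precision the
extinction time is reported as "no absorption" while rescue probabilities
remain well-defined (limit 1). Equilibrium sizes are kept real; integer
initializations round to nearest. The Gompertz density factor is capped at
its single-individual value `log K` in deterministic trajectories (the
stochastic process never needs the cap, since births require `N >= 1`).
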
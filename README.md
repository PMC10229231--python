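# rescuekit

Stochastic eco-evolutionary modelling of **evolutionary rescue in a
fluctuating environment**: exact event-driven simulation of a
density-regulated wild-type + generalist-mutant birth–death process under
alternating harsh/favourable phases, together with matching analytic
predictions for the extinction time, the rescue probability (de novo and
standing variation) and the appearance time of the rescuing mutant — each
cross-validated against the other.

Intended for theoretical population geneticists and ecologists studying
population persistence under periodic or noisy stress (e.g. microbes under
intermittent biostatic drug exposure, or species under seasonal/irregular
environmental stress).

## The model

A wild-type population of size *N*<sub>W</sub> ≤ *K* has per-capita birth
rate *b*<sub>W,α</sub> *g*(*N*/*K*) and death rate *d*<sub>W</sub>, where the
density factor *g* is logistic (1 − *N*/*K*), Gompertz (log(*K*/*N*)) or
Richards (1 − (*N*/*K*)<sup>β</sup>). The environment α alternates between a
favourable state (*b*<sub>W,F</sub> > *d*<sub>W</sub>, growth towards the
equilibrium *N*\* — e.g. *K*(1 − *d*<sub>W</sub>/*b*<sub>W,F</sub>) for the
logistic law) and a harsh state (*b*<sub>W,H</sub> < *d*<sub>W</sub>,
decline). Each phase lasts a random time τ drawn from a Dirac delta
(periodic switching) or a zero-truncated normal with mean τ and standard
deviation σ (quasi-periodic switching). A generalist mutant with
environment-independent rates *b*<sub>M</sub>, *d*<sub>M</sub> appears at
wild-type births with probability μ; if a mutant lineage escapes loss, the
population is *rescued*, otherwise it goes extinct at time *T*<sub>0</sub>.

Key analytic quantities (all in `rescuekit.extinction` / `rescuekit.rescue`):

- per-cycle extinction probabilities *p*<sub>0,H</sub> (within a harsh phase,
  from the birth–death master equation averaged over the duration law) and
  *p*<sub>0,F</sub> (rapid extinction early in a favourable phase, by a
  gambler's-ruin first-passage computation from the survivors' size
  distribution);
- the geometric law of the number *q*<sub>F</sub> of favourable phases
  survived, with mean ⟨*q*<sub>F</sub>⟩ = *s*/(1 − *s*) for per-cycle
  survival *s* = (1 − *p*<sub>0,H</sub>)(1 − *p*<sub>0,F</sub>), and the mean
  total extinction time
  *T*<sub>0</sub> = 2⟨*q*<sub>F</sub>⟩τ + (1 − ω<sub>F</sub>)τ<sub>0,H</sub> + ω<sub>F</sub>τ<sub>0,F</sub>;
- the fixation probability *p*<sub>fix</sub>(*t*<sub>0</sub>) of a mutant
  appearing at cycle time *t*<sub>0</sub>, from the time-inhomogeneous
  branching formula 1/(1 + ∫ *d*<sub>M</sub> e<sup>ρ(u)</sup> du) along the
  periodic mean-field wild-type orbit;
- per-cycle fixing-mutant supplies Σ<sub>H</sub>, Σ<sub>F</sub>, the de novo
  rescue probability
  *p*<sub>r,DN</sub> = Σ<sub>k</sub> *P*<sub>qF</sub>(k)(1 − e<sup>−(k+1)Σ<sub>H</sub> − kΣ<sub>F</sub></sup>),
  the standing-variation term *p*<sub>r,SGV</sub> = *p*<sub>fix</sub>(0) and
  the total *p*<sub>r</sub> = *p*<sub>r,SGV</sub> + (1 − *p*<sub>r,SGV</sub>)*p*<sub>r,DN</sub>;
- the mean appearance time of the fixing de novo mutant,
  τ<sub>af</sub> = (2⟨*q*<sub>af,F</sub>⟩ − 1)τ + *t*<sub>af</sub>.

The simulator (`rescuekit.simulate`) is an exact Gillespie implementation of
the same process (numba-accelerated when available), with per-replicate seed
streams, lineage tracking for the rescuing mutant's appearance time, and
ensemble summaries with 95% confidence intervals.

## Worked example

```python
from rescuekit import DurationDistribution, ModelParams, RescueAnalytics
from rescuekit.simulate import run_ensemble

params = ModelParams()            # b_WF=1, b_WH=0, d_W=0.1, b_M=1, d_M=0.1,
                                  # mu=1e-3, K=100  ->  N* = 90, tau_0H ~ 45
dist = DurationDistribution(22.5) # periodic phases of half the survival time

pred = RescueAnalytics(params, dist).predict()
print(f"analytic p_r_DN = {pred.p_r_DN:.3f}, p_r_SGV = {pred.p_r_SGV:.3f}")

summary = run_ensemble(params, dist, n_reps=300, seed=2)
print(f"simulated rescue fraction = {summary.p_rescue_hat:.3f} "
      f"(95% CI {summary.p_rescue_ci[0]:.3f}-{summary.p_rescue_ci[1]:.3f})")
```

prints

```
analytic p_r_DN = 0.999, p_r_SGV = 0.685
simulated rescue fraction = 0.997 (95% CI 0.981-0.999)
```

With phases half as long as the harsh-phase survival time and a mutational
influx *K*μ = 0.1, de novo rescue is nearly certain (the analytic 0.999
sits inside the simulated confidence interval); a single pre-existing mutant
alone would rescue with probability 0.685. The `examples/` directory walks through
each capability (trajectories, extinction times, the fast/slow transition,
periodic vs quasi-periodic switching, growth laws, standing variation), and
the `rescuekit` CLI exposes `simulate`, `analytics` and figure-style `sweep`
presets (`rescuekit sweep --preset fig3b --reps 1000 --out results/`).

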
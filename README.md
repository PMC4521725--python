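# openscr

Open-population capture–recapture modelling for wildlife monitoring, with
both **non-spatial** (CR, CR_dedge) and **spatial** (SCR) observation models
fitted by Markov chain Monte Carlo with Bayesian data augmentation.

The package targets studies that repeatedly identify individuals — for
example DNA hair-snag surveys of bears across several detector types — and
need annual abundance *N*, density *D*, apparent survival φ, per-capita
recruitment *R*, and population growth λ, together with honest uncertainty
and goodness-of-fit statements.

## The models

The detected population is augmented with a fixed pool of all-zero
pseudo-individuals.  Each individual *i* carries a latent alive indicator
with Jolly-Seber dynamics

```
z_it ~ Bernoulli(φ_t · z_i,t−1 + γ_t · a_it)
```

where `a_it` marks individuals that have never yet been alive (dead animals
cannot re-enter).  Abundance is `N_t = Σ_i z_it`, recruitment
`R_t = B_t / N_t−1` (first-time entries over previous abundance), growth
`λ_t = φ_t + R_t`, and study averages are geometric means over year
transitions, per MCMC iteration.

Detection, given alive:

* **non-spatial** — `logit(p_ikm) = B_mk (+ sex) (+ B_distedge · DEDGE_i)`,
  scaled for effort by a proportional hazard
  `p_eff = 1 − (1 − p)^(NDays/ReferenceDays)`.  `DEDGE` is the distance from
  the individual's observed home-range centre (centroid of the minimum
  convex polygon of its detection traps) to the study-area edge; augmented
  animals get a latent DEDGE from a truncated Gamma(shape, rate) prior whose
  parameters are estimated from the observed animals.
* **spatial (SCR)** — a bivariate half-normal kernel
  `p_ijk = g0_km · exp(−d_ij² / 2σ²)` between a latent activity centre on a
  buffered state space and each trap, with σ optionally sex-specific.

Fit is assessed with a Freeman–Tukey posterior-predictive (Bayesian)
p-value; convergence with the Gelman–Rubin statistic; intervals are 95%
highest-posterior-density windows.

A synthetic-data module generates both the square-grid benchmark design
(10×10 traps, spacing = σ = 1 km, φ = 0.8, R = 0.1, three years, five
occasions) and a grizzly-like three-detector design with ragged occasions
and variable effort, so everything is testable without field data.

## Worked example

```python
import numpy as np
from openscr import HIGH_SCENARIO, simulate_dataset, build_model, run_mcmc
from openscr.mcmc import SCALED_CONFIG, bayes_pvalue
from openscr.demographics import derive_demographics, summarize_posterior

dataset, traps, truth = simulate_dataset(HIGH_SCENARIO, np.random.default_rng(7))
model = build_model("scr", dataset, traps, HIGH_SCENARIO.boundary)
draws = run_mcmc(model, SCALED_CONFIG, seed=11)
demo = derive_demographics(draws, area_km2=HIGH_SCENARIO.area)
print(summarize_posterior({k: demo[k] for k in ("phi", "R", "lambda")}))
print("Bayes P:", round(bayes_pvalue(draws), 2))
```

prints (true values: φ 0.8, R 0.1, λ 0.9):

```
  parameter    median  hpd_lower  hpd_upper     cv_pct
0       phi  0.832140   0.790419   0.872303   2.578199
1         R  0.092093   0.071662   0.113386  11.655763
2    lambda  0.927041   0.882139   0.969333   2.469227
Bayes P: 0.62
```

The spatial model recovers survival and recruitment close to truth on this
replicate, and the posterior-predictive p-value near 0.5 shows no lack of
fit.  A command-line interface mirrors this flow
(`openscr simulate|fit|simstudy --help`).

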
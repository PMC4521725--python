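# Methods

## Model and assumptions

The package implements open-population capture–recapture with Bayesian data
augmentation.  A fixed pool of M individuals (detected + augmented) carries
latent alive indicators `z_it`.  Dynamics are Jolly-Seber with an
availability rule: apparent survival φ_t applies to individuals alive at
t−1; an entry probability γ_t applies only to individuals that have never
been alive (dead animals never re-enter).  Year-1 entry is `z_i1 ~
Bernoulli(γ_1)`, i.e. γ_1 is the initial inclusion probability — the
standard augmentation convention for the first session.  Apparent survival
confounds mortality and emigration; the package makes no attempt to
separate them.  Activity centres (and DEDGE) are constant across years:
there is no movement model.

Demographics are derived per MCMC iteration: `N_t = Σ z_it`; first-time
entries `B_t`; `R_t = B_t / N_{t−1}` (recorded as missing when `N_{t−1} =
0`, never divided through); `λ_t = φ_t + R_t` exactly; study averages are
geometric means over the year transitions.  The averaged abundance `N` is
the per-iteration arithmetic mean of the annual `N_t` (summarised by its
posterior median) — with three years there is no uniquely standard
convention, and this choice keeps `N` on the scale of an annual abundance.
Density divides by the rectangular state-space area and is reported per
1000 km²; the area used is always reported alongside since a different
state-space convention (e.g. a hull-shaped space) would change the scale.

## Detection sub-models

**Non-spatial (CR / CR_dedge).**  Baseline detection is logit-linear in
trap type × occasion (plus an additive male effect in combined-sex models),
with proportional-hazard effort scaling `1 − (1 − p)^(NDays/RefDays)`
(reference days 162 / 42 / 20 for bear rubs, hair traps, highway
crossings).  Likelihoods are computed separately per trap type and summed.
CR_dedge adds a linear distance-to-edge term.  Observed DEDGE comes from
the area centroid of the convex hull of an individual's detection traps
(trap location for one trap, midpoint for two, mean of unique points in the
collinear degenerate case — the degenerate conventions are this package's
choice).  Observed DEDGE values are fixed data that contribute to the
Gamma(shape, rate) likelihood; augmented individuals carry latent DEDGE
values updated by Metropolis steps against the truncated-gamma prior times
the observation likelihood.  The truncation point is the maximum observed
DEDGE of the dataset (18.5 km for the default grizzly-like design); the
truncated density is normalised with the regularised incomplete gamma
function, and prior draws use rejection sampling with an exact
inverse-CDF fallback when the acceptance probability drops below 5%.
The plain CR variant is CR_dedge with the edge slope fixed at zero and no
imputation; in the simulation study it uses a single intercept (constant p
per trap-occasion), which is what "no covariates" means here.

**Spatial (SCR).**  Bivariate half-normal kernel `g0 · exp(−d²/(2σ²))`
with g0 logit-linear in trap type (× occasion, × sex as configured) and σ
optionally sex-specific.  Effort enters as a binary trap-occasion activity
mask — day-count hazard scaling is specified only for the non-spatial
model, so SCR leaves it off by default.  Occasions sharing a detection
class are pooled into binomial cells, which is exact because p is constant
within a class, and the likelihood is computed as the all-zero mass (a
dense tensor contraction) plus sparse corrections at the positive counts.
The state space is the rectangle bounding the buffered trap array (2.5
spacings for the grid design, 25 km for the grizzly-like design); activity
centres have a uniform prior there.

## Sampler

Metropolis-within-Gibbs:

* **z** — each individual's whole trajectory is drawn from its exact full
  conditional.  Under the no-re-entry rule, admissible trajectories are the
  single contiguous alive runs (T(T+1)/2 + 1 of them), so the draw is a
  categorical over prior × likelihood weights via Gumbel-max, with
  trajectories that miss a detected year excluded.  This blocked update
  mixes better than year-by-year Bernoulli sweeps and is checked against
  exhaustive enumeration in the tests.
* **φ_t, γ_t** — Uniform(0,1) priors are conjugate to the Bernoulli
  transitions, so these are exact Beta draws (survivors/deaths among those
  at risk; entrants/non-entrants among those available).  Exactness and
  speed are why Gibbs is used here rather than random-walk steps.
* **continuous detection parameters** (logit-scale β and g0 terms, σ,
  DEDGE shape/rate, latent DEDGE, centres) — random-walk Metropolis with
  per-block step sizes adapted only during burn-in (multiplicative
  up/down factors targeting moderate acceptance), frozen afterwards to
  preserve detailed balance.  Centre proposals reflect at the state-space
  rectangle, which keeps the uniform prior invariant.  Latent sexes of
  augmented individuals (combined-sex models) are Gibbs draws, and p_male
  has a conjugate Beta update.

Priors: β and interaction terms Uniform(−10, 10); σ Uniform(0, 15);
DEDGE shape and rate Uniform(0, 30]; φ, γ, p_male Uniform(0, 1); centres
uniform on the state space.  Probabilities are clipped at 1e−12 inside
logs.  Initialisation: z spans each detected individual's detected years;
centres start at observed centres (detected) or uniform draws (augmented);
continuous parameters start near crude moment estimates with per-chain
jitter.  A non-finite log-likelihood at any iteration raises immediately
with the offending state keys.

Field-data defaults are 3 chains × 30 000 retained iterations after a
5 000-iteration burn-in with augmentation 200/200/280
(female/male/combined); no thinning — all post-burn-in draws are retained.
The simulation-study mode uses a 4 000 burn-in and repeats 5 000-iteration
cycles until every Gelman–Rubin statistic is below 1.1 (classic
between/within form, defined as 1.0 for constant draws), up to a cycle cap;
replicates still unconverged at the cap are flagged and excluded from
scores, with the exclusion counted.  Goodness of fit is the Freeman–Tukey
posterior-predictive p-value `Pr(T_obs > T_rep)` over individual ×
detector × occasion × year cells restricted to currently-alive
individual-years (computed every 10th retained iteration); values below
0.05 or above 0.95 flag misfit.  CV is posterior SD / posterior mean × 100.

## Synthetic data

The square-grid generator emulates the benchmark design: 10×10 traps at
spacing s = σ = 1 km, centres at fixed density (initial size exactly
`round(density × area)` — fixed, not Poisson) uniform on the grid buffered
by 2.5 s, φ = 0.8, survival and recruitment as independent Bernoulli events
per animal (recruits placed uniformly, entering the following year), three
years, five occasions, Bernoulli detection through the half-normal kernel.
The scenario grid crosses density {0.5, 1.0} s⁻² with g0 {0.1, 0.5}; the
low corner (0.5, 0.1) yields on average ≈86 unique individuals detected
and the high corner (1.0, 0.5) ≈211, matching the benchmark's reported
range.  True growth is φ + R = 0.9.

The grizzly-like design adds what the grid lacks: three detector types with
ragged occasion structures (7 bear-rub, 5 hair-trap, 8 crossing occasions;
hair grids only in the first and last years; rubs starting mid-way through
year 1), per-occasion trap-day effort feeding the hazard scaling,
sex-specific movement (σ 5 km females, 9 km males, following observed
home-range differences), a corridor of crossing detectors, and a 25 km
state-space buffer at a density of ~15 animals per 1000 km².  Neither
generator includes behavioural responses, density gradients, centre
movement between years, or identification error, so passing tests show
correct inference *under the stated model*, not robustness to those
real-data complications.

## Scaling of the shipped experiments

The default test-and-acceptance profile runs 2 scenarios × 10–20
replicates with 2 chains (1 000–1 500 burn-in, 1 500-iteration cycles, cap
3 cycles) and augmentation +150 — sizes chosen so the whole experiment
runs on a single CPU in minutes while keeping Monte-Carlo error on
scenario-mean biases near 0.01.  The full profile (4 scenarios × 100
replicates × 3 models, 3 chains, 5 000-iteration cycles) reproduces the
benchmark experiment at publication scale and is intended for a cluster or
an overnight run.

## Known limitations

* Euclidean distances only; no least-cost or barrier-aware kernels, and no
  habitat covariates on density.
* The rectangular state space slightly exceeds a buffered trap hull; density
  comparisons across packages must use the reported area.
* Apparent survival confounds mortality and emigration by design.
* Single-catch behaviour, counts per occasion, and genotyping error are out
  of scope; detection events are binary per individual × trap × occasion.
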
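# divepop

From dive-record signals to population dynamics for a Southern Ocean
diving predator.

King penguins breeding on subantarctic islands commute hundreds of
kilometres to feed on mesopelagic fish at the Antarctic polar front (PF),
the northern boundary of Antarctic surface waters. Warm sea-surface
anomalies push that front south, stretch the birds' foraging trips, deepen
their dives, and — through reduced breeding success and adult survival —
depress the breeding population. `divepop` is a tested, reusable
implementation of the computational chain that quantifies each link:

1. **dive-signal extraction** — dives, wiggles (brief depth reversals,
   a prey-pursuit proxy), steps (slow-descent periods), diving bouts, and
   prey-ingestion events from oesophageal temperature drops
   (rate ≥ 0.06 °C s⁻¹), plus thermocline depth from dive profiles;
2. **prey-capture regression** — negative-binomial GLMs of per-bout
   feeding-event counts on diving covariates, all-subsets QAIC model
   averaging with shrinkage, and concordance-index (C-index) validation;
3. **ocean indices** — monthly SST anomalies, the 5 °C-isotherm PF
   latitude, the area-mean box SSTA, the leading EOF of subtropical
   Atlantic–Indian SST anomalies (a dipole mode), and the
   front-shift-per-°C regression;
4. **population dynamics** — Poisson log-linear imputation of missing
   colony counts and a Bayesian stochastic Gompertz state-space model of
   log breeding-pair abundance;
5. **breeding success** — penalized cubic-spline Gaussian GAMs of annual
   breeding success on environmental covariates, smoothing chosen by GCV.

Because the original tracking, dive and count data are not public, a
first-class synthetic module (`divepop.synth`) generates every input with
known ground truth, so each stage is validated by round-trip recovery.

## The population model

With `x_t = ln N_t` the log number of breeding pairs, covariate `z_t`
(standardized) and observed log counts `y_t`:

```
x_{t+1} = x_t + r − b·x_t + c·z_t + ε_t,   ε_t ~ N(0, τ²)
y_t     = x_t + η_t,                        η_t ~ N(0, σ²)
```

`r` is the growth rate at N = 1, `b` the strength of density dependence
(1 − b is the lag-1 autocorrelation of log abundance), `c` the covariate
effect, τ and σ process and observation error s.d. Priors:
`r ~ N(0.10, 0.02²)` (demographic-invariant informative prior),
`b, c ~ N(0, 10²)`, `σ, τ ~ U(0, 3)`. The posterior is sampled by a Gibbs
scheme — forward-filter backward-sampling for the latent states
(conditionally linear-Gaussian), conjugate Gaussian updates for
`(r, b, c)`, truncated inverse-gamma updates for τ², σ² — with 2 chains of
50,000 draws after 10,000 burn-in at production scale (5,000/1,000 for the
test bench). Summaries report posterior means, 95 % highest-posterior-
density intervals, Pr(c < 0), and split-R̂.

## Worked example

`python analysis/04_population_dynamics.py` imputes a 4-colony × 30-year
count table with 43.9 % of cells missing, then simulates a 30-year series
under (r = 0.101, b = 0.008, c = −0.067, τ = 0.099, σ = 0.113) and refits
it. Output from a run with seed 1:

```
67 observed colony-years of 120; overdispersion factor 0.97

parameter  truth   posterior mean (95% HPD)        R-hat
r           0.101    0.100 ( 0.063;  0.141)   1.000
b           0.008    0.008 ( 0.003;  0.013)   1.000
c          -0.067   -0.109 (-0.165; -0.053)   1.001
tau         0.099    0.115 ( 0.034;  0.185)   1.000
sigma       0.113    0.076 ( 0.006;  0.138)   1.000
Pr(c<0) = 1.000
posterior-predictive 95% band covers 100% of years
```

The growth rate and density dependence are recovered on the nose; the
covariate effect and the τ/σ split wander within their HPD widths on any
single 30-year realization (this seed overstates |c|) — the 50-seed
average recovers all five (see below). The other drivers follow the same
pattern: `01` extracts dives/wiggles/steps and feeding events and finds
the planted doubled capture rate at the front (Mann–Whitney p = 0.008),
`02` reproduces the model-averaging table (wiggles and descent rate among
the strongest predictors; validation C-index 0.914), `03` recovers the
planted 27 % dipole variance fraction and the 130 km °C⁻¹ front shift
(128.2 km °C⁻¹, r² = 0.99), `05` the hump-shaped breeding-success
response. Each writes its tables under `results/`.

## Layout

```
src/divepop/      library: synth, dive_signal, prey_model, popdyn,
                  ocean, breeding_gam, pipeline, config, cli
analysis/         numbered narrative drivers (01–05)
tests/            pytest suite, including end-to-end recovery checks
scripts/          acceptance.py
docs/methods.md   models, assumptions, parameter choices, limitations
```

A thin CLI wraps the common entry points, e.g.
`divepop run --out results/`, `divepop synth sst --seed 1 --out sst.nc`,
`divepop popdyn-fit --counts counts.csv --covariate saiod`.
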
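# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the test suite does and does not establish.

## Dive-signal definitions

Depth is positive downward; vertical speed is the forward finite
difference Δdepth/Δt, positive while descending. A **dive** is a maximal
interval with depth above a surface threshold (0.5 m) reaching at least a
floor depth (3 m for all dives; foraging analyses filter at 50 m). The
**bottom phase** is where depth ≥ 80 % of the dive maximum — a common
biologging convention; descent and ascent are the segments before the
first and after the last bottom sample, and their rates are phase depth
span over phase duration.

A **wiggle** is operationalized as a below-zero excursion of vertical
speed that returns to ≥ 0 — one wiggle per −/+ zero-crossing pair —
counted over descent + bottom only. Counting against the prevailing
downward/flat motion keeps ascent (where negative speed is the norm) out;
whether ascent reversals should count is genuinely ambiguous, and the
exclusion is flagged here as a design choice. A **step** is a maximal run
of slow speed (|v| ≤ 0.35 m s⁻¹) with the phase's sign, counted in
descent and ascent separately; reversals belong to wiggles, not steps.

A **feeding event** is a drop episode in oesophageal temperature whose
maximum descending rate reaches 0.06 °C s⁻¹, with amplitude ≥ 0.1 °C and
duration ≤ 300 s. Episodes are maximal declining runs, merged with the
next decline when the rebound between them recovers less than half the
previous drop. The amplitude/duration gates and the recovery fraction are
parameters, not claims: the calibration experiments that fixed them for
real sensors are not reproducible here, so defaults are exposed in
`PipelineConfig`. Episode construction is independent of the rate
threshold, which makes detection monotone in it (tested).

**Thermocline**: dive profiles are binned to a 2-m depth grid, combined
by the median across dives, smoothed with a 5-bin moving average, and
differentiated centrally; the estimate is the depth of maximum |dT/dz|,
with gradient-plateau ties resolved to the plateau midpoint. The estimate
is invariant to adding a constant to all temperatures.

**Bouts**: consecutive dives whose separating surface interval is below a
gap threshold (default 1800 s — unstated in the original procedure and
therefore explicit configuration). Bout covariates are per-dive means
plus log(n dives) and its square.

Transit vs front comparisons use Mann–Whitney (exact for n ≤ 12 without
ties, normal approximation with tie correction otherwise).

## Prey-capture model

Per-bout feeding-event counts are modelled as NB2 negative binomial with
log link; covariates are centred and scaled. Overdispersion is checked
two ways: the auxiliary-regression test of Var = μ + α μ² and the NB-vs-
Poisson likelihood ratio with the boundary-corrected null
(p = ½ P(χ²₁ > LR)).

All 192 covariate subsets are fitted (the quadratic log-dives term only
ever enters with the linear term — a marginality constraint; Akaike-type
averaging over ill-formed polynomials is not meaningful). The dispersion
α is estimated once, by maximum likelihood on the global model, and held
fixed across the candidate set; ĉ for QAIC (−2 log L/ĉ + 2k, k counting
the inflation factor) is the global model's Pearson χ²/df, clamped at 1.
Both are the standard global-model estimators in the QAIC literature.
Weights w ∝ exp(−ΔQAIC/2) are computed over the full candidate set; the
95 % confidence set is the smallest QAIC-ordered prefix with cumulative
weight ≥ 0.95, and averaging runs over that set with renormalized
weights. Averaging is "full" (with shrinkage): absent terms contribute 0,
and unconditional standard errors are
√(Σ w (se² + (β − β̄)²)). Validation uses the concordance index over
pairs with distinct observed counts (prediction ties count ½), with
standardization statistics frozen on the fit rows. Per-individual random
effects are deliberately omitted (too few individuals at the emulated
study size); per-individual refits are available as a diagnostic loop.

## Ocean products

Anomalies remove a per-cell, per-calendar-month climatology. Box SSTA is
the cos-latitude-weighted mean over 47–53° S, 49–55° E in February–March.
The PF latitude is, per longitude column of the 50–54° E sector, the
northernmost latitude where the summer-mean (January–March, configurable)
SST crosses 5 °C, by linear interpolation between grid rows; the sector
mean is reported with its anomaly (positive = southward) and great-circle
distance from the colony (−46.43° S, 51.86° E). The dipole index is the
leading PC of √cos(lat)-weighted, covariance-based PCA of Feb–Mar
anomalies over 10–50° S, 50° W–150° E, standardized to unit variance, the
sign fixed so a positive index goes with positive loadings in the
southwest of both basins. Degrees convert to kilometres at
111.2 km deg⁻¹. The front-shift regression is OLS of southward PF
displacement (km) on box SSTA.

## Population model

See the README for the state-space equations and priors. Sampler details:
the prior on the initial state is N(y₁, 1) (diffuse but proper); τ and σ
have flat priors on (0, 3), giving truncated inverse-gamma conditionals
for their squares, sampled by rejection from the untruncated conditional
(the truncation is rarely active). Standard deviations are floored at
10⁻⁴ so noise-free degenerate inputs keep the Kalman recursions defined.
"Error s.d." is used throughout where source material ambiguously writes
s.e.m. — the standard state-space reading. The covariate is standardized
before entry, so c is on a per-s.d. scale. Chains are seeded
deterministically from one integer; the kernel is compiled with numba.
R̂ is the split-chain Gelman–Rubin statistic; HPD intervals are the
shortest interval containing 95 % of draws.

With σ → 0 the model collapses to a Gompertz autoregression and the
posterior of (r, b, c) matches the conjugate regression of x_{t+1} − x_t
on [1, −x_t, z_t] — this oracle equivalence is tested, as are HPD
coverage at the nominal rate and the 1 − b lag-1-autocorrelation
identity. At T = 30 the covariate effect c and the τ/σ split are weakly
identified in any single realization; recovery claims are therefore made
about averages over 50 replicate series. The growth rate is largely
prior-identified by design (the informative demographic prior), which in
turn identifies b ≈ r/x̄; both show over-nominal HPD coverage.

Missing colony counts are imputed from a Poisson log-linear model with
colony and year as discrete factors, fitted on observed cells; missing
cells take fitted values and their standard errors are inflated by the
Pearson overdispersion factor. Serial correlation beyond this factor is a
documented simplification. A colony or year with no observation at all is
an error by construction.

## Breeding-success GAM

Gaussian family on the proportion scale (kept deliberately — the
procedure being reproduced used it; a logit link would be the textbook
alternative), cubic B-spline basis with 10 basis functions and interior
knots at covariate quantiles, exact second-derivative penalty (3-point
Gauss–Legendre per inter-knot interval, exact for piecewise-quadratic
integrands). The covariate is mapped to [0, 1] internally, making fits
invariant to affine covariate transforms. GCV n·RSS/(n − tr S)² is
minimized over a 65-point log-spaced grid; among candidates within a
negligible GCV margin the smoothest wins (flat profiles arise on
noiseless data). Reported edf is tr S − 1 (the smooth term, excluding the
constant); adjusted R² = 1 − (RSS/(n − tr S))/(TSS/(n − 1)) and may be
negative; the F-test against the constant model uses edf-based degrees of
freedom and is approximate in the usual penalized-regression sense. GCV's
finite-sample efficiency relative to a truth-knowing oracle is about
1.1–1.3× risk (mgcv's own GCV behaves identically on the same data); the
test suite asserts that empirically supported bound.

## Synthetic-data design

Every generator is deterministic given one seed and returns its ground
truth. What they emulate, and what they do not:

* **Dive records** are piecewise-linear with segment durations snapped to
  the sampling grid, so planted wiggle/step counts are recovered exactly
  by the definitional scans; real traces add sensor noise, irregular
  bottom topography and surface drift (a noise option exists but exact
  round-trips are only claimed noise-free). Depths are drawn from the
  observed 50–306 m foraging range; vertical speeds centre on the
  species-typical 1.3 m s⁻¹. The second half of a trip doubles the
  per-dive capture rate, the transit-vs-front contrast the trip emulates.
* **Oesophageal traces** drop linearly at the planted rate and recover
  exponentially (60 s constant — the true recovery dynamics are not
  public; the constant is a parameter). The smallest detectable prey mass
  defaults to 1.8 g, the sensitivity floor established on captive birds;
  lighter prey leave no signal. Near-simultaneous ingestions merge into
  one drop, as they would on a real sensor.
* **Count series** simulate the Gompertz process forward from its
  stationary point with exactly the stated parameters. **Colony tables**
  are multiplicative Poisson (optionally gamma-overdispersed) with cells
  masked at 43.9 % at random, never masking a colony's or year's last
  observation.
* **Bout tables** draw covariates at realistic scales, standardize them,
  and generate NB counts from the documented standardized coefficients
  (intercept 3.13, log n-dives 1.45, its square −0.25, wiggles 0.32,
  descent rate 0.47, surface duration −0.25; others 0). The quadratic
  term is built on the centred log scale so curvature is identifiable
  rather than collinear. The NB dispersion θ = 12 is not documented
  anywhere; it was calibrated once so the oracle predictive concordance
  of the default table (~0.91) sits at the scale of the reported
  C-indices (0.92–0.94) while counts stay clearly overdispersed
  (variance ≈ 3× mean). The default size is 74 bouts (36 fit, 38
  validation).
* **SST fields** superpose (i) a meridional mean state putting the 5 °C
  isotherm at 52° S with gradient 111.2/130 °C deg⁻¹, so a +1 °C box
  anomaly moves the front south by exactly 130 km; (ii) a subtropical
  NE–SW dipole pattern (unit norm under the EOF weighting, zero south of
  44° S); (iii) a polar-band anomaly realizing the box SSTA series,
  confined to 48–56° E; and (iv) noise. The variance budget over the EOF
  domain is exact by construction: the realized PC is standardized, the
  band series and the noise are made temporally orthogonal to it, the
  noise is spatially orthogonal to the pattern and spectrally flattened,
  and everything is scaled so the planted mode explains exactly the
  configured fraction (27 % default). Real SST anomalies have red spatial
  spectra and leading-mode estimates inflated by eigenvalue repulsion
  (~2–3 points at these sizes); the exact-budget construction removes
  that bias deliberately, so passing tests certify the EOF machinery, not
  finite-sample EOF bias behaviour on real fields.

## Problem sizes

The test bench uses 30-year series with 2 × 5,000 (+1,000) MCMC draws and
50 replicate seeds; 20 seeds × 20-year SST records for the front
regression; 20 seeds × 33-year records for the EOF fraction; 100 seeds ×
500 bouts for coefficient recovery; 1,000 random traces for the signal
oracles. The production MCMC default (2 × 50,000 after 10,000) is exposed
as `popdyn.PRODUCTION_MCMC`. These sizes are the package's documented
study conditions for its own validation experiments.

## Known limitations

* No Argos track processing, accelerometry, or spatial movement model;
  the synthetic trips have no geometry beyond transit-vs-front halves.
* The imputation model ignores serial correlation beyond a dispersion
  factor; colony × year interactions beyond the multiplicative model
  appear as overdispersion.
* The Gompertz sampler assumes Gaussian errors on the log scale
  throughout; count likelihoods (e.g. Poisson observation) are out of
  scope.
* GAM inference (F, p) is approximate; no smoothing-parameter uncertainty
  is propagated.
* Real-data reproduction of the original tables and figures is out of
  scope by construction — the raw data are unreleased; all quantitative
  claims here are about recovery of planted truth.
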
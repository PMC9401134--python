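# Methods

This note documents the models and procedures implemented in `smokecast`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Fire activity from hotspot points

A *fire day* runs from local midday to the next local midday, matching the
afternoon-ignition / overnight-smoke cycle of hazard reduction burns.
Timestamps in [12:00, 24:00) of date D belong to fire day D; the night
overpass lands around 0–2 am, so timestamps before 07:00 of D+1 are
credited back to D. The [07:00, 12:00) morning gap — where polar overpasses
essentially never fall — stays on its own calendar date.

Distances (the 150 km study buffer, the 5 km cluster linkage) are
great-circle on a spherical Earth (R = 6371.0088 km). "Within 5 km of each
other" is implemented as *single-linkage* connectivity: clusters are
connected components of the ≤ 5 km graph, so chains of nearby detections
merge. A day is active when some cluster holds ≥ 3 detections; this filters
out the one-or-two-point days that typically come from trivial fires.

Hotspot detections are points, but the instrument pixel is ~375 m, so each
detection is rasterized as a 375 m axis-aligned square footprint centred on
the point, in a local spherical transverse-Mercator projection centred on
the reference station (at a 150 km extent the projection error is orders of
magnitude below the 500 m cell size). Cells count when the overlap has
positive area: a footprint edge exactly on a grid line does not capture the
neighbouring cell, and a point exactly on a cell corner captures all four.
Daily fire area = unique intersected 500 m cells × 25 ha, which
automatically collapses swath-overlap double captures. A `point` mode
(containing cell only) is available since the original GIS operation's
footprint convention is not knowable. Sector areas partition *hotspots* by
centre-point bearing (west [225°, 315°), south [135°, 225°), north
[315°, 45°), half-open) before rasterizing, so a footprint is never split
across sectors; the eastern quadrant contributes to the total but to no
sector predictor. Clustering is applied per fire day, not per overpass.

## Daily model rows

All daily aggregates use the same midday-to-midday window as the fire day —
one coherent day definition — except the coastal wind components, which are
averaged over 2–6 pm local of the window's start date to capture afternoon
sea-breeze onset. The ventilation index is computed hourly
(√(u²+v²) · boundary-layer height) and then averaged; the alternative
order (daily-mean speed × daily-mean height) is a policy switch
(`AggregationPolicy.vi_method`), since the original order of operations is
not documented and the hourly product is the physically standard one.

Missing-data policy (the sources state none, so these are package
defaults, both configurable): a station or site daily mean requires ≥ 75%
of the window's hours; the regional responses require ≥ 3 of the 5
stations. The 24 h lag is the previous calendar day's regional mean
computed from the *full* continuous record (active or not), so a run of
inactive days does not break the lag; rows without a computable lag are
dropped and logged. Model rows are restricted to active fire days in
March–September.

## Penalized Gamma GAM

Responses are strictly positive, right-skewed daily means whose spread
grows with the level, hence Gamma with a log link. Each 1-D predictor
enters as a cubic B-spline on an even, unclamped knot grid (P-spline
convention) with a second-order difference penalty, whose null space
contains exactly the linear trend — so "no effect beyond linear" is
reachable by penalization alone. Default basis size 10 (k − 1 = 9 columns
after the sum-to-zero centring constraint, absorbed by a QR
reparameterization). U/V wind pairs enter as one isotropic 2-D smooth: a
thin-plate kernel (r² log r) on a deterministic greedy k-centre knot set
over the isotropically standardized components, with linear columns
unpenalized and the bending-energy penalty projected onto the
polynomial-orthogonal subspace; default dimension 30. Isotropic
standardization makes the term invariant to rotating the wind plane, which
is verified by test.

Fitting is penalized Fisher scoring. For the Gamma/log pair the Fisher
weights are identically one, so each iteration solves
`(XᵀX + Σ λ_t S_t) β = Xᵀ z` with working response `z = η + (y − µ)/µ`;
step-halving guards the rare non-monotone step; convergence is a relative
deviance change below 1e-8 (1e-6 inside the model search) within 200
iterations; non-convergence is flagged, not raised. Smoothing parameters
maximize a Laplace-approximate restricted marginal likelihood
(REML — stabler than GCV at a few hundred rows; which criterion the
original analysis used is unknowable) over log λ by Nelder–Mead, with the
Gamma shape at its profile MLE at each evaluation. Effective degrees of
freedom are `tr[(XᵀX + S_λ)⁻¹XᵀX]`, and
`AIC = −2ℓ(β̂, α̂) + 2(edf + 1)`, the +1 counting the dispersion — the
conventional additive-model form; alternative constants cancel in
within-dataset comparisons.

## All-subsets selection

The candidate set has 11 units (9 singles + 2 U/V pairs); all 2^11 subsets
are fitted on the training split and ranked by AIC, ties broken toward
fewer terms then lexicographic formula text. To keep a 2048-model search
desk-fast, submodels reuse the full model's REML smoothing parameters and
the relaxed IRLS tolerance; the winner is refitted from scratch (its own
REML, full tolerance) before being reported or refitted Bayesianly.
Per-model REML is available as `strategy="reml"`. The train/test split is
random with a recorded seed (the original split method is not documented);
`method="chronological"` is provided. Test-set skill is the squared Pearson
correlation of observed vs predicted.

A structural property of this procedure, visible in the selection tests: a
pure-noise smooth always keeps its unpenalized linear degree(s) of freedom
no matter how hard REML shrinks the wiggles, so it lowers AIC whenever its
χ² improvement exceeds twice its null dimension — probability ≈ 0.16 per
1-D unit regardless of sample size. Exhaustive AIC search therefore
reliably *contains* the true drivers but usually carries a few spurious
weak terms; exact support recovery is not a property AIC provides.

## Bayesian refit

The selected formula is refitted with the standard Bayesian reading of the
penalty: per term, coefficients in the penalty eigenbasis get
`β_j ~ N(0, τ_t²/d_j)` on the penalized directions; unpenalized directions
get wide normals (sd 10 per standardized column); the intercept a
Student-t(3, log ȳ, 10); the smooth sds τ_t half-t(3, 2.5); the Gamma shape
half-t(3, 10). All priors are configurable and recorded in the saved fit
bundle; they are deliberate weakly-informative stand-ins, since the
original prior specification is undocumented.

The sampler is a hybrid designed for this posterior's two failure modes:

* **Coefficients** | hyperparameters: preconditioned MALA (analytic
  gradient), 4 sub-steps per sweep, with the Laplace mass matrix
  `(α XᵀX + prior precision)⁻¹` rebuilt from the *current* hyperparameters
  every sweep (XᵀX is cached, so the p×p Cholesky is cheap), and the step
  size dual-averaged toward 0.574 acceptance during warmup.
* **Smooth sds**: univariate slice sampling, twice per sweep per term —
  once conditional on the coefficients (centered; fast when the term is
  strongly identified) and once rescaling the term's whole contribution
  (non-centered, interweaved; fast when the term is weak). This
  interweaving removes the usual funnel sticking.
* **Shape**: slice sampling on log α.

Chains run sequentially from per-chain seeded generators
(`default_rng([seed, 811, chain])`), so a fixed seed reproduces the
retained draws bit-for-bit. Retained draws = chains × (iterations −
warmup)/thin; the reference settings (4 × 10000, warmup 5000, thin 10 →
2000 draws) are the default, and the test suite uses 4 × 1000/500/2.
Convergence: split-chain rank-normalized Rhat (arviz) with pass = all
Rhat < 1.01 (operationalizing "all Rhat = 1"), plus bulk ESS; degenerate
(constant) parameters are excluded from the pass rule. Saved draws store
coefficients in the design basis, because the penalty eigenbasis has
sign/ordering ambiguity across rebuilds.

Posterior prediction always simulates the Gamma observation noise (one
outcome per retained draw and row). Exceedance uses strict inequality —
immaterial for continuous draws, fixed for determinism. Effect curves
report response-scale predictions along one predictor with fire areas at
zero and all other predictors at their training means (overridable), with
central 0.5/0.8/0.95 credible bands; wind terms are displayed over (speed,
direction-from) via the exact inverse of the U/V conversion
(direction = (270° − atan2(v, u)) mod 360, "180 = southerly").
Out-of-range grid points are flagged as extrapolation, never suppressed.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with all "truths" stored for recovery tests:

* **Weather**: daily synoptic latents (AR(1), ρ = 0.5) drive western wind
  speed and boundary-layer height (hence ventilation index) and, through a
  shared loading, inland wind speed; hourly series add AR(1) noise and
  diurnal profiles (boundary layer booms mid-afternoon; temperature peaks
  ~3 pm; winter minimum mid-season). The latent loading is the correlation
  target divided by a fixed attenuation constant 0.95, calibrated once for
  the default noise settings so the realized ventilation-index /
  inland-speed correlation lands on the target (default 0.7, the
  collinearity seen in the real predictors). Cloud is a logistic transform
  (in [0, 1]); boundary-layer heights are clipped positive.
* **Hotspots**: each day is active (default probability 0.6), isolated
  (1–2 scattered points, to exercise the active-day filter) or empty.
  Active days draw 1 + Poisson(0.8) clusters at uniform bearing and
  √uniform × 140 km range; cluster offsets are clipped to 2 km so every
  pair sits inside the 5 km linkage and the ≥ 3 rule is met by
  construction. Points get day (~1–3 pm) or night (~0:30–2 am next date)
  timestamps; 20% are duplicated with ~100 m jitter (swath overlap);
  optional decoys land beyond 150 km.
* **PM2.5**: the daily regional mean is Gamma(shape 12 by default) with
  log-mean = intercept + Σ effects + 0.03 × lag, the lag recursing through
  the previously generated day. Default effect shapes follow the fitted
  qualitative picture: decreasing in ventilation index, U-shaped in
  temperature with minimum at 19 °C, increasing-saturating in the fire
  areas, raised by easterly coastal afternoons and westerly inland flow.
  The intercept 1.45 puts typical regional means near 10 µg m⁻³. Station
  and hourly values are mean-one multiplicative perturbations renormalized
  so the daily regional mean is preserved exactly — the analysis consumes
  daily means, so sub-daily realism is not attempted. Optional per-hour
  missingness exercises the completeness rules.

Not emulated: reanalysis grid structure, satellite swath geometry, cloud
obscuration of hotspots, real Sydney climatology (marginal weather
distributions are pragmatic), and sub-daily pollution dynamics. Passing
tests therefore demonstrate that the pipeline's statistics behave as
designed when the model is correctly specified — not that the real data
meet those assumptions.

## Problem sizes and numerical choices in the test suite

The test suite runs everything at compact sizes chosen to make the
statistical checks sharp but quick: smooth recovery at n = 2000 rows × 10
replicates (frozen MISE tolerance 1e-3 on the log-mean scale, calibrated
once on that scenario); selection consistency at n ≈ 1000 × 20 replicates
with basis dimensions (6, 12); Bayesian agreement/calibration with 600
training and 500 held-out rows at 4 × 1000/500/2 MCMC; the pipeline smoke
test at 220 days. Numerical guards: linear predictors clipped at ±30;
Cholesky jitter on near-singular penalized Hessians; log λ clipped to
[−15, 18] inside REML; the Gamma shape MLE solved by Brent's method on
log α − ψ(α) = c and capped at 1e10 for numerically exact fits.

## Known limitations

* AIC overselection (above): the best model typically includes the true
  drivers plus a few weak extras; interpret selected weak terms with care.
* The fast search transfers the full model's smoothing parameters to
  submodels; the AIC ranking can differ slightly from per-model REML
  (available but ~50× slower).
* MALA/slice sampling is tuned for this model family; very small training
  sets combined with many 2-D terms leave the posterior weakly identified
  and may need longer chains than the test-scale settings.
* Sector areas assign whole footprints by centre bearing, so a footprint
  straddling a sector boundary is not split; with 500 m cells the effect
  is at most one cell per boundary-straddling cluster.
* The generator's lag for the first day of each March–September block has
  no prior day and the row is dropped, mirroring the real first-day-of-
  record behaviour.
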
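# Methods

## Visit independence and weekly counts

Trail cameras fire many images per animal visit. We delimit *independent
visits* per species per location by a minimum time gap: a new visit starts
whenever the interval since the previous image is **greater than or equal
to** one hour (a gap of exactly 60 minutes therefore separates two visits).
The gap is configurable; camera trigger delays (10–60 s) are far below it
and never split a visit, so they are treated as metadata only. Each visit is
scored by the maximum number of individuals in any single image — a
conservative lower bound on group size that is robust to animals wandering
in and out of frame — and weekly totals of these scores form the model
response (a `--count-mode visits` option counts visits instead).

Weeks are contiguous 7-day blocks anchored at the site's earliest camera
deployment (an ISO-anchored variant is available); anchoring at deployment
avoids a partial first week. Timestamps are taken as local site time with no
zone conversion. Effort is the overlap, in days, of merged camera
deployment intervals with each week; weeks with zero camera-days contribute
no observations (no pseudo-zeros), while partially operated weeks keep their
counts and let the log camera-day offset absorb the exposure difference.
For covariate alignment a week is attributed to the calendar month of its
start date; monthly *summaries* instead attribute each visit to the month of
its own start timestamp, which keeps monthly profiles exact while weekly
bins stay rectangular.

## Weather covariates

Four weekly covariates: TMAX = weekly mean of daily maximum temperature
(°C), RH = weekly mean of daily minimum relative humidity (%), P1 = weekly
precipitation total (mm), P6 = precipitation total over the week and the
previous five weeks (mm; the first five weeks of a series are undefined).
Daily statistics average over whatever hours were observed; a week with no
data yields a missing value, never a silent zero. Gaps are filled from an
ordered list of donor series (nearest logger first, then station), each
missing cell taking the first available donor value, with per-cell
provenance flags and a reported fill fraction. Observed cells are never
altered; cells missing everywhere are dropped from the model likelihood
rather than imputed.

Covariates are standardized (sample SD, n−1) over exactly the rows entering
a given fit, so effects are per-SD and comparable across species and sites;
the (mean, SD) pairs are retained for back-transformation. Collinearity is
screened pairwise: when Pearson |r| ≥ 0.60 the lower-priority column is
dropped, with a deterministic priority order (default TMAX > P6 > P1 > RH)
and a full decision report. The screen runs per fitted dataset. RH and P1
can be excluded per analysis by configuration (some site models do not
converge with them included).

## Count model

Weekly counts are negative binomial: a Poisson whose mean carries a
gamma(θ, θ) multiplicative deviate, giving pmf
Γ(y+θ)/(Γ(y+1)Γ(θ)) · (λ/(λ+θ))^y · (θ/(λ+θ))^θ, variance λ + λ²/θ, and the
Poisson limit as θ → ∞. θ is shared across locations and, by default,
species (per-species θ is a configuration option). The log mean follows an
observation-driven AR(1):

log λ[i,j,k] = α0[k] + Σ_v w[v,k] α[v,k] X[v,i,j]
               + δ[k]·g(1 + y[i,j−1,k]) + β[k]·h(λ[i,j−1,k]) + offset[i,j]

δ captures short-term dependence on last week's count, β long-term
dependence through the lagged mean. The default transforms are
g = h = log, the numerically stable log-linear autoregression; an
`ar_form="linear"` option uses identity transforms, which under the log link
grows explosively for positive coefficients and is provided for comparison
only. All coefficients are species-indexed, with slopes pooled across
species as α[v,k] ~ Normal(μ_v, σ_v²) — this pooling is how auxiliary
species (bobcat, jackrabbit, cottontail, elk, gray fox, oryx, pronghorn in
the motivating study) sharpen the focal species' variance estimates. For
predator species, the same-week standardized visit counts of their prey
enter as additional candidate covariates (candidate masks keep them out of
the prey models themselves).

Variable selection uses Bernoulli(0.5) inclusion indicators multiplying each
slope (Kuo–Mallick spike-and-slab). A covariate is flagged highly supported
when its posterior inclusion probability exceeds 0.70 — strictly: exactly
0.70 is not retained.

**Priors** (all configurable): α0, μ_v ~ Normal(0, 10²); σ_v ~
Half-Normal(1); δ, β ~ Normal(0, 1); θ ~ Gamma(0.01, 0.01) (shape–rate).
These are weakly informative on the log scale of weekly counts.

**Sampling.** Adaptive random-walk Metropolis for each continuous scalar
(proposal scales tuned toward 0.44 acceptance during burn-in by
Robbins–Monro on the log scale, then frozen so the kept chain is Markov),
conjugate Gibbs for μ_v, Metropolis on log σ_v and log θ, and exact
Bernoulli full-conditional draws for the indicators — when a covariate is
excluded its slope is refreshed from the hierarchical prior, which is what
makes the indicator's full conditional available in closed form. Four
chains with overdispersed starts are the default; a fixed seed reproduces
draws bit for bit. Production-scale runs use 4 × 150,000 iterations with
50,000 burn-in; the desk-scale preset (4 × 6,000 with 1,000 burn-in,
minutes on one CPU) is what the test suite and acceptance script use.

**Numerical choices.** The likelihood recursion starts at week 1 with
y[i,0,k] := 0 and λ[i,0,k] := exp(α0[k] + offset[i,1]) (a stationary-start
approximation; configurable through the start state). Cells with zero
effort or missing covariates are masked out of the likelihood; their lagged
count is imputed by the conditional mean so the recursion stays defined.
A log-mean above 30 on an in-likelihood cell rejects the proposal (the
public `linear_predictor` raises, naming the cell); on masked cells the mean
is clamped instead, so the guard never truncates the prior — a prior-only
run reproduces Pr(w) = 0.5 exactly. Log-scale proposals for σ_v and θ are
bounded at ±40 to avoid under/overflow in degenerate (no-data) regimes.

**Diagnostics.** Gelman–Rubin potential scale reduction per scalar
parameter, in the classic (non-split) form R̂ = sqrt(V̂/W) with
V̂ = (n−1)/n·W + (1+1/m)·B/n; duplicated chains give R̂ = 1 up to O(1/n).
We use 1.1 as the convergence yardstick. Slopes of covariates with low
inclusion probability mix by design between the spike (prior refresh) and
slab and are not meaningful convergence targets; R̂ is assessed on
identified parameters. Model adequacy uses a posterior-predictive Bayesian
p-value: replicate panels are drawn from the fitted negative binomial at
each (thinned) draw's conditional means — conditional on the observed
history, the standard replication for observation-driven models — and P_D
is the fraction of draws whose replicate discrepancy exceeds the observed
one. The default discrepancy is Freeman–Tukey Σ(√y − √λ)², robust for
overdispersed counts; a χ² form Σ(y−λ)²/(λ+λ²/θ) is available. Values near
0.5 indicate adequate fit; near 0 or 1, misfit.

## Seasonal summaries

Monthly profiles are computed per site-year and species: monthly summed
group counts divided by monthly camera-days, then normalized to sum to 1
over the twelve months. Only full years — all twelve months with positive
effort — are eligible. Profiles are effort-corrected *before* normalizing
and site-years are averaged with equal weight (matching summaries reported
as mean ± SD over N site-years), rather than pooling raw counts. The peak
window is the contiguous 4- or 5-month span maximizing the pooled mean
share; wraparound (e.g. Nov–Feb) is allowed and ties break to the earliest
start month. Window shares of any species inside the focal species' window
are reported with the uniform baselines width/12 (8.3% monthly, 33% and 42%
for 4- and 5-month spans). "Species a is r times more responsive than b" is
computed as the posterior ratio of standardized slope magnitudes
|α[v,a]|/|α[v,b]| (not exponentiated rate multipliers — the alternative is
one `exp` away but changes the number); the ratio is flagged unstable when
the denominator's credible interval covers zero, and cross-site summaries
aggregate per-site posterior-mean ratios as mean ± SD.

## Synthetic data

The generator produces every input the pipeline reads, with the statistical
structure the model assumes. Hourly temperature combines an annual sinusoid
(peak day-of-year 185, amplitude 12 °C around a 26 °C mean of daily maxima),
a diurnal sinusoid (±8 °C, peak 15:00) and Gaussian noise; relative humidity
runs on a phase-shifted cycle (trough day 120, before the monsoon) with
week-scale synoptic noise — the phase shift matters, because it keeps weekly
TMAX–RH correlation below the 0.60 screen, as in the field data the model
was designed for. Precipitation is a Bernoulli(0.1)-exponential(6 mm) daily
process, so P1 and P6 correlate at about 1/√6. Effort is ~7 camera-days per
week with 5% whole-week dropout. Counts follow the model's own forward
recursion at the true parameters: default α0 = (−1.0, −0.7, −1.3, −2.0),
TMAX effects (0.8, 0.5, 0.2, 0.3), RH (−0.3, −0.2, −0.4, −0.1), P1 all zero
(the variable-selection negative control), P6 (−0.5, −0.6, −0.3, −0.4),
δ = β = 0.15, θ = 2 — a temperature-driven seasonal concentrator (bighorn
analogue) plus three year-round species, at 10 locations × 104 weeks. The
gamma deviate is drawn once per location by default (location-level
overdispersion); `eps_mode="cell"` draws it per cell, giving the exact
marginal negative binomial the likelihood assumes — recovery and coverage
studies use this mode because it is the correctly-specified condition, while
the location-shared default adds the extra within-location dependence real
panels show. Weekly totals are decomposed into visits (group sizes ≥ 1
summing to the total, starts ≥ 2 h apart within the week) and visits into
image bursts (images < 1 h apart, per-image counts bounded by and attaining
the group size), so collapsing the stream recovers the generating visits
exactly — the round trip is an identity, not an approximation.

What the generator does *not* emulate: animal movement and behavioral
interaction between species, camera false triggers and misclassification,
imperfect detection, multi-camera interference at a location, and real
weather's spatial gradients between loggers. Passing recovery tests
therefore demonstrates the estimator is correct for the assumed data
structure, not that the model describes any particular field system.

## Problem sizes in tests

The suite fits desk-scale panels (10 × 104 × 4; 4 chains × 6,000
iterations), our chosen balance of statistical resolution against laptop
runtime: large enough that a standardized effect of 0.5 is selected
essentially always and 95% intervals attain near-nominal coverage, small
enough that a replicate study runs in minutes. Production analyses should
scale chains and iterations up, not down.

## Known limitations

- The sampler is single-site Metropolis: adequate at desk scale, slower
  mixing than gradient-based samplers on strongly correlated posteriors
  (α0–δ–β trade off along a ridge in short series).
- The model has no location intercepts; location-level heterogeneity enters
  only through the gamma dispersion and the AR feedback. On panels with
  strong location-shared heterogeneity (the generator's `eps_mode=
  "location"`), inclusion probabilities of weakly relevant covariates can
  inflate relative to the correctly-specified per-cell condition — a reason
  to read selection results jointly with the Bayesian p-value.
- P6 inherits its first five weeks as missing; model masks drop those weeks.
- The literal linear AR form is retained for fidelity but is numerically
  fragile; the log form is the supported default.
- Slope-magnitude ratios are unstable when the denominator slope is near
  zero; the unstable flag should be honored when summarizing.
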
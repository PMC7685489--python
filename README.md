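# watervisits

Tools for analysing wildlife visits to managed water sources ("catchments",
"drinkers") monitored by trail cameras in arid rangelands. The package was
built around a multi-year, multi-site camera study of desert bighorn sheep
(*Ovis canadensis nelsoni*), mule deer, coyotes and mountain lions at
managed waters in the Chihuahuan, Sonoran and Mojave deserts, and implements
that study's full analysis chain:

1. **Independent visits.** Camera images of one species at one location are
   collapsed into independent visit events: images one hour or more apart
   start a new visit; each visit contributes the maximum number of
   individuals seen in any single image, and these counts are summed per
   week to give the response `y[i,j,k]` (location *i*, week *j*, species
   *k*).
2. **Weekly weather covariates.** TMAX (weekly mean of daily maximum
   temperature), RH (weekly mean of daily minimum relative humidity), P1
   (weekly precipitation) and P6 (precipitation over the week plus the
   previous five weeks), built from hourly loggers and daily station data,
   gap-filled from ordered donor series, standardized, and screened so no
   model uses a covariate pair with Pearson |r| ≥ 0.60.
3. **Count model.** A hierarchical Bayesian multi-species negative-binomial
   autoregression,

   ```
   y[i,j,k] ~ NegBin(λ[i,j,k], θ)
   log λ[i,j,k] = α0[k] + Σ_v w[v,k] α[v,k] X[v,i,j]
                  + δ[k] log(1 + y[i,j-1,k]) + β[k] log λ[i,j-1,k]
                  + log(camera-days[i,j])
   ```

   with Bernoulli(0.5) inclusion indicators `w` (Kuo–Mallick variable
   selection; a covariate is highly supported when its posterior inclusion
   probability exceeds 0.70), species slopes pooled as
   `α[v,k] ~ Normal(μ_v, σ_v²)` so auxiliary species sharpen the focal
   estimates, shared dispersion θ, and a log camera-day effort offset.
   Fitting is by adaptive Metropolis-within-Gibbs MCMC with exact Bernoulli
   updates for the indicators; diagnostics include Gelman–Rubin R̂ and a
   posterior-predictive Bayesian p-value (Freeman–Tukey discrepancy).
4. **Seasonal summaries.** Effort-corrected monthly visit profiles per
   site-year, pooled per desert; the contiguous 4–5 month peak window; visit
   shares of other species inside the focal species' window (against the
   uniform baselines of 8.3% per month, 33% per 4 months, 42% per 5
   months); and standardized-slope ratios between species.
5. **Synthetic data.** Generators for hourly weather, camera logs, weekly
   count panels drawn from the model's own generative form, and image-level
   detection streams that collapse back to their generating visits exactly —
   so the entire pipeline runs and is tested with no external data.

## Worked example

```python
from dataclasses import replace
import watervisits as wv
from watervisits.synthetic import SimConfig, simulate_dataset

# a two-year, 10-location, 4-species synthetic study with per-cell
# gamma heterogeneity (the exact marginal negative binomial)
ds = simulate_dataset(replace(SimConfig(), eps_mode="cell", seed=1))

# image stream -> independent visits (one-hour rule)
visits = wv.collapse_visits(ds.detections)
effort = wv.compute_effort(ds.camera_log, ds.weeks)
weekly = wv.weekly_counts(visits, effort, ds.weeks)
print(len(visits), "visits,", weekly["y"].sum(), "summed group counts")

# fit the count model on the generator's design arrays
from watervisits.synthetic import model_from_truth
model = model_from_truth(ds.cfg, ds.truth)
res = model.fit(draws=2000, burn=1000, chains=4, seed=1)
print(res.summary())

# seasonal concentration of the temperature-driven species
import pandas as pd
profiles = [wv.monthly_profile(visits, ds.camera_log, "S1", yr, "bighorn")
            for yr in (2012, 2013)]
mean, sd, n = wv.pooled_profile(profiles)
window, share = wv.peak_window(mean, 5)
print("peak window", window, f"share {100 * share:.0f}%",
      f"uniform baseline {wv.uniform_baseline(5):.0f}%")
```

Output from this exact script (seed 1):

```
19046 visits, 27556 summed group counts
...
theta                 2.0022  0.0749   1.8621   2.1557  1.0016
...
peak window (4, 5, 6, 7, 8) share 91% uniform baseline 42%
```

The `summary()` table lists each parameter's posterior mean, SD, 95%
credible interval and R̂, followed by the covariate × species inclusion
probabilities. Here the April–August window holds 91% of the synthetic
bighorn's visits — far above the 42% a species visiting uniformly would
show — and the dispersion estimate's credible interval (1.86, 2.16)
brackets the generating value θ = 2.

A thin command line mirrors the library:
`watervisits simulate|ingest|build-design|fit|summarize --help`.

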
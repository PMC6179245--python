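# siteuse

Bayesian single-season site-use (occupancy) analysis for camera-trap
surveys across protection gradients.

Camera-trap networks photograph animals at fixed stations, but a blank
week at a station does not mean the animal was absent — detection is
imperfect. `siteuse` implements the full pipeline from raw time-stamped
photographic records to inference about where a focal species *uses*
the landscape and why: it builds weekly detection histories, engineers
the site covariates ecologists use for large carnivores (a
catch-per-unit-effort prey-biomass index, livestock pressure, distance
surfaces), fits a hierarchical Bayesian occupancy model with indicator
variable selection by MCMC, and checks the residuals for leftover
spatial autocorrelation. A synthetic-landscape generator reproduces the
statistical structure of a real multi-zone survey (national park /
wildlife management area / village land) with known truth, so the whole
pipeline is testable end-to-end.

## The model

Site $i$ in sampling area $a(i)$ is used with probability $\Psi_i$ and,
given use, detected in week $j$ with probability $p_{ij}$:

$$\mathrm{logit}(\Psi_i) = \alpha_{area(i)} + \sum_{c} w_c\,\alpha_c\,x_{ic},
\qquad Z_i \sim \mathrm{Bernoulli}(\Psi_i)$$

$$\mathrm{logit}(p_{ij}) = \beta_0 + \beta_k\,\mathrm{Trail}_i,
\qquad y_{ij} \sim \mathrm{Bernoulli}(Z_i\,p_{ij})$$

* $\alpha_{area} \sim \mathcal N(\mu, \tau^2)$ is an area-level random
  intercept absorbing spatial clustering;
* $x_{ic}$ are z-scored site covariates (livestock events, distance to
  river, distance to household, prey CPUE);
* $w_c \sim \mathrm{Bernoulli}(0.5)$ are Kuo–Mallick inclusion
  indicators: the posterior mean of $w_c$ is the probability that
  covariate $c$ belongs in the best of the $2^C$ candidate models, and
  averaging $w_c\,\alpha_c$ over the draws gives model-averaged
  coefficients;
* slopes and detection coefficients carry Uniform(−10, 10) priors;
  trail type (animal trail / no trail / road) is a three-level factor
  with animal trail as reference.

The sampler is Metropolis-within-Gibbs (numba-compiled): exact Gibbs
for the latent $Z_i$ and the indicators, conjugate Gibbs for $\mu$,
adaptive random-walk (plus occasional prior independence proposals) for
the coefficients. Convergence is checked with the classic split
Gelman–Rubin R-hat.

## Worked example

Simulate a survey at the default design scale (127 stations, 11 areas,
32 weekly occasions, ragged effort) and refit it:

```python
import siteuse

stations = siteuse.simulate_stations(seed=11)
cov = siteuse.simulate_covariates(stations, seed=12)
hist, records, stations, truth = siteuse.simulate_detection_data(stations, cov, seed=13)
print(siteuse.tabulate_by_zone(hist, records, stations))

zcov = siteuse.zscore_standardize(cov)
draws = siteuse.run_mcmc(hist, zcov, stations,
                         settings=siteuse.McmcSettings.reduced(seed=21))
print(siteuse.model_average_coefficients(draws))
```

Output (abridged):

```
               n_stations  n_stations_detected  n_events  effort_days
zone
national_park          77                   53       297         8370
wma                    16                    5        12         1613
village_land           34                    1         2         2994

                          w  mean_model_avg  sd_model_avg  mean_conditional
alpha[livestock]       0.90           -5.86          3.00             -6.52
alpha[dist_river]      0.10           -0.04          0.38             -0.42
alpha[dist_household]  0.83            2.54          1.88              3.06
alpha[cpue]            0.34            1.06          2.14              3.17

sites used: mean 76.8 sd 3.8 CI (69, 84)   max R-hat: 1.042
```

The generating truth had strong effects on livestock (−2) and distance
to household (+2) and zero effects on the other two covariates: the two
real effects are selected with high inclusion probability `w` and the
right signs, the null river covariate stays out of the model, and the
zone table shows the simulated protection gradient (heavy use inside
the park, a near-empty village land). The livestock coefficient
illustrates a real feature of such designs: because village stations
have livestock *and* no detections, the data only bound the effect from
above and the posterior stretches toward the prior bound, inflating the
magnitude — the same behaviour surveys of this type show in the field.

The same pipeline is scriptable from the shell:

```sh
siteuse simulate --seed 42 --out-dir sim/
siteuse history --records sim/records.csv --stations sim/stations.csv \
    --species leopard --start 2015-06-01 --out history.csv
siteuse fit --history sim/history.csv --covariates sim/covariates.csv \
    --stations sim/stations.csv --config model.yaml --out-dir results/
siteuse diagnose --history sim/history.csv --covariates sim/covariates.csv \
    --stations sim/stations.csv --bins 10 --out correlogram.csv
```

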
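# Methods

This note documents the modelling and numerical choices in `siteuse`:
what the pipeline computes, the defaults and why, what the synthetic
landscape does and does not emulate, and the known limitations of the
recovery harness.

## From records to detection histories

**Independent events.** Photographic bursts are collapsed with a
chained gap rule: within each (station, species) group, a record is
kept iff its gap to the previously *kept* record is strictly greater
than the independence window (default 5 minutes; a pair exactly 5
minutes apart counts as one event). Chaining to the retained record —
rather than to the raw predecessor or to the event start — makes the
filter idempotent, which the test suite asserts as an invariant.

**Occasions.** The survey timeline is one global calendar of
fixed-length bins (default 32 occasions of 7 days) shared by all
stations; stations that start late or stop early simply contribute
missing cells. A shared grid is what makes the sites × occasions matrix
well defined in a pooled single-season design. Station activity is
stored as half-open date windows `[start, end)`; the per-cell effort is
the number of active days intersecting each occasion. Occasions with
partial effort (1–6 active days) are treated as valid observations, not
missing — there is no standard per-occasion effort correction for this
design, and down-weighting partial weeks would require a detection
model per trap-day rather than per occasion.

The 32 × 7 = 224-day grid slightly exceeds the ~210 days such surveys
typically run; the number of occasions is a configuration value and
trailing all-missing occasions are harmless.

## Covariates

**CPUE prey index.** Relative prey biomass per station:
`cpue_i = 100 · Σ_s N_is · mass_s / effort_i` (kg per 100 trap-days),
where `N_is` counts independent events of prey species `s` and
`effort_i` is the station's total trap-days across the survey (not
per-occasion effort — the index is a season-level availability
measure). Default masses for the five prey species (bushbuck 45 kg,
common duiker 18 kg, greater kudu 200 kg, impala 50 kg, warthog 75 kg)
are field-guide adult averages and ship as an editable table.

**Livestock.** Cattle, goat and donkey records are independence-
filtered per species, then pooled into one event count per station —
the covariate measures overall grazing pressure regardless of species.

**Distances.** Distance-to-feature covariates are planar Euclidean
distances on a metric CRS, computed as 500 m rasters (cell value =
distance from the cell centre to the nearest feature point or
polyline), stored as plain-text ESRI ASCII grids, and sampled at
stations by containing cell with no interpolation. A station exactly on
a cell edge deterministically belongs to the lower-index cell. The
containing-cell rule discretizes the true distance by at most half a
cell diagonal (≈ 354 m at 500 m resolution), which the tests bound
explicitly. Geodesic corrections are negligible at landscape scale and
are not applied.

**Screening.** All covariates are z-scored (sample SD, n−1) before
fitting; the stored means/SDs let prediction curves be drawn in natural
units. Collinearity is screened with the conventional thresholds
|Pearson r| < 0.7 and VIF < 3, VIF computed by regressing each
standardized covariate on the others (perfect collinearity reports
VIF = ∞ and fails).

## The site-use model and its sampler

The model is the hierarchical zero-inflated Bernoulli occupancy model
stated in the README. Priors:

| parameter | prior | default | rationale |
|---|---|---|---|
| slopes α_c, β_0, β_k | Uniform(−10, 10) | — | "uninformative" on the logit scale; ±10 is far outside any plausible effect and wide enough that published fits of this model press against it under separation |
| μ (mean area intercept) | Normal(0, 10²) | — | weakly informative, BUGS/JAGS-style |
| τ (between-area SD) | Uniform(0, 10) | — | flat on the SD scale, standard for variance components with few groups |
| w_c, w_βk | Bernoulli(0.5) | — | indifferent prior over the 2^C model space |

Indicator selection follows the Kuo–Mallick construction: the linear
predictor uses the effective coefficient `w_c · α_c`, the indicator has
a closed-form Gibbs update given the current coefficient, and a
coefficient whose indicator is off refreshes from its prior (its full
conditional). Selection applies to all non-intercept terms, detection
contrasts included; both the model-averaged summary (mean of
`w_c · α_c`, zero when excluded) and the conditional-on-inclusion
summary are reported, since either convention appears in the
literature.

Sampler details:

* latent `Z_i`: exact Gibbs; a site with any detection has `Z_i = 1`
  with probability one; an all-zero site uses
  `P(Z=1) = ψq/(ψq + 1 − ψ)` with `q = Π(1−p)` over observed occasions.
  Missing occasions contribute nothing to the likelihood.
* detection depends only on trail type, so the detection likelihood
  reduces to per-trail sufficient statistics over currently-used sites;
  one full scan is O(n_sites), and the hot loop is numba-compiled
  (three chains of 500 000 iterations run in about a minute).
* coefficients: random-walk Metropolis with per-parameter scales
  adapted toward 0.44 acceptance during burn-in only (frozen afterwards
  so the retained chain has exactly the right stationary law), mixed
  with a 20% independence proposal from the prior. The independence
  component is what keeps weakly-identified coefficients mixing — with
  no data at all the coefficient marginals are exactly their priors,
  which the test suite verifies by Kolmogorov–Smirnov on thinned
  draws (KS requires near-independent samples, so it is applied to
  every 10th retained draw).
* μ: conjugate Gibbs given the area intercepts (or Metropolis on the
  occupancy likelihood when the random intercept is disabled); τ:
  random-walk Metropolis on the SD scale.
* one master seed fans out per-chain seeds through `SeedSequence`; every
  simulation and fit in the package is reproducible from its seed.
* default chain geometry is 3 × 500 000 iterations, 50 000 burn-in,
  thin 10; the test suite and diagnostics use 3 × 20 000 / 4 000 / thin
  5, which the grid-oracle comparison shows is already accurate to well
  under 1% on posterior means for small designs.

Convergence: classic split Gelman–Rubin R-hat (each chain halved,
`sqrt(((n−1)/n · W + B/n)/W)`), with < 1.1 as the working threshold;
the implementation is cross-checked against arviz's split estimator in
the tests. Degenerate edge cases: a site with `y = 1` and `p = 0` has
likelihood zero and the marginal log-likelihood returns −∞ rather than
raising; constant chains return R-hat ≈ 1.

The sampler is validated three independent ways: exhaustive enumeration
of the marginal likelihood for all detection patterns up to J = 4; a
dense-grid quadrature posterior on a 3-site instance (agreement on
posterior means to ~0.3%); and prior recovery on a fully-missing
design.

## Spatial diagnostics

Site-level residuals are `naive_use_i − E[Ψ_i | data]` (naive use = 1
iff the site ever recorded the species). The correlogram is
nonparametric: pairs are binned by distance (default 10 equal-width
bins to half the maximum pair distance), and each bin reports the
Pearson correlation over its residual pairs, each unordered pair
entering in both orders so the estimator is symmetric. Bins with fewer
than 5 pairs are reported missing. The 95% band comes from 200
bootstrap resamples of stations (resampled pairs that reuse the same
original station are dropped, since their zero distance and identical
residuals would fabricate correlation). A smoothing spline over pair
distances is a common alternative presentation; binning was chosen
because it has an explicit, testable contract per bin.

The diagnostic contrast fits the model twice: once with the area
random intercept (the full model) and once with τ fixed at 0 (a plain
logit model). On area-clustered landscapes the naive fit leaves
positive short-range residual correlation that the random intercept
largely absorbs; the test suite measures this as the mean absolute
correlation over the first three bins across replicate simulations of
a purpose-built clustered scenario (large between-area SD, zero
covariate effects, so all between-site structure sits at the area
level). Under the default truth the zone-structured covariates explain
much of the area signal even without the random intercept, and the
naive fit's short-range correlation can sit at the noise floor — the
reduction property needs genuinely area-driven data to be visible.
The random intercept is at the sampling-area level, matching the fitted
model (not at the station level, where a random intercept would be
confounded with the single Bernoulli response per station).

## The synthetic landscape

The generator mirrors the design of a real three-zone survey:

* **Stations:** 127 stations in 11 areas (77 national park / 16 WMA /
  34 village land), ≥ 1.5 km apart within areas, area centroids ≥ 15 km
  apart, zones laid out as west→east bands so zones are spatially
  segregated as in the field. (Published counts for the survey this
  emulates are internally inconsistent — a 127 total against per-zone
  counts summing to 128; the generator keeps the 127 total and gives
  one village area 8 stations.)
* **Effort:** per-area mean active days echo the real survey's ragged
  effort table — one long-running area (~177 days/station) and several
  short windows (19–118 days) — as single contiguous windows with
  ±20% jitter and random starts. Default totals come out near the real
  ~13 000 trap-days.
* **Covariates:** livestock counts are negative-binomial with
  zone-dependent means (≈0 in the park, heavy in village lands); CPUE
  is lognormal decreasing toward village lands; households cluster
  around village-area centroids (distance = nearest household); river
  distance comes from a fixed synthetic polyline near the park
  boundary. A `strength` parameter scales the zone contrasts; at 0 all
  covariates are drawn iid from pooled marginals, giving an
  exchangeable null landscape.
* **Truth:** defaults are μ = −0.75, τ = 1, slopes (−2, 0, +2, 0) for
  (livestock, river, household, CPUE), β₀ = −1.6 (p ≈ 0.17 per week),
  zero trail contrasts — signs and magnitudes chosen to reproduce the
  qualitative findings of such surveys: strong anthropogenic effects,
  no prey or river effect, detection ≈ 0.17, roughly 40–60% of sites
  used, and an (almost) empty village land.
* **Records:** every simulated detection cell emits ≥ 1 timestamp with
  gaps above the independence window, so the raw-records ingest path
  reproduces the simulated history exactly (asserted in the tests).

What it does **not** emulate: animal movement and home ranges (each
site's use is an independent Bernoulli given covariates and area),
within-season trends or closure violations, camera failures mid-window,
misidentification, and spatial autocorrelation beyond the area level.
Passing recovery tests therefore certify the estimator under the
model's own assumptions, not robustness to their violation.

## Known limitations of the recovery harness

The default landscape is — deliberately — as confounded as the real
survey it copies. Livestock occurs almost only in village lands, which
the strong household effect empties of detections, so the livestock
slope is bounded only from above (quasi-separation): its posterior
stretches toward the −10 prior bound, its magnitude is overestimated,
and its inclusion probability sits near 0.65 rather than near 1 even
though the true effect is large. The same confounding lets the
between-area SD τ absorb covariate signal, biasing it upward, and its
equal-tailed CI covers the generating value in somewhat fewer than 95%
of replicates at this design size.

Inclusion probabilities for truly-null covariates do not stay at the
0.5 prior under informative data: with a Uniform(−10, 10) slab, the
integrated likelihood of inclusion is penalized by the prior width
(the Lindley–Bartlett effect), and measured null-covariate inclusion
probabilities at this design size are ≈ 0.15–0.2. A 0.5 inclusion
probability for a null covariate is only reached when the data carry
essentially no information about that slope. Both behaviours are
properties of the model-plus-design, not of the sampler — the sampler
reproduces quadrature posteriors to a fraction of a percent — and both
have visible analogues in published fits of this model, where weakly
supported covariates print inclusion probabilities anywhere from 0.1
to 0.5 and separated coefficients press against the prior bounds.

Test-scale choices: the suite runs the sampler at 3 × 20 000
iterations and 20 replicates for the recovery and correlogram
harnesses; these sizes keep the full suite in the minutes range while
leaving Monte-Carlo error well below the tolerances being asserted.
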
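# Methods

`avitrend` implements a trend-analysis pipeline for long-term, multi-project
point-count surveys of breeding birds, together with a synthetic-data
generator that reproduces the statistical structure such surveys exhibit, so
every stage can be tested against known truth.

## The estimation problem

A point count records all birds seen or heard in a fixed time at a fixed
location; merged long-term datasets are typically heterogeneous, because the
contributing projects placed their sites differently across habitats and
years.  The surveyed covariate distribution therefore drifts over time
(environmental bias), and naive yearly means confound habitat drift with
population change.  Count data additionally show overdispersion and an
excess of zeros.  The pipeline addresses all three by (i) modelling counts
with covariate-adjusted regressions, (ii) comparing four likelihood
families, and (iii) predicting indices at *standardized* covariates so the
habitat composition is held fixed across years.

## Count models

For each species the breeding-pair count at a site is modelled with a log
link on

* survey year as a categorical factor (first surveyed year as reference),
* fixed-df cubic regression splines (df = 4, interior knots at covariate
  quantiles) for each land-cover fraction, elevation and slope,
* aspect sine and cosine as linear terms,
* a 3 x 3 tensor-product spline in the planar coordinates for residual
  spatial trend.

Four families are fitted by maximum likelihood: Poisson, NB2
(variance mu + mu^2/k), zero-inflated Poisson and zero-inflated NB2, the
zero-inflated pair adding a logit model for the structural-zero probability
on elevation and the 2500 m urban and forest covers.  Fitting is delegated
to statsmodels' discrete likelihood models; zero-inflated fits start from
the matching non-zero-inflated fit plus an empirical excess-zero intercept,
and a simplex restart is attempted when the gradient optimizer leaves the
likelihood's domain (the NB dispersion must stay positive).  Unpenalized
bases keep the parameter count, AIC and the coefficient covariance exactly
defined; the basis type and knot rule are this package's choice, since
fixed-df smooths only pin down the dimension, not the basis.  Aliased
columns are removed once by pivoted QR and the reduced design is frozen so
prediction uses the identical matrix.

The best family is the minimum-AIC converged fit, ties going to the simpler
family (P < NB < ZIP < ZINB).  Explained deviance is reported per
likelihood component against the component-wise reduced model
(intercept-only count part or intercept-only zero part), measured on the
saturated-likelihood deviance scale; for plain families this is the usual
GLM deviance explained.

## Population indices

The yearly index is the model's unconditional expected pairs per site,
(1 - pi) * mu for zero-inflated families, evaluated on one standardized
covariate row per surveyed year: land-cover values follow a polynomial
smooth of degree min(4, number of snapshots - 1) fitted to the land-cover
snapshot means and clamped to [0, 1]; topography is fixed at its overall
mean and the coordinates at the area centroid.  When the minimum convex
hull of a species' presence points covers less than 80% of the region, the
covariate extraction (snapshot means, topographic means, centroid) is
restricted to that hull; the hull does not restrict the fitting data.
A single standardized covariate vector is used rather than an averaged
site grid — the simpler of the two readings, applied uniformly.

Uncertainty comes from a parametric bootstrap of the coefficients: B draws
from N(theta_hat, Sigma_hat) (Sigma_hat the inverse observed information;
small negative eigenvalues are clipped, a strongly indefinite matrix is an
error), with the median as the index and the 2.5th/97.5th percentiles
(type-7 interpolation) as the 95% band.  Response data are not re-simulated.
The NB dispersion is drawn along with the other coefficients since it is
estimated jointly, but it does not enter the mean prediction.  Indices
exist only for surveyed years, since year is a factor.

## Trends

The long-term trend is a weighted least-squares regression of the median
index on calendar year with weights 1/CI-width.  Significance is judged at
p <= 0.05 on the slope's t statistic (n - 2 df).  The percent change T% is
computed from the WLS fitted values at the series' first and last year —
fitted endpoints, not raw medians, so noisy endpoint years do not dominate.
Adjusted R^2 is floored at zero.  A year with zero CI width has its weight
capped at ten times the largest finite weight; an all-zero-width series
falls back to OLS with a warning.  Significant trends with T% < -50 are
flagged as steep declines.  Yearly indices are serially dependent, so the
p-values are approximate; no autocorrelation correction is applied.

## Traits and functional groups

Eight categorical traits are derived per species: migration strategy;
dispersal ratio (wing length / cube root of body mass); annual fecundity
(clutch size x broods per year, brood parasites forced to one brood);
incubation period; diet by the 70% rule (scavenging counts toward
vertebrates); nest type reclassified to elevated / ground / hole nesters;
landscape type by the strict >50% median-cover rule; and an overall
specialization index.  Numeric traits are discretized at the first and
third type-7 quartiles with inclusive boundaries; the published cut-offs
(28.278/33.737 for dispersal ratio, 5/10.625 for fecundity, 13/17.25 days
for incubation) ship as reference constants and can be supplied instead of
recomputing.

The per-axis specialization index on binary usage data is the coefficient
of variation (population SD over mean) of the usage vector across the
axis's resource categories — 0 for a species using every category,
sqrt(K - 1) for a single-category user — and the overall index is the mean
of the five axes.  The source index is defined on frequency data; this
binary-data arithmetic is the package's documented reading, isolated in one
function.

Trait redundancy is screened with Cramer's V on every pair of categorical
traits (chi-square test without continuity correction; Fisher's exact test
for 2x2 tables with any expected cell below 5 — no exact r x c test is
available, so larger sparse tables keep the chi-square path and are flagged
in the report).  Pairs significantly associated with V >= 0.5 are flagged;
by default the member with the higher mean V is dropped, or an explicit
drop list can be supplied.

For each trait, species index series are first normalized by their own
first-year median (late entrants by their first recorded year), then pooled
into one weighted linear model, index ~ group + year + year:group with
weights 1/normalized-CI-width.  Species-level random effects are not used —
the grouped model is a fixed-effects weighted regression, a known
simplification.  Group slopes (year + interaction) are tested against zero
and against each other with finite-sample F statistics on linear contrasts;
single-constraint tests satisfy F = t^2 exactly.

## Synthetic data generator

The generator emulates: spatially autocorrelated covariates (low-rank
Gaussian random fields from random Fourier features, correlation length
8 km by default); 17 land-cover fractions by a logistic-normal construction
over 18 classes (17 + remainder), so fractions are in [0, 1] and sum to at
most 1, with slow linear drifts (urban up ~1%/yr on the latent scale,
arable down, forest up) so decade-scale snapshot tables change; a 500 m
minimum spacing within each survey year, with an explicit square-packing
capacity check; epoch-dependent sampling weights over covariate space to
emulate multi-project environmental bias; Poisson/NB2 counts with optional
structural zeros driven by elevation and landscape-scale covers; log-linear
true year trends, optionally shared within configured trait groups; and
gregarious species whose emitted individual counts are
(pairs - 1) * CF + U{1..CF}, so ceiling division by the conversion factor
recovers pairs exactly (the distribution of individuals per detected group
is not documented anywhere; bounded uniform noise is a stand-in).  Default
temporal frame: survey years 1992-2019 without 1993-94 and 1997-98, and
snapshot years 1980/1999/2007/2012/2015/2018.

It does not simulate real GIS rasters, within-season repeat visits, or a
detection process, so passing tests say nothing about detectability bias in
real surveys; they do validate the estimation chain under the model's own
assumptions.

## Validation experiments and problem sizes

`avitrend.experiments` measures operating characteristics, at sizes chosen
to run in minutes on one core:

* **Trend-test size** — 1000 flat-truth series over the 24 survey years;
  per-year noise SD drawn from U(0.05, 0.15) (roughly the 2-3x CI-width
  heterogeneity implied by the survey's 373-1443 yearly point counts) and
  CI width set to the matching normal width, so weights relate to the noise
  exactly as in the real pipeline.  Expected rejection near 0.05.
* **Family selection** — 100 replicates of a well-separated ZINB truth
  (n = 5000, dispersion k = 1, structural-zero probability around 0.45);
  the AIC winner is scored against the truth.
* **Bootstrap coverage** — 200 replicates of a Poisson year-factor model
  (480 site-years), B = 200; pooled coverage of the true yearly index by
  the 95% band.
* **Group-slope recovery** — 20 species per group with linear normalized
  trends (-0.02 farmland, +0.01 woodland), noise SD 0.05; estimates must
  fall within 3 SEs of truth.
* **Sign recovery** — the full pipeline (site placement, simulation, pair
  conversion, selection, bootstrap, weighted trend) on 12 species with
  |true log-trend| >= 0.02, 100 sites/year over 12 years, B = 200.

`scripts/acceptance.py` reruns all of these plus the packaged-table
roll-ups from a single seed and writes the numbers as JSON.

## Known limitations

Fixed-df unpenalized smooths rather than penalized smoothness selection;
no detection probability; no temporal autocorrelation correction in the
trend test; no species-level random effects in the group models; the
coefficient bootstrap reflects asymptotic-normal uncertainty only.  These
mirror the method being implemented rather than gaps to be closed.
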
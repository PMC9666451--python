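# Methods

## Model

`karstocc` implements a single-season, two-taxon site-occupancy model with
imperfect detection. The latent occurrence state of taxon *i* at sampling
unit *j* is `z_ij ~ Bernoulli(ψ_ij)`; each survey's outcome is
`y_ijk ~ Bernoulli(z_ij p_ijk)`. The model admits no false positives: a
single detection fixes `z_ij = 1`. Units are treated as independent given
their covariates — there are no site-level random effects, spatial terms,
or between-taxon co-occurrence terms.

Occurrence covariates are site-level (units within a site share values):
the human disturbance index (natural log, then standardized) and dominant
lithology (limestone = 1, dolostone = reference). Detection covariates
are unit-level — water volume (log m³, standardized), water-column
velocity (flowing = 1), substrate (fine = 1) — plus the survey-level
method dummy (visual = 1, eDNA = reference) and its interactions with
velocity, substrate, and volume.

Taxa use a means parameterization: each taxon carries its own absolute
coefficient rather than a difference from a reference taxon, which leaves
the likelihood identical to dummy coding (verified numerically in the
test suite) but makes each coefficient directly interpretable. Two
detection terms — the velocity main effect and the method-by-velocity
interaction — are pooled across taxa; every other term is taxon-specific.
The parameter vector therefore has 20 entries: 6 occurrence (intercept,
disturbance slope, lithology effect per taxon) and 14 detection.

## Disturbance index

The index for a site is `Σ_c proportion_c × w_c` over the land-use
classes of a 500-m buffer, with fixed weights: open-space development
1.83, low- and medium-intensity development 7.31, high-intensity
development 8.67, pasture/hay 2.99, cultivated crops 4.54, and 1.00 for
the aggregate `undisturbed` class that absorbs everything else (water,
barren, forest, ...; callers pre-aggregate). Being a convex combination,
the index lies in [1.00, 8.67] for any valid composition, is monotone in
shifting mass toward higher-weight classes, and is permutation-invariant.
Compositions must sum to 1 within 1e−6; renormalization is available only
behind an explicit flag because a bad sum usually signals an upstream GIS
error. Buffer construction itself (GIS) is out of scope — the package
consumes the resulting proportion table.

## eDNA aggregation

Each water sample yields two extraction subsamples run in qPCR
triplicate: six pseudoreplicates per unit and taxon. A unit is positive
if any clean-plate pseudoreplicate amplified. A plate on which any
negative plate control amplified is discarded wholesale *before*
aggregation, and samples seen only on discarded plates are recorded as
missing rather than zero — a contaminated run is evidence of nothing.
Amplified field negative controls are reported but do not automatically
invalidate co-collected samples; reporting is the conservative default in
the absence of an established invalidation rule. Cq values, standard
curves, and assay specificity are wet-lab concerns outside the package.

## Transforms and screening

Volume and disturbance are log-transformed first (both are right-skewed)
and then standardized to mean 0, sd 1 with the sample (n−1) standard
deviation; the realized (mean, sd) pairs are stored in a `TransformSpec`
so model-scale and raw-scale values map back and forth exactly.
Standardization statistics are computed over the J sampling units, with
site-level values repeated per unit, because the model is indexed at the
unit level; nothing in the data dictates pooling at the site level
instead, and the choice is recorded and auditable in the
`TransformSpec`. Zero-variance continuous covariates and constant
lithology raise errors (no contrast to estimate); constant velocity or
substrate only warn, since those columns are not standardized.

Candidate occurrence covariates are screened by pairwise Pearson
correlation among continuous variables (|r| > 0.65 flags a pair; the
non-disturbance member is listed for exclusion) and by point-biserial
correlation against lithology. Elevation range and NDVI enter only this
screening step, never the model.

## Priors and likelihood

Every coefficient has an independent Uniform(−10, 10) prior by default —
logit-scale effects beyond ±10 are numerically saturated — with bounds
configurable per parameter. All Bernoulli terms are accumulated in log
space as `log σ((2y−1)η)` via `log_expit`; the per-unit marginal with z
summed out is `ψ Π p^y (1−p)^(1−y)` when any detection occurred and
`ψ Π(1−p) + (1−ψ)` otherwise, combined with `logaddexp`. The joint
density returns −∞ (never raises) outside the prior support or when a
latent absence coexists with a detection.

## Sampler

Posterior sampling is Metropolis-within-Gibbs, written from scratch:

1. each `z_ij` is drawn exactly from its full conditional — forced to 1
   where any detection occurred, otherwise Bernoulli with logit
   `logit(ψ_ij) + Σ_k log(1−p_ijk)`;
2. each coefficient takes a single-parameter Gaussian random-walk
   Metropolis step on the joint log density, using cached linear
   predictors so an update costs O(surveys).

Proposal scales adapt every 50 iterations during burn-in toward a 0.35
acceptance rate (multiplicative update, clipped to [1e−3, 50]) and are
frozen at the end of burn-in, so the retained draws come from a fixed,
detailed-balance-preserving kernel. Chains start at 0 (or the prior
midpoint when 0 is outside the support), with z initialized at 1 wherever
a detection occurred and Bernoulli(0.5) elsewhere. One master seed yields
per-chain `SeedSequence(seed, chain)` streams; runs are bit-reproducible.
Default run length follows the motivating study: two chains of 55,000
total iterations, the first 5,000 discarded as burn-in, no thinning.

A second sampler (`marginalized=True`) integrates z out analytically and
runs the same adaptive random-walk on the coefficients alone. It targets
the identical coefficient posterior and serves as an internal
cross-check; the test suite verifies both samplers against deterministic
two-dimensional grid quadrature on a reduced intercept-only model, using
the spread of independent chain means as the Monte Carlo standard error
(within-chain estimators such as batch means proved optimistic for the
weakly identified occupancy intercept, whose chain makes rare excursions
along the ψ–p ridge).

## Diagnostics

**R̂.** The Brooks–Gelman–Rubin potential scale reduction factor,
`sqrt(((n−1)/n · W + B/n) / W)` from the within- (W) and between-chain
(B/n) variances of the retained draws; values below 1.1 are read as
adequate mixing. Constant chains return NaN with a warning.

**HDI.** The 95% highest-density interval is the shortest contiguous
window over the sorted draws containing ⌈0.95 n⌉ points, ties broken
toward the lowest window; at least 20 draws are required. On a
multimodal posterior this still returns one contiguous interval — a
recorded limitation.

**Bayesian p-value.** The posterior predictive check replays a
discrepancy statistic over evenly spaced retained draws and reports
`P(T_rep ≥ T_obs)`; 0.10–0.90 is read as adequate fit. The default
statistic is the number of (taxon, unit) pairs with at least one
detection, with the replicate drawn from the full generative model
(fresh `z_rep ~ Bernoulli(ψ)`, then detections) and a mid-p correction
for ties. This choice is deliberate: calibration simulations on
correctly specified synthetic data showed the more traditional
Freeman–Tukey measure on per-unit detection sums, conditioned on the
drawn latent states, reads systematically low under the broad uniform
priors — all-zero detection histories at units drawn occupied contribute
`(0 − √E)²` to the observed arm, an event the replicate arm rarely
reproduces — with one-sided p-values clustering near 0.05–0.35 (a
deviance discrepancy behaves the same way). The detected-units count was
well centred in the same simulations. The Freeman–Tukey statistic
remains available (`statistic="freeman_tukey"`, and
`posterior_predictive_discrepancy` for a single draw), and the two should
be read together when fit is in doubt.

**Prediction curves.** `predict_occurrence` maps a raw disturbance grid
through the stored transform, evaluates ψ per retained draw with
lithology held fixed, and reports the posterior mean with a 95% HDI band
per grid point, warning when the grid leaves the index's attainable
[1.00, 8.67] range.

## Synthetic data

The generator emulates the motivating field study's design: 21 cave, 12
spring, and 7 well sites holding 61 sampling units (one per site, the
remainder allocated to caves), each surveyed on 1–5 occasions (occasion
distribution with mean ≈ 1.9, matching ≈ 233 surveys over 61 units at
two methods per occasion). Covariates echo the observed field
distributions: site lithology limestone with probability 43/61; water
volume log-normal with log-mean 3.34 and log-sd 1.28 (mean ≈ 64 m³,
sd ≈ 130 m³), clipped to the observed 0.6–800 m³ range; disturbance
1 + Gamma(1.06, 0.96) clipped at 8.67 (mean ≈ 2.02, sd ≈ 0.99 on the
index scale), realized as an exact two-class land-use composition so the
index round-trips through the scorer without error; velocity and
substrate Bernoulli at the observed 128/233 and 34/61 splits. Detections
are then generated by the exact model equations under supplied truth
coefficients — by default the posterior means estimated in the Ozark
Highlands study, so recovery experiments exercise realistic effect
sizes.

What the generator does **not** emulate: spatial autocorrelation among
sites, covariate measurement error, occasion-level variation in
unit-level covariates (volume, velocity, and substrate are fixed per
unit, as the schema stores them), taxon-level heterogeneity within the
two species groups, or any false-positive detection process. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness of the model
to real-data violations of them.

`recovery_experiment` repeatedly simulates and refits, reporting
per-parameter bias, RMSE, 95% HDI coverage, and sign recovery, excluding
(and counting) replicates where any R̂ reaches 1.1.

## Numerical and design notes

* Proposal adaptation happens only during burn-in; acceptance rates are
  reported from the post-burn-in phase only.
* `summarize` pools draws across chains for means, sds, and HDIs and
  degrades the HDI to the sample range below 20 pooled draws.
* Test-suite problem sizes: enumeration oracles run at ≤ 3 units × 3
  surveys; the quadrature cross-check uses 30 units × 5 surveys with
  8 × 15,000 retained draws; recovery runs 50 replicates of the 61-unit
  scenario at 2 × 6,000 retained draws after 1,000 burn-in; calibration
  of the p-value uses 20 replicates at 2 × 2,500. These sizes were chosen
  so the full suite completes in a few minutes on one core while leaving
  Monte Carlo error well below the tolerances tested.

## Known limitations

* Frequentist coverage of 95% HDIs is near-nominal for well-identified
  parameters but genuinely degrades for one-sided-identified ones: in
  replicates where a taxon is never detected in one lithology class, its
  occurrence intercept is bounded only from above by the likelihood, the
  posterior slides to the lower prior bound, and the HDI can exclude the
  generating value. At the default study scale and effect sizes this
  affects the cave crayfish occurrence intercept (observed coverage
  ≈ 0.78–0.81 versus nominal 0.95, driven by the ≈ 22% of replicates with
  zero crayfish detections on dolostone units). This is a property of
  bounded vague priors at a fixed truth, not of the sampler; widening the
  prior worsens it.
* The HDI is contiguous by construction; heavily multimodal posteriors
  would be summarized poorly.
* Detection covariates are stored per unit; if field protocols re-assess
  volume or velocity per occasion, the schema (and model) would need an
  occasion index on those columns.
* The Bayesian p-value, like all posterior predictive checks, reuses the
  data and is not a frequentist test; its band is a screening heuristic.
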
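# karstocc

Bayesian two-taxon site-occupancy modelling for karst stygobionts —
cavefishes and cave crayfishes surveyed by environmental DNA and visual
methods in caves, springs, and wells.

Groundwater-obligate species are cryptic: a survey that finds nothing does
not demonstrate absence. `karstocc` separates *occurrence* from *detection*
with a hierarchical occupancy model, and wraps the full analysis path
around it: a land-use **disturbance index** for each site, **qPCR
pseudoreplicate aggregation** with negative-control QC for the eDNA data,
covariate **transforms and screening**, a from-scratch **MCMC sampler**,
convergence and fit **diagnostics**, occurrence-probability **prediction
curves**, and a **synthetic-data generator** with known truth so the whole
pipeline is testable end to end.

## The model

For taxon *i* at sampling unit *j* with repeat surveys *k*:

```
z_ij  ~ Bernoulli(ψ_ij)                      true occurrence state
y_ijk ~ Bernoulli(z_ij · p_ijk)              detection given presence
```

so a detection implies presence (no false positives). Both probabilities
get logit-linear models. Occurrence depends on the site's human
disturbance index (log, standardized) and lithology (limestone vs
dolostone reference):

```
logit(ψ_ij) = γ_i + β1_i · disturbance_j + β2_i · lithology_j
```

Detection depends on water-column velocity X1 (flowing vs not), survey
method X2 (visual vs eDNA), substrate X3 (fine vs coarse), and water
volume X4 (log m³, standardized), with method interactions:

```
logit(p_ijk) = α1_i + α2 X1 + α3_i X2 + α4 X1 X2 + α5_i X3 + α6_i X4
               + α7_i X2 X3 + α8_i X2 X4
```

Taxa are coded by a means parameterization (each taxon has its own
absolute coefficient); the velocity main effect α2 and the
method-by-velocity interaction α4 are pooled across taxa, giving 6
occurrence and 14 detection parameters. Coefficients carry broad
Uniform(−10, 10) priors.

The disturbance index is a proportion-weighted sum of fixed land-use
coefficients within a 500-m site buffer — open-space development 1.83,
low/medium-intensity development 7.31, high-intensity development 8.67,
pasture/hay 2.99, cultivated crops 4.54, everything else (undisturbed)
1.00 — so it ranges from 1.00 (fully undisturbed) to 8.67 (fully
high-intensity development).

## Worked example

Simulate a study shaped like the motivating Ozark Highlands field study
(61 sampling units in 40 sites, 1–5 occasions, eDNA + visual per
occasion), then fit it:

```sh
karstocc simulate --seed 42 --units 61 --out data
printf 'mcmc:\n  n_iterations: 15000\n  n_burnin: 3000\n  seed: 7\n' > config.yaml
karstocc fit --sites data/sites.csv --units data/units.csv \
             --surveys data/surveys.csv --config config.yaml --out fit
head -7 fit/summary.csv
```

```
parameter,mean,sd,hdi_low,hdi_high,rhat
cave_crayfish_occ_intercept,-4.112715982697913,1.4021592552891189,-6.845179991038139,-1.5486835463964954,1.0072486678578794
cavefish_occ_intercept,-1.0567250628879028,0.8068703548002784,-2.7460368789805383,0.4680009749761206,1.0005653998392696
cave_crayfish_occ_disturbance,-2.2255821738930512,0.649222365119894,-3.513664540499064,-1.0321831215165138,1.0002658327749843
cavefish_occ_disturbance,-0.2363939586884701,0.47660882842567254,-1.179916754176771,0.66188286870718,0.999994803395376
cave_crayfish_occ_lithology,4.9290981359226205,1.5805104947655064,2.0965894724903955,8.078258697241647,1.004727604968546
cavefish_occ_lithology,2.9275703888876183,1.2213527718349257,0.7737840573395562,5.2337738597402845,1.0002250376823139
```

Each row is a posterior mean ± sd with a 95% highest-density interval and
the Brooks–Gelman–Rubin R̂. Here the generating truth for the crayfish
disturbance slope was −1.37; the fit recovers a clearly negative effect
(mean −2.23, HDI (−3.51, −1.03)) and a positive limestone effect, while
R̂ ≤ 1.008 indicates the two chains mixed. `fit/diagnostics.json` adds a
posterior-predictive Bayesian p-value (0.286 for this run — inside the
0.10–0.90 adequacy band, as expected for correctly specified data), and
`fit/predictions.csv` tabulates ψ against the raw disturbance index per
taxon: for cave crayfish on dolostone the curve drops from ψ ≈ 0.46 at
index 1.0 to ψ ≈ 0.05 by index 1.6.

Other entry points: `karstocc disturbance score` (site indices from
land-use tables), `karstocc edna aggregate` (qPCR pseudoreplicates →
binary detections plus QC report), `karstocc recover` (simulate-and-refit
bias/coverage experiments), `karstocc summarize` and `karstocc predict`
(re-derive outputs from stored draws). The same operations are available
as library functions (`karstocc.fit_study`, `karstocc.generate_study`,
...).

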
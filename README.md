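# mrrake

Small-area prevalence estimation by **multilevel regression with raking** —
MRP for the common situation where the census publishes only *marginal*
population distributions, not the full joint table the classical method
requires.

## The problem

Health surveys (BRFSS-style telephone surveys, for instance) are sized for
national or metro-level estimates; individual counties rarely have enough
respondents for a reliable direct estimate of, say, the share of adults
with a dental visit in the past year. Multilevel regression and
post-stratification (MRP) borrows strength across areas: fit a hierarchical
outcome model on the survey, predict the outcome probability for every
socio-demographic cell in every county, and average those predictions
weighted by the census count of each cell. The catch is that MRP needs the
**joint** population distribution over all stratification factors (e.g.
age-sex × education × race/ethnicity = 240 cells per county), and census
products typically publish only margins (a joint age×sex table, one-way
education and race distributions).

`mrrake` closes that gap with a hybrid estimator:

1. **Fit** a random-intercept multilevel logistic model on the survey
   microdata: `logit(p_ij) = x_ij'β + z_i'η + μ_i`, with `x_ij` the
   dummy-coded individual factors, `z_i` continuous area covariates (e.g.
   percent below poverty), and `μ_i ~ N(0, σ_μ²)` an area random effect.
   Estimation is exact maximum likelihood via adaptive Gauss–Hermite
   quadrature (the random-intercept structure makes the marginal
   likelihood one-dimensional per area).
2. **Predict** `p̂_i(cell)` for every post-stratification cell of every
   target area — including areas with no survey respondents.
3. **Rake**: estimate the joint cell counts `N̂_i(cell)` per area from the
   known margins by iterative proportional fitting, with margins allowed
   on arbitrary factor subsets (a two-way age×sex margin plus one-way
   margins is the canonical case) and a uniform seed so *every* weighting
   cell receives mass, sampled or not.
4. **Post-stratify**: `p̂_i = Σ_cells N̂_i(cell) p̂_i(cell) / N_i`.
5. **Quantify uncertainty** with a stratified case-resampling bootstrap
   (respondents resampled within areas, census counts held fixed),
   percentile intervals; for areas outside the survey the unobserved
   random intercept is drawn parametrically per replicate so their
   intervals behave like prediction intervals.

A synthetic-data module generates multi-county populations with
*dependent* categorical factors (pairwise log-linear interactions — the
regime where raking beats the independence approximation), logistic
outcomes with county random effects, and metro-style survey coverage
(5 surveyed areas out of 58 by default), so the whole pipeline is testable
end to end without any restricted data.

## Worked example

```python
import mrrake as m

# a synthetic study at the default conditions: 58 areas, 5 surveyed,
# 240 cells (age-sex 6x2, education 4, race/ethnicity 5), n ≈ 7,200
cfg = m.default_config()
pop, margins, survey = m.generate_dataset(cfg)

spec = m.ModelSpec(fixed=["age_sex", "education", "race"],
                   area_covariates=["pct_poverty"])
fit = m.fit_multilevel_logistic(survey, pop.covariates, spec)
print(f"sigma_mu = {fit.sigma_mu:.3f}, eta = {fit.eta[0]:+.3f}")

preds = m.predict_cell_probabilities(fit, pop.scheme, pop.covariates,
                                     pop.area_ids)
raked = m.rake_all_areas(pop.scheme, margins)
estimates = m.poststratify(preds, raked)

vals = sorted(100 * e.estimate for e in estimates)
print(f"county estimates range {vals[0]:.1f}–{vals[-1]:.1f}%")
```

prints

```
sigma_mu = 0.143, eta = -0.568
county estimates range 33.4–93.4%
```

i.e. the fitted between-county SD on the logit scale, the poverty
coefficient per SD (negative: poorer counties use dental care less, as
generated), and the cross-county spread of the post-stratified estimates.
Spearman rank correlation with the true simulated prevalences on this run
is 0.865 across the 58 areas, 53 of which have no survey respondents.

The same pipeline is scriptable from the shell:

```bash
mrrake simulate --profile default --seed 42 --out data/
mrrake estimate --config pipeline.yaml --bootstrap 1000 --seed 20180101 --out out/
mrrake validate --model out/estimates.csv --direct direct.csv --out report.json
```

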
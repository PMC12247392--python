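# Methods

## The estimator

`mrrake` implements a hybrid small-area estimator for a binary outcome
observed in a survey that covers only a subset of the areas for which
estimates are wanted, when the census provides cell population counts only
as marginal distributions.

**Outcome model.** For respondent `j` in area `i`,

    logit(p_ij) = x_ij' β + z_i' η + μ_i,        μ_i ~ N(0, σ_μ²)

- `x_ij`: dummy-coded categorical individual factors (the
  post-stratification factors, or a subset). The first declared level of
  each factor is the reference; any full-rank coding yields identical
  predictions.
- `z_i`: continuous area-level covariates (standardized units recommended;
  the synthetic generator draws them N(0,1)).
- `μ_i`: area random intercept. Setting `random_intercept=False` replaces
  it with fixed area-indicator dummies (first sampled area as reference) —
  the fixed-effect model variant, fitted by ordinary binomial GLM.

The fit is **unweighted maximum likelihood**: every respondent counts
once. Survey weights present in the data are carried through I/O but
ignored by the fitter, with a warning.

**Estimation.** Respondents sharing an (area, cell) pair are collapsed to
binomial rows, so likelihood cost scales with occupied cells, not
respondents. The random intercept is integrated out per area with
*adaptive* Gauss–Hermite quadrature: the integrand is recentred at the
per-area posterior mode (found by a safeguarded Newton iteration; the
inner objective is strictly concave) and scaled by the local curvature,
with 15 nodes by default. L-BFGS-B maximizes over (β, η, log σ_μ), with
log σ_μ bounded in [log 1e−6, log 20] so the σ→0 boundary is reachable
(fits at the boundary reproduce the ordinary logistic MLE to ~1e−6).
Gradients are analytic with the quadrature nodes held fixed at the current
adaptation; the omitted terms are of the order of the quadrature error
itself (verified against finite differences at ~1e−8). Convergence
requires the optimizer's own criterion or a gradient max-norm below 1e−3;
otherwise a `FittingError` with diagnostics is raised. Coefficients
exceeding 30 in absolute value are treated as separation divergence.
Standard errors come from the numerically differentiated observed
information.

The fitter was cross-checked against an independent implementation of the
same likelihood (R lme4 `glmer`, nAGQ=25) and agrees to five decimals on
coefficients, σ̂_μ, log-likelihood, and posterior-mode random effects;
that check is part of the test suite. Like any ML variance-component
estimate, σ̂_μ carries a small downward finite-sample bias when few areas
are sampled (there is no REML analogue here); with 3 sampled areas σ̂_μ
is exactly 0 in over half of simulated replicates.

**Prediction for post-stratification cells.** For each target area and
each cell, `p̂ = expit(x'β̂ + z'η̂ + μ*)`. The random-effect plug-in `μ*`
follows one of three policies:

- `conditional_blup` (default): the area's posterior mode if the area was
  surveyed, else 0 (the best predictor of an unobserved group effect);
- `conditional_zero`: 0 everywhere;
- `marginal`: posterior mode for surveyed areas; for unsurveyed areas the
  population-averaged probability `∫ expit(x'β̂ + z'η̂ + u) φ(u; 0, σ̂²) du`
  by 41-node Gauss–Hermite quadrature. Because expit is nonlinear this
  differs from plugging in μ = 0 (it is pulled toward 1/2); both are
  offered because the choice is genuinely open and the difference is
  itself informative about σ̂.

**Raking.** Joint cell counts per area are estimated from the margins by
iterative proportional fitting generalised to margins on arbitrary factor
subsets: each update rescales the current table so one margin (a slice sum
over the complementary axes) matches its target, cycling through margins
in their declared order. Properties and choices:

- Convergence: maximum absolute deviation of every fitted margin below
  `tol · N_i` (default tol 1e−8), iteration cap 1000 cycles. Because every
  margin sums to `N_i`, the grand total is preserved exactly after each
  update.
- Seed: `uniform` (all ones) by default, so cells without sampled
  respondents — and entire unsurveyed areas — receive estimated mass; this
  is what lets the method cover all weighting cells.
  `sample_counts_plus_epsilon` (observed cell counts + 0.5) is available
  when a survey-anchored seed is preferred.
- Structural zeros: cells inside any zero margin slice are fixed at
  exactly 0 before iteration (avoids 0/0 rescaling).
- Infeasible margin systems (possible when independently rounded census
  margins disagree): the final iterate is returned flagged
  `converged=False` with a warning rather than an exception — estimates
  should degrade visibly, not abort. Margin totals disagreeing by more
  than a relative 1e−6 are an input error; `rescale` repairs them
  proportionally to the mean total.
- At convergence the result is the minimum-discrimination-information
  table consistent with the margins and seed, so margin order is
  immaterial up to the tolerance; with one-way margins and a uniform seed
  it is exactly the product-of-margins (independence) table, and when a
  single margin is the full joint, raking is the identity — the classical
  MRP special case, which the tests verify to 1e−10.

**Post-stratification and aggregation.** The area estimate is the raked-
count-weighted mean of cell predictions, hence always inside the convex
hull of the cell probabilities and invariant to rescaling an area's
counts. Aggregation to coarser units (counties → metro areas) is the
population-weighted mean using the census-derived raked totals `N_i` —
the only weighting consistent with the post-stratification logic.

**Bootstrap.** Percentile intervals from B resamples (B ≥ 2; 1000 is the
conventional choice, B=200 is used in the heavier simulation tests).
Design choices, since the resampling scheme is genuinely open:

- Respondents are resampled with replacement *within* each surveyed area,
  keeping per-area sample sizes fixed (respects the survey's clustering);
  areas themselves are fixed, and the raked census counts are treated as
  known, computed once and reused by every replicate.
- Each replicate refits the model (warm-started at the original MLE) and
  re-predicts; replicates that fail to converge are dropped and counted,
  and more than 10% failures is an error unless `allow_unstable`.
- For areas outside the survey, each replicate additionally draws the
  unobserved random intercept from N(0, σ̂_b²). Without this, the interval
  reflects only parameter noise while the estimand contains a genuinely
  unobserved μ_i, and coverage for unsurveyed areas collapses (~47% in our
  simulations, vs ~92% for surveyed areas). The draw turns those intervals
  into prediction intervals; `draw_unsampled_re=False` restores pure
  case-resampling.
- In the rare replicate set whose percentile interval misses the original
  point estimate, the interval is widened to include the point (the raw
  replicate matrix is returned for anyone wanting unwidened percentiles).
- All randomness flows from one integer master seed through spawned
  per-replicate substreams; results are bitwise reproducible given
  (seed, B).

Known limitation: when very few areas are surveyed, σ̂_μ is biased toward
0 (often exactly 0 with 3 areas) and the between-area component of η̂'s
sampling error is invisible to within-area resampling, so intervals for
unsurveyed areas remain anti-conservative — in simulations at the small
test profile (6 areas, 3 surveyed, n≈800), pooled coverage of nominal 95%
intervals is roughly 73% (surveyed ~92%, unsurveyed ~55%). At the default
study scale (58 areas, 5 surveyed, n≈7,200) single-dataset checks are
materially better (~90%+), but users estimating many unsurveyed areas from
a handful of surveyed ones should read unsurveyed-area intervals as
optimistic. A parametric bootstrap that redraws area effects would address
this but is out of scope.

**Validation metrics.** Model-based vs direct estimates are compared on
their common areas, on the percentage scale: MSE `mean((m−d)²)` (units
%²), MAD `mean(|m−d|)`, Pearson and Spearman correlations (average ranks
for ties), five-number summaries with linear-interpolation quartiles, and
closed-interval CI containment in both directions. Zero-variance series
make correlations *undefined* (flagged), never 0.

## Synthetic data

The generator emulates the structure the method assumes, with full ground
truth returned for oracle comparisons:

- **Composition**: per-area cell counts are multinomial with cell
  probabilities from a log-linear model — factor main effects (SD 0.5,
  shared across areas with per-area jitter SD 0.15) plus *pairwise
  interactions* with SD `dependence_strength` (default 0.3). The
  interactions are the point: they make the true joint measurably
  different from the product of its margins, which is precisely the
  regime raking exists for (at `dependence_strength=0` raking one-way
  margins reconstructs the joint up to multinomial noise, and the tests
  check that the reconstruction error grows with the dependence).
- **Populations**: lognormal area sizes (median ≈ 60k adults at the
  default), floored at 10 cells' worth.
- **Outcomes**: the logistic model at configured coefficients. Defaults:
  intercept 0.2; a rising age gradient (0 to 0.55) with +0.15 for women;
  an education gradient (0, 0.35, 0.7, 0.9); race/ethnicity contrasts
  (0, −0.3, −0.4, +0.1, −0.2); poverty effect η = −0.6 per SD — a strong
  area-level effect, deliberately, so that model-comparison behaviour
  (dropping the covariate shrinks cross-area variation) is testable;
  σ_μ = 0.3.
- **Survey**: the 5 most populous of 58 areas are surveyed (metro-style
  coverage) with sample sizes 3400/830/1512/882/533 — the 2018 five-MMSA
  pattern, ~7,200 respondents. Cells are sampled proportional to their
  counts times a lognormal per-cell tilt (SD 0.2 on the log scale),
  emulating unequal selection probabilities of a disproportionate
  stratified design; outcomes are Bernoulli at the true cell probability.
  `sampling_rate=1` returns the full area (census case, used as an exact
  fixture).
- **Profiles**: `default_config()` is the study-scale fixture above;
  `tiny_config()` (6 areas, 3 surveyed, 2×2×2 cells, n = 400/250/150) is
  the unit-test default. Both were fixed once on realism and speed
  grounds; simulation sizes in tests (100 replicates for parameter
  recovery, 20 for rank agreement, 200 datasets × B=200 for bootstrap
  coverage, 6–8 replicate pairs for width-shrinkage) are the package's own
  choices balancing Monte-Carlo error against suite runtime.

What the generator does **not** emulate: telephone-frame nonresponse,
multilingual interviewing effects, survey-weighting design effects, or any
systematic measurement difference between surveys — so passing tests show
the *estimator* works under its assumptions, not that those assumptions
hold for any particular real survey pair.

## Numerical conventions

- Cell order: row-major over the declared factor order, everywhere.
- Margin totals: relative tolerance 1e−6; optional proportional rescale.
- Raking: tol 1e−8 (relative to N_i), max 1000 cycles.
- Fitting: 15 quadrature nodes (7 vs 25 changes β̂ by <1e−4 on
  well-conditioned data), L-BFGS-B ftol 1e−12 / gtol 1e−6, 500 iterations.
- Percentile CIs, closed containment intervals, linear-interpolation
  quartiles, average ranks for Spearman ties.
- Estimates are proportions in [0,1] internally; reports and CSV display
  columns use the percentage scale with one decimal.
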
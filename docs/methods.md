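# Methods

This note documents the statistical machinery in `survtrend`, the defaults
it ships with, and the choices made where the design was genuinely open.

## Time grids

Interviews are indexed by ISO-8601 calendar week (week-based year, so
2021-01-01 lies in 2020-W53) and by monthly periods running from the middle
of one month to the middle of the next, matching the field periods of the
monthly telephone surveys the pipeline was designed around.  The boundary
day defaults to the 15th and the boundary day itself opens the *new* period
(half-open convention `[15th, next 15th)`), which makes the periods an
unambiguous partition of the calendar; both conventions are configurable.
Week and month counters count **calendar** units from the series start, so
collection gaps leave holes in the data but not in the axis — the smoother
sees true elapsed time.

## Adjustment weighting

Raking (iterative proportional fitting) cycles through the four adjustment
levels, multiplying each record's weight by `target share / current
weighted share` of its cell.  One *iteration* is one full cycle over all
levels; the procedure stops when every level's weighted margin deviates
from its target by less than `convergence_tol` (default 1e-6; the original
macros' counting convention is unknowable, so the cycle convention is
documented rather than claimed) or after 300 cycles.  Weights are
normalized to mean one per period, keeping effective sample sizes
interpretable; the result is invariant to rescaling the design weights.

Guard rules for sparse cells:

* cells with n < 10 whose adjustment factor (adjusted weight over
  normalized design weight) is below 1e-12 or above 10 trigger the
  collapse workflow, as does a hit iteration cap;
* collapsing merges *adjacent* age-group categories, youngest-first among
  flagged cells, summing their targets, and re-rakes — preserving the
  ordinal age structure; it repeats until the rules clear or one age
  category remains;
* a level without an age variable (the regional level) cannot be
  collapsed; it is left unchanged with a diagnostic warning;
* a target cell with **zero** observations cannot be fitted at all; it is
  excluded from that level's margin (remaining targets renormalized) so
  the fit proceeds on the occupied cells, and the collapse workflow merges
  it away wherever an age variable exists.

Missing weighting variables are resolved before raking: education to the
middle category; federal-state group drawn from the national distribution;
municipality size drawn from the distribution within the (possibly
imputed) state.  The draws are pseudo-random under a caller-supplied seed
so pipeline runs are reproducible.  Only interviews with known sex and age
enter the sample at all.

## Window estimation and standardization

The month-*t* estimate pools months *t−1, t, t+1*; two months suffice
(series edges, gaps), one month is a gap.  Within a window:

* metric indicators: weighted least squares of the score on
  `sex * age_group * education` (full three-way interaction — the
  cell-mean model);
* binary indicators: weighted logistic regression with two-way
  interactions only, since full interactions make empty cells — and hence
  inestimable margins — much more likely at low prevalence.

Age enters the models in the 7 groups of the first adjustment level by
default (the grouping is configurable).  The adjusted weights act as
probability weights.  The reported covariance is the **sandwich** (HC1)
covariance of the weighted score: a probability-weighted estimator's
variance exceeds the naive model-based one by roughly the factor
`1 + cv²(w)`, and simulation coverage with the model-based covariance fell
to the mid-80s where the sandwich restores ~92–95% — matching what
`margins` under pweights in survey software does.  The model-based
covariance remains available (`cov_type="model"`).

Predictions are averaged over a standard population (census joint counts
over sex × age group × education) with the predictive-margin formula; for
standardized subgroup series every population row is counterfactually
assigned to the subgroup, so subgroups differ only through model
coefficients, not composition.  Delta-method standard errors use the
analytic gradient of the margin; intervals use normal (z) quantiles, and
proportions are transformed to the logit scale and back so the bounds stay
strictly inside (0, 1) even at p near 1e-6 (bounds are clamped to the
nearest representable interior double in the extreme-SE limit).  Windows
whose data leave a model cell empty, separate the logistic fit
(zero-variance outcome in a cell, diverging coefficients, IRLS
non-convergence in 100 iterations), or make the design rank-deficient are
reported with status `degenerate`; their month keeps its row in the output
with empty estimate fields, as do gap months.

## Weekly smoothing

The weekly model is

```
y ~ s(week, by = interaction(age_group, sex, education)) + age_group*sex*education
```

Each smooth is a low-rank thin-plate regression spline in one dimension:
radial basis |r|³/12 on the group's distinct (rescaled) week values,
eigen-truncated to the `basis_dim` leading eigenvectors, polynomial
constraint absorbed, leaving `basis_dim − 2` penalized columns plus an
unpenalized linear column; the constant is removed by sum-to-zero centering
over the group's rows.  The second-order wiggliness penalty is positive
semi-definite with the constant-plus-linear trend in its null space, so a
smooth shrunk completely retains exactly one effective degree of freedom
(its linear term).

Smoothing parameters — one per smooth, penalties not shared across groups
— maximize the restricted likelihood.  For the Gaussian family the scale
is profiled out analytically and the criterion and its exact gradient
(involving `tr(A⁻¹Sⱼ)` and `β'Sⱼβ`) are optimized by L-BFGS-B over log-λ;
for the binomial family, penalized IRLS alternates with REML selection on
the working model (scale fixed at one) until joint convergence.  GCV is
available as an alternative but tends to undersmooth these series, which
is why REML is the default.  Defaults: `basis_dim = 10` per group smooth,
automatically reduced for groups with fewer distinct weeks; groups with
fewer than four distinct weeks get no smooth (their parametric cell mean
remains).  Observation weights enter as likelihood weights — an
approximation, as design-based uncertainty propagation through a GAM is
an unresolved problem; accordingly **only point estimates** are produced
for the weekly curves, no intervals.

Weekly standardized predictions apply the same predictive-margin formula
with the GAM prediction as `g`.  Extrapolation beyond the observed week
range is refused — the curve describes, it does not forecast.  In the
orchestrated pipeline the factor-by-curve smooths default to the coarse
3-level age grouping (the window regressions keep 7 groups): with 42
groups the per-group weekly sample is too thin at realistic monthly sample
sizes for stable smooths, which short-series fits are known to produce.

The comparison baseline is a restricted cubic spline with 5 knots at the
(0.05, 0.275, 0.5, 0.725, 0.95) quantiles of the observed weeks
(Harrell's recommendation), linear before the first and after the last
knot; `k` knots yield `k−1` basis columns including the linear term.  The
update-stability experiment refits a chosen curve on data truncated at
each cutoff of a schedule and records the absolute change of past weekly
predictions between consecutive fits; it runs on an overall (single-curve)
series, which is where the thin-plate-versus-restricted-cubic comparison
is defined.

## Synthetic data and ground truth

The generator emulates the structure the pipeline assumes: interview dates
uniform within mid-month periods (36 months, n=1,000/month, a two-month
gap in the reference scenario); demographics drawn from a census-style
joint distribution *tilted* by participation multipliers increasing with
age (0.55 → 1.6 across the 7 age groups) and education (0.8 / 1.0 / 1.3)
— the classic telephone-survey nonresponse pattern; design weights from a
simple municipality-size selection mechanism; regional variables from
fixed distributions (10 combined federal-state groups, 7 Nielsen areas, 4
municipality-size classes, with a state-dependent municipality mix);
missingness injected per variable (education 3%, regions 2%, indicator 2%,
sex/age 0.5%).

The metric indicator is a latent Gaussian `trend(week, cell) + noise`
(noise SD 1.3 on the 0–6 scale) **rounded** to the nearest integer and
clipped to 0–6; the binary indicator is `score > 2`.  Under the rounding
convention both true moments are exact Gaussian-cell probabilities —
`P(score > 2) = Φ((μ − 2.5)/σ)` — so ground truth is computed analytically
from the trend functions and population counts, never by simulation.
Rounding (rather than truncation) was fixed once because the binary truth
formula depends on it.  Reference trends assign a late +0.5 level break to
the youngest coarse age group, a slow +0.4 rise to the middle, and a flat
line to the oldest, plus small additive sex and education effects;
monthly truth is the average of weekly truths over a period's weeks, which
is what a centered window targets under uniform interviewing.

What the generator does **not** emulate: the dual-frame telephone sampling
mechanics behind real design weights, informative missingness, measurement
error or mode effects, and within-cell heterogeneity beyond the additive
trend structure.  Passing tests therefore demonstrate the estimators'
correctness under the stated model, not robustness to violations of it.

## Verification problem sizes

The simulation-based checks use 200 replicates where coverage or bias is
asserted (CI coverage at n=300/month over three months; recovery bias at
n=1,000/month over five months with flat-plus-linear trends, judged on the
three interior months whose windows are fully centered), a 24-month
n=500/month sine-trend series for smoothing quality, a grid step of 0.25
in log-λ for the REML oracle, and ten 4-week updates of the reference
scenario for the stability experiment.  Edge months intentionally use
two-month windows and are therefore excluded from unbiasedness claims —
their windows are off-center by construction.

## Known limitations

* No confidence intervals for the weekly GAM curves (see above).
* The regional adjustment level cannot be collapsed when sparse; its
  margins are fitted over occupied cells only.
* Raking assumes the target tables cover every category present in the
  data; unknown categories are an error, not an imputation case.
* The logistic window model declares any zero-variance outcome cell
  degenerate, which is conservative at very low prevalence — matching the
  observed sparsity of published proportion series rather than maximizing
  the number of reportable months.
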
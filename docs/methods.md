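# Methods

`didsim` is a Monte-Carlo laboratory for difference-in-differences (DID)
style evaluations of state-level policies on annual panel outcomes. It
generates balanced state × year panels with a known no-policy baseline,
assigns hypothetical ("placebo" or effective) policies to random subsets of
states, injects effects of known size, fits a grid of commonly used panel
regressions, and scores them on bias, error, and hypothesis-testing
behaviour. This note records the models, the data-generating process, the
numerical choices, and the limits of what the synthetic experiments show.

## Potential-outcomes setup

For state *i* and year *t*, let `Y_it0` be the no-policy outcome (a crude
death rate per 100,000) and `Y_it1` the outcome with the policy in effect.
Exposure `A_it ∈ [0, 1]` measures the fraction of year *t* the policy was
effective in state *i*; the observed outcome is the mixture

    Y_obs = A·Y1 + (1 − A)·Y0.

Treated states and enactment dates are drawn uniformly at random, so there
is no confounding by construction; enactment years are restricted so every
treated state retains at least three full pre- and post-years. Under the
instantaneous coding the enactment-year exposure is the fraction of the
calendar year after the enactment month (policy starts on the month's first
day); under the 3-year phase-in, effectiveness ramps linearly by month to
full strength at 36 months and annual values are means of the 12 monthly
values. The same annualized exposure is used for data generation and as the
analytic policy regressor, so the analytic models are correctly specified
with respect to timing; a deliberately misspecified analysis can be produced
by passing a step-coded exposure to `fit_model` directly.

## Effect sizes on two scales

Effects are defined multiplicatively as s ∈ {±5%, ±15%, ±25%} (small,
medium, large), injected as `Y1 = Y0·(1 + s)`. Linear models analyse data
with an additive rate effect `Y1 = Y0 + α` instead, where α is *calibrated*
so that the national excess-death magnitude matches the multiplicative
condition on the panel in use: averaging over random assignments,

    α = s · E[Σ A·r0·pop] / E[Σ A·pop],

i.e. s times the exposure-weighted mean baseline rate. On a panel with a
constant rate r this reduces to α = s·r exactly. Enactment-year doses scale
linearly in exposure on both scales (additive `A·α`, multiplicative
`1 + A·s`), which makes the step and phase-in codings nest. Additive
injections that would drive a rate negative are clamped at zero and
counted. Injected crude rates are kept exact; death counts are re-derived
from the injected rate and rounded to the nearest integer so count
likelihoods see integers. Strict rate/count consistency therefore holds for
baseline panels but not cell-by-cell for injected ones (the discrepancy is
below one death per cell).

## Model grid

Four regression families × link × weighting (17 cells), each returning the
policy coefficient on its native scale:

* **twfe** — `g(Y) = α·A + β·X + state FE + year FE`: the classic DID
  two-way fixed-effects regression.
* **detrended** — twfe plus state-specific linear slopes in centred panel
  time. One state's slope is absorbed: the shared trend is carried by the
  year effects, so the remaining 49 slope terms are differences from the
  national trend (the policy coefficient is invariant to which state is
  absorbed; a test verifies this against an over-parameterized
  pseudoinverse fit).
* **ar** — lagged-outcome model: `g(Y_t) = α·ΔA + β·X + γ·y_{t−1} + year FE`
  with *change coding* ΔA = A_t − A_{t−1} and no state effects; the first
  panel year is dropped. The lag enters on the link-native scale (lagged
  rate for the linear link, lagged log rate otherwise) so predictor and
  outcome stay commensurable. Level-coded policy (`ar_coding="level"`) is
  available for the bias comparison; on autocorrelated data it is markedly
  more biased, which a simulation test checks.
* **gee** — estimating equations with year effects, clustered by state,
  Gaussian family, AR(1) working correlation `corr(t, m) = ρ^|t−m|` with ρ
  re-estimated by the standard moment update each iteration (statsmodels'
  grid-based update; iteration cap 100, non-convergence flagged and
  excluded). Linear link only.

Links: linear (crude rate), log-linear (log crude rate; a zero rate gets a
half-count continuity correction `0.5/pop·1e5` before logging, with
occurrences counted), Poisson and negative-binomial on death counts with
`log(pop/1e5)` offset, so exponentiated coefficients are incidence-rate
ratios per 100k. The NB dispersion is estimated by maximum likelihood
(profiled via the unconstrained NB2 fit, then a GLM refit at the fitted
dispersion supplies model-based SEs, as in `MASS::glm.nb`). Linear and
log-linear models are optionally population-weighted via weighted least
squares on the (transformed) outcome.

Standard errors: model-based ("none"), Huber/HC1 sandwich (meat scaled by
n/(n−p)), and state-clustered CR1 sandwich (G/(G−1)·(n−1)/(n−p)), all
computed explicitly from per-observation scores (WLS: `w·e·x`; Poisson:
`(y−μ)·x`; NB2 at fixed dispersion: `(y−μ)/(1+aμ)·x`). p-values use a
normal reference except clustered SEs, which use t with G−1 degrees of
freedom. GEE reports only its own robust SE. Fewer than two clusters gives
a NaN SE; cluster-level fixed effects can make the clustered variance of
the policy term structurally zero, and numerically negative values are
clipped to zero rather than propagated as NaN.

## Synthetic baseline

Real mortality panels are restricted-use, so the baseline generator is a
documented surrogate whose targets are the qualitative features that drive
estimator behaviour: right-skewed crude rates, strong within-state
year-over-year autocorrelation, a rising national trend, heterogeneous
state levels and slopes, overdispersed counts, and populations spanning
roughly two orders of magnitude. The latent process is

    log r_it = a_i + (log g + b_i)·(t−1) + e_it,  e ~ AR(1)(ρ, σ),

with defaults: 50 states × 18 years (1999–2016 labels; 900 records);
populations log-uniform on 10^5.7–10^7.6 (≈0.5M–40M), constant over time;
year-one mean rate 3 per 100k with state log-level sd 0.4; national growth
g = 1.12/yr with state slope sd 0.03; ρ = 0.8, innovation sd 0.12; counts
negative-binomial with dispersion 50 (Var = μ + μ²/50); unemployment AR(1)
around 5.5% (sd 1.0, ρ 0.7). These defaults are design choices, not
estimates from any particular dataset; they yield national deaths rising
from roughly 15k to 95k over the panel and rate skewness ≈ 4. A
`deterministic` mode zeroes the AR noise and count sampling (rates equal
the latent trend exactly, deaths are rounded expected counts) for
exact-recovery tests; its unemployment covariate is a smooth
state-staggered cycle so the design keeps a non-constant covariate without
randomness.

The generator's lag-1 autocorrelation target is checked on *latent* rates:
realized rates add count-sampling noise that attenuates the pooled
correlation (strongly for small states), which is exactly the measurement
structure real crude rates have. Per-state linear detrending also biases
the lag-1 estimate downward at short T (Nickell-type bias ≈ (1+3ρ)/T), so
the recovery property is asserted at T = 200 where the bias is within the
±0.05 tolerance.

## Performance metrics

With paired signed conditions (truths α, −α) and per-simulation estimates:

* directional bias `(mean(pos−α) + mean(neg+α))/2` and magnitude bias
  `(mean(pos−α) − mean(neg+α))/2` — their sum and difference recover the
  per-sign mean biases exactly (a property test asserts the identity);
* RMSE on the native scale;
* Type I error: fraction of null-condition p < 0.05 among converged fits;
* correct rejection rate: fraction significant *and* correctly signed,
  after dividing |t| by an SE correction factor.

The correction factor is the empirical upper-5% order statistic of |t|
under the matching null condition divided by the nominal critical value;
rejection uses a strict inequality, so on the calibration sample the
corrected Type I error equals the nominal level exactly (up to the n·level
integrality). Factors are computed per (model, SE method, k, phase-in) cell
from that cell's own null runs — the strictest calibration granularity.
Bias is also standardized to national annual excess deaths (linear: rate ×
national population / 1e5; log links: (exp(effect)−1) × mean annual
baseline deaths) and expressed as a percentage of the excess implied by the
true effect, making linear and count models comparable. Non-converged fits
are excluded from all metrics and counted.

## Orchestration and reproducibility

A run crosses k ∈ {1, 5, 15, 30}, size classes, and phase-ins, with null
conditions executed first to feed calibration. Per-simulation seeds are
`blake2b(master seed | condition key | sim index)` truncated below 2^31, so
results are bit-reproducible, every model sees the same simulated datasets,
and adding a model to the grid changes no other model's estimates (tested).
Estimates are archived per condition as CSV so metrics can be recomputed
without re-simulation; an unchanged configuration hash lets a rerun skip
completed conditions. The canonical scale is 5000 simulations per
condition; the default is 500, and the package's own acceptance
computations use 250–1000 depending on the statistic, sizes chosen so the
full linear-model checks run in minutes on one CPU.

## What the synthetic experiments do and do not show

Passing tests demonstrate internal correctness (formulas, codings,
invariances, calibration) and reproduce the qualitative behaviour expected
on strongly autocorrelated panels: the unadjusted change-coded
lagged-outcome model holds the nominal Type I level where the fixed-effects
models badly overreject; its null RMSE is the smallest of the linear
models; power rises with effect size and the number of treated states; and
the population-weighted classic DID model's percent bias explodes when a
single state is treated. They do not establish numeric performance on any
real mortality panel: the generator omits confounded adoption,
heterogeneous or time-varying effects, policy repeal, spatial spillovers,
and time-varying populations, and its parameters are design targets rather
than fitted values. Known limitations otherwise: the Arellano SE variant
and random-effects/synthetic-control/doubly-robust estimators are out of
scope, and the enactment-day convention (first of the month) is one of
several defensible readings of month-granularity policy data.
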
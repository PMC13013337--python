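# Methods

## Model structure

Two observation families share one filtering engine.  Every modelled series
(a group's daily census, a caregiver type's daily hours) carries one latent
state block per linear predictor: the count model has a block for
logit p (occupancy) and one for log η (positive-count intensity); the hours
model has a block for μ and one for log σ² of log hours.  Blocks are
filtered independently — cross-predictor covariance is taken as zero,
matching the block structure of the linear predictors — and each follows

    θ_t = G θ_{t−1} + ω_t,   ω_t ~ N(0, W_t).

The daily cycle per block:

1. **Evolve** (m, V) → (Gm, GVG′ + W).
2. **Project** onto the predictor: (F′m, F′VF).
3. **Match** a conjugate prior with those moments of the transformed
   parameter: Beta(a, b) with ψ(a) − ψ(b) = m and ψ′(a) + ψ′(b) = v for
   logit p; Gamma(shape, rate) with ψ′(shape) = v and
   rate = exp(ψ(shape) − m) for log η; Normal-Inverse-Gamma for (μ, log σ²)
   jointly.
4. **Update** the conjugate parameters with the day's observation
   (Beta–Bernoulli; Gamma–Poisson on the positive count; NIG–Normal on log
   hours).
5. **Map back** the posterior moments of the transformed parameter and
   revise the state by the linear-Bayes step
   m_t = m + VF(Δm)/V^φ, V_t = V − VFF′V(1 − V^φ_post/V^φ)/V^φ.

The cycle uses only first and second moments, so there is no sampling in
the filter itself.  With the Normal known-variance family the cycle is
*exactly* the local-level Kalman filter (this is a tested identity); with
the matched families it is the standard conjugate dynamic-GLM
approximation.

### Assumptions

* Counts are conditionally zero-truncated-Poisson given occupancy; zeros
  are structural (empty group), not thinned counts.  On a zero day the
  intensity block receives no data update — zeros are routed entirely to
  the occupancy gate — but the block still evolves, so its uncertainty
  grows through runs of zeros.  No censoring correction is applied for the
  truncation at zero in the default update: the positive count is treated
  as plain Poisson evidence (shape + y, rate + 1).  An `exact` mode
  integrates the truncated likelihood by quadrature and re-matches the
  Gamma; the difference is O(e^{−η}) and negligible unless η is small.
* Hours are conditionally lognormal; days with zero total hours have no
  log-scale likelihood and are skipped (the state evolves without data).
* Latent states drift slowly relative to the daily sampling rate; all
  nonstationarity is absorbed by the state evolution, not by explicit
  trend/seasonal regressors (the shipped defaults are F = 1, G = I).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `discount` δ | 0.95 | evolution noise as W = ((1−δ)/δ)GVG′; memory ≈ 1/(1−δ) ≈ 20 days.  δ = 1 freezes the state (static model). |
| `update_mode` | `conjugate` | positive-count update; `exact` adds the zero-truncation correction by quadrature. |
| shared `lag` | 1 day | how far back the shared covariate looks; 1 keeps the information set strictly causal. |
| shared `standardize` | on | shared covariate centred/scaled by its own running history. |
| cluster `threshold` | 0.5 | correlation above which groups tend to share a cluster (cut at distance 1 − ρ, average linkage). |
| `n_samples` | 1000 | predictive samples per day; the point forecast is the lower median (order statistic ⌈n/2⌉), keeping count forecasts integer and the protocol bit-reproducible. |
| initialization | — | occupancy predictor starts at the Beta(1,1) equivalent (0, π²/3); intensity at (log mean positive count of the first observed week, 1); hours at the NIG(m₀, 1, 2, 1) equivalent with m₀ the first week's mean log hours. |
| shared-effect prior | N(0, 0.25) | weakly informative start for each appended covariate coefficient; diffuse enough to learn a unit-scale effect on a standardized covariate within a few weeks, tight enough not to destabilize early forecasts. |

## Numerical choices

* Digamma/trigamma inversions are damped Newton iterations on
  log-parameters (monotone maps; max 100 iterations, residual 1e-10, with
  closed-form asymptotic initializers), not generic root-finders — the
  filter calls them once per block per day.
* If matching fails at extreme moments the predictor variance is inflated
  1.5× (at most five times) and retried; inflation only widens the prior.
  NIG matching requires shape a₀ > 1 for finite V[μ]; when the
  log-variance moments are too diffuse (v ≥ ψ′(1) ≈ 1.645) the variance is
  floored at 0.64, pinning a₀ near 2.  Both fallbacks log a warning.
* After every linear-Bayes step the state covariance is symmetrized and
  eigenvalues below zero are clipped — float drift over a year of
  recursions otherwise accumulates at the 1e-15 level.
* Multi-step recursion feeds the sample-median point forecast back as a
  full-weight pseudo-observation; earlier pseudo-observations persist in
  the state for later steps.  A `marginal` mode evolves states without
  updates instead, giving non-decreasing predictive spread with horizon.
* MAPE excludes zero-observation days (the count series genuinely contain
  zeros); the excluded count is reported, and MAPE is NaN when every day
  was zero.

## Synthetic data

`simulate_series` draws directly from the generative model: per-group
deterministic skeletons (level + linear trend + weekly/biweekly sinusoid)
plus Gaussian random-walk noise on both the occupancy logit and the log
intensity, then the Bernoulli gate and zero-truncated Poisson counts, then
staff hours as the staffing-table-weighted count sum with multiplicative
lognormal noise (sd 0.05).  Default levels give six groups averaging
roughly 2–20 residents with a low-volume group (BSS) near the occupancy
gate producing ~50% zero days, mirroring a mid-size facility.  The default
staffing table is synthetic — magnitudes of 0.3–1.5 licensed-nurse hours
and 2–3 aide hours per resident-day — not a published payment-model
schedule.  An optional common factor (sinusoid + stationary AR(1)) loads
on chosen groups' log intensity; the AR component is what produces
correlated *first differences*, the signal the shared-information variant
uses.  `shared_factor_scenario` packages the strong-factor study condition
(two groups at η ≈ 20–25, loadings 1.0, factor sd ≈ 0.5 with daily change
sd ≈ 0.3).

`simulate_residents` generates the upstream records instead: Poisson
admissions, geometric lengths of stay (chosen for tractability; only the
mean is calibrated), quarterly reassessments with a group-transition
probability, and optional blanked discharge/group fields to exercise the
cleaning rules.

What the generator does *not* emulate: day-of-week admission patterns,
holiday effects, correlated admissions across groups, heavy-tailed stay
durations, or measurement artifacts of real assessment extracts.  Passing
tests therefore demonstrate correctness of the method under its own model
class and robustness to the structural features listed (zeros, drift,
oscillation, cross-correlation) — not performance on any real facility's
records.

## Census pipeline conventions

* Stay intervals are half-open [admission, discharge): a resident
  transferred or readmitted is never double counted.
* A resident's group on a day is the most recent assessment at or before
  the day; days before the first assessment back-fill from it (logged).
* Missing discharge dates: a death-in-facility assessment dates the
  discharge exactly; otherwise the stay is carried forward 92 days (the
  quarterly assessment cycle) from the last assessment, capped at the
  study end.  The carry-forward span is configurable.
* Duplicate assessments (same resident, date, type, group) collapse to
  one; assessments with a missing group inherit the most recent prior
  group; residents with no usable assessment are dropped with a logged
  count.  Cleaning is idempotent.
* Staff aggregation d_{r,t} = Σ_g λ_{r,g} z_{g,t} is exact float
  arithmetic on integer counts; zero-total days are emitted as 0 and
  skipped by the hours model.

## Evaluation protocol and problem sizes

The default protocol trains on 243 days (eight months of a non-leap year),
forecasts a 90-day horizon in 30-day rolling windows (three origins), and
takes medians of 1000 predictive samples.  The acceptance script runs this
protocol on one year of synthetic data, plus: 20 seeded 200-day scenarios
for each skill comparison (model vs lag-1 naive; shared vs plain), 1000
filtered days for interval coverage, and a 100-step Gaussian cycle for the
Kalman identity.  The test suite uses the same designs at these or smaller
sizes (e.g. 50 replicates of the 365-day six-group recovery check).

## Design notes and open points

* The occupancy prior is a Beta distribution — the conjugate family for a
  Bernoulli likelihood; the probability parameter itself cannot carry a
  Bernoulli-distributed prior.
* The evolution noise is specified by a discount factor rather than a
  hand-set W: it is self-scaling, has one interpretable knob, and is
  standard dynamic-linear-model practice.
* The (μ, σ²) pair is updated jointly through the NIG and then *split*
  into the two predictor blocks via the moments of μ and of log σ²; with
  intercept-only covariates this realization is exact for μ and
  moment-faithful for log σ².
* What the shared covariates should be is genuinely open; this package
  uses lagged observations of cluster partners (raw counts for the count
  model, log hours for the hours model), which keeps the information set
  strictly causal.  Fitted values or jointly inferred latent factors are
  plausible alternatives and out of scope.
* Known limitations: no backward smoothing; no cross-series covariance in
  the filter (sharing is covariate-based only); recursive multi-step
  forecasts inherit the usual bias of feeding point estimates into a
  nonlinear model; MAPE is unstable for near-zero-volume groups (the BSS
  column in the examples shows this).
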
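# Methods

## The model

`doublecox` fits a fully parametric, non-proportional-hazards survival model
for clustered right-censored data.  Conditional on a cluster-level frailty
`Z`, the cumulative hazard of a subject with covariate vector `u` is
`Z * H(t|u)` with

* Weibull baseline:   `H(t|u) = exp(βs·u_s) · t^B / a`
* Gompertz baseline:  `H(t|u) = a · exp(βs·u_s) · (exp(B·t) − 1) / B`

where `B = b · exp(βh·u_h)`.  Two separate Cox-regression terms act on the
model: `βs` multiplies the hazard (classical proportional-hazards effect on
the *scale*) and `βh` log-linearly modulates the *shape* parameter `b`.
Non-zero `βh` makes hazards cross: covariates can change the steepness of
ageing/wear-out, not just its level.  With `βh = 0` the model reduces to the
classical parametric proportional-hazards frailty model.

The frailty is gamma with mean 1 and variance `σ²`, shared by all subjects of
a cluster.  Its Laplace transform gives the closed-form marginal survival
`S(t|u) = (1 + σ²H(t|u))^(−1/σ²)` and a closed-form marginal likelihood: for a
cluster with `d` events, summed cumulative hazard `Hs` and event log-hazards
`ln h_j`,

```
ℓ_cluster = Σ_j ln h_j + lnΓ(1/σ² + d) − lnΓ(1/σ²) + d·ln σ²
            − (1/σ² + d)·ln(1 + σ²·Hs).
```

At `σ² = 0` this degenerates continuously to `Σ ln h_j − Hs`.  All likelihood
work is done on the log scale; values of `σ²` below `1e−10` take the exact
`σ² = 0` branch to avoid cancellation.

### Weibull parameterization

The Weibull cumulative hazard is taken as `t^B / a` — i.e. `a` divides, and is
on the scale of `t^B` — rather than `(t/a)^B`.  Only this reading reproduces
the package's reference mean-survival values: at `a=20, b=1.5, σ²=1` the
marginal mean is `a^(1/b)·(π/b)/sin(π/b) = 17.82`, the device-lifetime
benchmark used throughout the tests, whereas `(t/a)^B` would give 48.4.
`test_model.py` pins this down.

### Event-indicator convention

Internally `event = 1` always means the event was observed (density term in
the likelihood); the CSV reader accepts either file convention through
`ColumnMapping.status_event_value`.

## Estimation

`fit_ml` maximizes the total marginal log-likelihood by L-BFGS-B on the
unconstrained scale `(ln a, ln b, βs, βh, ln σ²)`, with the analytic score:
the gradient with respect to every hazard parameter is the conditional score
evaluated with the posterior frailty means
`w_i = (1 + σ²·d_i)/(1 + σ²·Hs_i)` as subject weights, and the `σ²` component
follows from differentiating the gamma marginalization (digamma terms).  The
gradient is unit-tested against central differences at 1e−6 steps.

* **Starting values.**  A crude event rate `d / Σt` sets the baseline level
  (Weibull: `a₀ = Σt/d, b₀ = 1`; Gompertz: `a₀ = d/Σt`, `b₀ = 1/mean(t)`),
  coefficients start at 0 and `σ²` at 0.1.  `multistart` (default 3) adds
  normally perturbed starts (SD 0.3 on the estimation scale) because the
  scale and shape terms of the same covariate can compete for the likelihood;
  the best final likelihood wins.  In the simulation studies shipped with the
  package a single start reaches the same optimum, so the study harness runs
  with `multistart = 1`.
* **Boundary handling.**  If the unconstrained optimum puts `σ²` below
  `boundary_epsilon` (default 1e−6), the no-frailty model is refitted and the
  better of the two is returned with `σ² = 0` and a boundary flag.
* **Degenerate inputs.**  Clusters without events contribute only survival
  terms and need no special casing; a dataset with *no* events at all raises
  `AllCensoredError`.

`fit_em` implements the classical gamma-frailty EM: the E-step computes the
posterior frailty means `w_i` above; the M-step maximizes the expected
complete-data log-likelihood over `(a, b, βs, βh)` (a weighted no-frailty
fit); `σ²` is then refreshed by a one-dimensional profile search on the
marginal likelihood.  At fixed `σ²` each sweep is a genuine EM step, so the
marginal log-likelihood cannot decrease — a property the tests verify along
with agreement with the direct route (1e−4 in parameters, 1e−6 in
log-likelihood).  EM is retained as a cross-check; the direct route is an
order of magnitude faster and is the default everywhere.

## Interval estimation

* **Observed information** is a central-difference Hessian of the negative
  marginal log-likelihood on the mixed reporting scale
  `(ln a, ln b, β, σ²)`, with per-coordinate steps `1e−4·max(|x|, 0.1)`, a
  grid shifted one step into the feasible region when `σ̂² = 0`, and inversion
  with a pseudo-inverse fallback plus a reliability flag (positive
  definiteness and condition number below 1e12).  A Richardson step-halving
  variant serves as an internal accuracy cross-check (agreement to 1e−4).
* **Wald intervals** are `estimate ± z·SE`, with `a` and `b` handled on the
  log scale and back-transformed (hence asymmetric), and regression
  coefficients on the natural scale.
* **Boundary mixture for `σ²`.**  Because `σ² = 0` is a boundary point, the
  asymptotic law of `√N·σ̂²` is a mixture of a truncated normal and a point
  mass at zero.  With the plug-in center `ν = √N·σ̂²` and scale
  `κ = √(N·Var(σ̂²))`, the mixture CDF collapses to `Φ((x−ν)/κ)` on `x ≥ 0`
  (equivalently: the law of `max(N(ν, κ²), 0)`), so the interval is the Wald
  interval clipped below at zero — the lower endpoint is exactly 0 whenever
  `σ̂² = 0`.  The full CDF/quantile pair is exposed and verified against a
  10⁶-draw Monte-Carlo sample.  The `√N` scaling is adopted as the
  dimensionally consistent form of the asymptotic statement; as implemented
  the `√N` cancels and never enters the numbers.
* **Profile-likelihood intervals** invert the likelihood-ratio test: an
  endpoint `v` solves `2(l_max − l_profile(v)) = 3.84` (the 95% χ²(1)
  quantile), where the profile re-maximizes over all remaining parameters
  with warm starts, `σ²` constrained non-negative.  The first bracket step
  comes from a local quadratic fit to the profile deficit, expands
  geometrically (60 doublings max), and endpoints are refined by bisection to
  `|2Δl − 3.84| < 1e−3`.  A side that never crosses the threshold is
  reported unbounded and flagged.  For `σ²`, if the deficit at `σ² = 0` is
  below the threshold the lower endpoint is 0.

## Synthetic data

The generator emulates the benchmark simulation design:

* covariates: binary `Success ~ Bernoulli(p_Success)` and continuous
  `Score ~ N(0, 0.2)` (variance 0.2), independent;
* baseline truths: Weibull `(a, b) = (20, 1.5)` and Gompertz
  `(a, b) = (1e−4, 0.1)` — chosen so that at `σ² = 1` the marginal life
  expectancies are 17.8 (device lifetime) and 69.2 (human longevity);
* scale coefficients `(±0.5, ±1)`, shape coefficients one order smaller
  `(±0.05, ±0.1)`; frailty variance 0–5; `N ∈ {300, 1000, 10000}`;
  `Ncl ∈ {10, 100}`; censoring rates `{0, 0.4, 0.8}`;
* subjects are allocated to clusters in equal contiguous blocks (remainder to
  the first clusters) — cluster sizes are otherwise unspecified in the
  design, and equal blocks are the simplest reproducible choice;
* event times invert `z·H(t|u) = e` against unit-exponential draws `e`, with
  the cluster's shared gamma frailty `z`;
* censoring times are `Uniform(0, θ)`.  `θ` is calibrated by Monte Carlo:
  `p(θ) = E[min(T, θ)]/θ` is the exact censoring probability given a fixed
  sample of event times `T` (drawn fresh from the full generative model,
  covariates and frailty marginalized, default 10⁶ draws), and the root of
  `p(θ) = p_cens` is found by Brent's method.  The conditional form avoids
  simulating `C` during calibration (variance reduction) and makes `p(θ)`
  smooth and strictly monotone.  Calibration is bit-reproducible under a
  fixed seed and is verified against the closed form for exponential times.

What the generator does *not* emulate: covariate-dependent or administrative
censoring, left truncation, time-varying covariates, unequal or informative
cluster sizes, model misspecification of the baseline family.  Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

## Numerical choices

* Life expectancy integrates the marginal survival on doubling windows.
  Under gamma frailty the survival tail can be algebraic
  (`S ~ t^(−B/σ²)` for the Weibull), so the ratio of successive window
  increments is used as an empirical tail test: once increments decay the
  remaining tail is integrated exactly under `t → 1/x`; if the window limit
  passes 1e8 time units with no decay the mean is reported divergent rather
  than as a number.  Convergent results carry relative accuracy 1e−8 and are
  tested against the closed forms available at `σ² ∈ {0, 1}`.
* The quadrature likelihood oracle integrates each cluster's conditional
  likelihood against the gamma density after the substitution `z = e^y` and
  Laplace standardization (mode-centered, curvature-scaled), which keeps the
  integrand a well-scaled bump for any `d`, `Hs`, `σ²`.  It exists for
  verification only and shares no code path with the closed form.
* Optimizer bounds on the estimation scale (`ln a ∈ [−25, 25]`,
  `ln b ∈ [−12, 8]`, `β ∈ [−30, 30]`, `ln σ² ∈ [−30, 4]`) are wide enough
  never to bind at a genuine optimum in the study scenarios; they exist to
  keep line searches out of overflow territory, and non-finite objective
  values are mapped to a large finite penalty so backtracking works.

## Study harness and reproducibility

Replication `r` of grid cell `c` under master seed `s` uses the RNG stream
`SeedSequence([s, c, r])`, so every replication is reproducible in isolation
and results are identical across worker counts and execution orders.  The
default replication count is 300 (the full design used 5000 repetitions per
configuration across 1440 configurations, which is not a desk-scale
computation); bias and coverage cells carry Monte-Carlo standard errors
(`sd/√R` and `√(p(1−p)/R)`), and cells with more than 20% convergence
failures are flagged.

The shipped verification studies use larger replication counts than the
harness default because the quantities under test are small relative to the
estimators' sampling SDs: the heavy-censoring bias study (N=1000, 80%
censoring) runs 15 000–20 000 replications so that the Monte-Carlo SE of the
mean of a shape coefficient of 0.05 is about 2% in relative terms, and the
over-parametrization comparison (N=300) runs 10 000–40 000 replications.
The double-Cox binary scale coefficient at N=300 has sampling SD ≈ 0.7 — the
scale/shape competition produces a wide, weakly bimodal, nearly unbiased
sampling distribution (a secondary likelihood mode swaps part of the effect
between the scale and shape terms) — so a mean-error measurement at a
few-percent resolution genuinely needs tens of thousands of replications.
In the over-parametrization study the double-Cox fit is warm-started from
the nested single-Cox solution; this was verified replication-by-replication
to reach the same optimum as the default start, and roughly halves the cost
of the second fit.

## Known limitations

* Maximum marginal likelihood underestimates `σ²`, most visibly with few
  clusters; the bias declines roughly linearly in `1/Ncl`.  No REML-type
  correction exists for gamma frailty, and none is attempted.
* SE-based (Wald) intervals undercover for shape coefficients and for `σ²`
  in small samples; the profile intervals are the recommended method.
* Only Weibull and Gompertz baselines, gamma frailty, right censoring, and
  time-constant covariates are supported.
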
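# Methods

`gelrct` estimates the difference between outcome means of a two-arm
randomized trial with nonparametric covariate adjustment based on the
generalized empirical likelihood (GEL) family, and provides the
ANOVA/ANCOVA comparator (classical and HC3 robust standard errors)
together with the Monte-Carlo machinery to evaluate both.

## Model and moment conditions

Let `y` be a continuous outcome, `z ∈ {0,1}` the randomized group
indicator (`z=0` control, `z=1` intervention) and `x_1..x_k` baseline
covariates, `k ∈ {0,1,2}`.  The parameters are `θ = (μ1, Δ, μx)`:

* `μ1 = E[y | z=1]` — intervention-group outcome mean,
* `Δ = E[y | z=0] − E[y | z=1]` — the estimand (control minus
  intervention),
* `μx` — the *common* covariate means (randomization guarantees a
  common value).

The per-observation moment vector stacks the two group-wise outcome
conditions with a pair of balance conditions per covariate:

```
g_i(θ) = [ z_i (y_i − μ1),
           (1−z_i)(y_i − μ1 − Δ),
           z_i (x_ij − μx_j),  (1−z_i)(x_ij − μx_j),  j = 1..k ]
```

`q = 2 + 2k` conditions for `p = 2 + k` parameters.  The `k`
overidentifying restrictions say exactly that the reweighted covariate
means coincide across arms — covariate balance — which is what lowers
the variance of the adjusted `Δ̂` relative to the raw difference in
means, in the same way the covariate term does for ANCOVA.

## GEL saddle-point estimation

The estimator minimises over `θ` the inner maximum

```
Q(θ) = sup_λ (1/n) Σ_i ρ(λ' g_i(θ))
```

with carrier `ρ` normalised so ρ(0)=0, ρ′(0)=ρ″(0)=−1:

| family | ρ(v)          | implied weight ∝ −ρ′(λ'g_i) |
|--------|---------------|------------------------------|
| EL     | log(1 − v)    | 1/(1 − λ'g_i) (positive)     |
| ET     | 1 − exp(v)    | exp(λ'g_i) (positive)        |
| CUE    | −v − v²/2     | 1 + λ'g_i (may be negative)  |

Implied probabilities are normalised to sum to one.  Negative CUE
weights are inherent to the Euclidean likelihood; they are flagged on
the results object (`has_negative_weights`), never clipped.

Numerical choices:

* **Inner problem (EL/ET).**  Strictly concave; safeguarded Newton with
  an Armijo backtracking line search, gradient tolerance 1e-10, at most
  100 iterations.  EL uses Owen's pseudo-logarithm — `log x` for
  `x ≥ 1/n`, its second-order Taylor extension below — so the objective
  is globally smooth and finite.  When a hypothesised value pushes the
  required mean outside the convex hull of the moment support, the
  profiled criterion simply becomes large and the value is rejected,
  instead of the solver crashing; this matters most for EL on
  heavy-tailed data, where instability is a known weakness of the
  method.
* **Inner problem (CUE).**  Closed form, `λ = −S(θ)^{-1} ḡ(θ)` with
  `S = n^{-1} Σ g_i g_i'`; the profiled objective equals the
  continuous-updating GMM criterion `½ ḡ'S^{-1}ḡ` (an identity used as
  a test oracle).  A singular `S` falls back to the pseudo-inverse and
  is flagged.
* **Outer problem.**  The moments are linear in `θ`, so the envelope
  gradient of `Q` is exact and cheap:
  `∂Q/∂θ = (1/n) Σ ρ′(λ̂'g_i) (∂g_i/∂θ)'λ̂`.  BFGS from the
  closed-form initialiser (group means and covariate grand means),
  gradient tolerance 1e-9, with a Nelder–Mead fallback if BFGS reports
  failure.  With `k = 0` the model is just-identified and the
  initialiser is already the exact solution — a property asserted in
  the tests for all three families.
* **Non-convergence** is a flag, not an exception: the simulation layer
  excludes failed replicates from aggregates per method and reports the
  count (at the observed rates, a few per ten thousand concentrated in
  EL on t(3) data, the handling is numerically immaterial either way).

## Test-inversion confidence intervals

For a hypothesised `Δ0`, the profiled statistic is

```
D(Δ0) = 2n [ min_{μ1, μx} Q(μ1, Δ0, μx) − Q(θ̂) ]
```

asymptotically χ²(1) under the null for all three families (they are
first-order equivalent; no small-sample correction is applied — Bartlett
correction and bootstrap calibration are out of scope).  The 95% CI is
`{Δ0 : D(Δ0) ≤ 3.841459}`.  Endpoints are located by doubling a step of
one unadjusted-difference standard error away from `Δ̂` (up to 20 such
standard errors, widened once to 40 before flagging failure) and then
Brent root-finding to 1e-6 on the `Δ` scale.  Restricted fits are
warm-started from the nearest previously solved restriction.  Degenerate
data with no outcome variability yield a zero-width interval.  The same
machinery profiles any single parameter, which is how the per-parameter
CIs of `analyze_dataset` (μ1, Δ, μx) are produced.

## ANOVA/ANCOVA comparator

OLS of `y` on `[1, z, x_1..x_k]`; `Δ̂ = −` (coefficient on `z`); with
`k=0` this is exactly the pooled-variance two-sample t procedure.  HC3
covariance `(X'X)^{-1} X' diag(e_i²/(1−h_ii)²) X (X'X)^{-1}` with
leverages `h_ii`; both classical and robust intervals use `t(n−p)`
quantiles (slightly conservative; common practice).  No
treatment-by-covariate interaction terms are included even when the
data-generating process has them — that deliberate misspecification is
the stress the heteroscedastic scenarios are designed to expose.

## Synthetic data generator

`Scenario` draws `(y0, x1, x2)` from one of three families, each
standardised to mean 0, variance 1 and equicorrelation ρ:

* **normal** — Cholesky transform of iid normals;
* **t3** — multivariate t with 3 df and scale matrix `C/3`, so the
  marginal variances are `(ν/(ν−2))·(1/3) = 1`;
* **lognormal** — coordinatewise `exp` of a latent Gaussian, then
  centred.  Unit lognormal variance forces the latent variance `s²` to
  solve `e^{s²}(e^{s²}−1) = 1`, i.e. `e^{s²}` is the golden ratio;
  the latent cross-covariance solves `e^{s²}(e^{s_ij}−1) = ρ`, which is
  feasible (positive definite) for all ρ ∈ [0, 1).

Group assignment is the deterministic block layout (first `n(1−δ)`
observations are controls); because the generated rows are exchangeable
this is distributionally equivalent to randomized assignment.  Treated
outcomes are transformed as `y = sqrt(v1)·y0 + β2(x1 + x2)`; controls
get `y = y0 + Δ_true`, bit-identical to `y0` when `Δ_true = 0`.  The
`sqrt(v1)` scaling is the reading consistent with the closed-form
group-2 moments

```
Var(y|z=1) = v1 + 2ρkβ2√v1 + β2²k(1+(k−1)ρ)
Cor(y,x_j|z=1) = [ρ√v1 + β2(1+(k−1)ρ)] / sqrt(Var(y|z=1))
```

which reproduce the five stress cases exactly (Case 1: 4.16/0.71,
Case 2: 2.75/0.75, Cases 3–5 variances 1/2/2).  Note the transform
changes the group-2 variance and outcome–covariate correlation but not
the moment conditions above, so the GEL estimators remain valid while
the classical ANCOVA assumptions break.

A second generator emulates a dust-control lead-exposure prevention
trial from its summary statistics: bivariate normal (outcome,
baseline covariate) with means (1.82, 1.07), SDs (0.58, 0.52),
correlation 0.35, 100 subjects per arm.  Effect sizes are expressed in
outcome-SD units: the control mean is `1.82 + 0.58·Δ`, so ANCOVA power
at Δ=0.5 lands near 0.96, whereas a raw-scale shift of 0.5 would push
it to ≈1.

What the generator does *not* emulate: real covariate distributions
(skewed, bounded, measurement error), missing data, non-compliance, or
stratified randomization.  Passing the simulation benchmarks therefore
demonstrates correctness of the estimators and calibration under the
stated families, not robustness to every feature of real trial data.

## Reproducibility and problem sizes

Every stochastic routine takes a seed; a root `SeedSequence` spawns one
substream per replicate, so results are bit-identical across runs and
independent of any parallelisation or batching.  The package's own
evaluation runs the OLS-family surfaces at 10,000 replicates (a
vectorised batch path makes these take seconds) and the GEL
test-inversion surfaces at 1,000 replicates — the package's chosen
trade-off, since CI inversion costs ~20 restricted fits per replicate;
tolerance bands in the tests are 3 binomial/Monte-Carlo standard errors
at the replication actually used.  `reproduce_table` accepts
`gel_reps=10_000` for full-scale runs.

## Known limitations

* EL (and to a lesser extent ET) undercovers on heavy-tailed data
  (t(3) coverage ≈ 0.92 at n=200); this is a property of the method —
  reproduced, not repaired.  Bartlett/bootstrap calibration are not
  implemented.
* The χ²(1) calibration is asymptotic; no finite-sample correction.
* Only two-arm trials, identity balance functions f(x)=x, and at most
  two adjustment covariates are exercised (the moment layout itself
  generalises in k).
* CUE intervals require an invertible second-moment matrix per
  restricted fit; near-degenerate data fall back to pseudo-inverse
  solves with a diagnostic flag.
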
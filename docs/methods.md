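# Methods

## Empirical Lorenz construction

A sample of n non-negative sizes is sorted ascending (ties kept as distinct
observations, each with rank weight 1/n) and mapped to points
`x_i = i/n`, `y_i = (sum of the i smallest sizes)/(total size)`, i = 1..n,
with the origin (0,0) as an implicit anchor. Leading zeros produce a
horizontal run `y = 0`. This per-observation convention is exact for
individual data; grouped/binned (quantile-share) input and observation
weights are out of scope.

The discrete ("actual") Gini index is the trapezoid value
`G_pop = 1 − Σ (x_i − x_{i−1})(y_i + y_{i−1})` (origin prepended). The
default reported variant multiplies by `n/(n−1)`; this sample correction
removes the bias from each observation being compared against itself and is
what makes the discrete Gini of the extreme-inequality benchmark equal
0.495 rather than the raw trapezoid value 0.490. Descriptive statistics use
the sample (n−1) standard deviation for the same reason: it reproduces the
benchmark's printed SD of 9.80.

## The universal model

```
y(x) = (1−ρ)·L(x) + ρ·[(1−ω)·E(x) + ω·Π(x)],  u = (x−δ)/(1−δ)
L(x) = (2/(P+1))·u  for δ ≤ x < 1,  L(1) = 1,  L = 0 for x < δ
E(x) = u^P,   Π(x) = 1 − (1−u)^(1/P)          (both 0 for x < δ)
```

with `0 ≤ δ < 1`, `0 ≤ ρ ≤ 1`, `0 ≤ ω ≤ 1`, `P ≥ 1`. Each component
integrates to `(1−δ)/(P+1)`, giving the closed-form Gini
`1 − 2(1−δ)/(P+1)`, independent of ρ and ω.

Numerical conventions:

* The linear component's piecewise value `L(1) = 1` is implemented literally.
  For ρ < 1 and P > 1 the curve therefore has a jump discontinuity at x = 1 —
  a mass atom at the top rank. This is deliberate: it is what lets the model
  interpolate a one-large/many-equal sample exactly, and it does not affect
  the area (a single point has measure zero). `check_lorenz_conditions`
  reports the jump magnitude `(1−ρ)(P−1)/(P+1)` rather than failing.
* `0^0 = 1` by continuity in the SCS form; `Π(1) = 1` by continuity.
* Monotonicity and convexity are verified by finite differences of the
  implemented curve on a dense grid (first differences ≥ −1e−12 everywhere,
  second differences ≥ −1e−10 on the convex portion x > δ, excluding the
  cell that spans the jump), not by transcribing analytic derivative
  expressions.
* Quadrature (SCS Gini, test oracles) uses adaptive Gauss–Kronrod
  integration with absolute tolerance 1e−9, with the integrand split at δ
  for the universal model; the Pareto term's infinite derivative at x → 1 is
  integrable and handled by the adaptive subdivision. A result whose error
  estimate exceeds the tolerance by two orders of magnitude raises instead
  of returning silently.

## Comparator models

SCS: `y = x^γ (1−(1−x)^α)^β`, γ ≥ 0, 0 < α ≤ 1, β ≥ 1; no closed-form Gini,
computed by quadrature. S: `y = (1−λ+η)x + λx^(a1+1) − η(1−(1−x)^(a2+1))`
with λ ≥ 0, a1 ≥ 0, a2 + 1 > 0, η·a2 ≥ 0, η·a2 + λ ≤ 1, and closed-form
Gini `λ(1 − 2/(2+a1)) + η(1 − 2/(2+a2))`. η ≥ 0 is additionally assumed:
the printed constraints admit η < 0 only in degenerate combinations and all
published parameterizations are non-negative.

## Fitting

Parameters minimize `SSE = Σ_i (y_i − ŷ(x_i))²` over all n empirical points
(the final point (1,1) included; it is fit exactly by construction for the
universal and S models). The SSE surface is multimodal and exactly flat in ω
whenever ρ = 0, so a single local search is not reliable. The default
procedure is multistart bounded local optimization, 32 starts, seed
20230323:

* data-driven starts first — δ̂ from the empirical zero run, P̂ from
  inverting the closed-form Gini at the discrete Gini of the data — plus a
  few fixed corner starts;
* remaining starts drawn sequentially from a seeded generator (uniform on
  bounded parameters, log-uniform on scale parameters). Sequential draws
  make the start list prefix-stable, so increasing the start count can only
  improve (never worsen) the returned SSE, and two runs with the same seed
  are bit-identical.
* local solver: trust-region-reflective least squares for the universal and
  SCS models (box constraints only); SLSQP with the explicit inequality
  `η·a2 + λ ≤ 1` for the S model, followed by a trust-region polish when the
  constraint is inactive at the optimum.
* open/strict bounds are realized as closed numerical boxes:
  δ ≤ 1 − 1e−6, α ≥ 1e−6. Unbounded-above parameters get generous boxes
  (P ≤ 1000, β ≤ 500, γ ≤ 100, a1/a2 ≤ 1000, η ≤ 1e6) that cover all
  published fits with headroom.

Among starts whose final SSE ties within 1e−12 the smallest ρ, then ω, then
δ wins, so redundant components are reported as 0. After selection the fit
is canonicalized: ρ ≤ 1e−6 (linear-only fit, ω unidentified) snaps ρ and ω
to 0; P = 1 with δ = 0 (egalitarian line, all components coincide) snaps ρ
and ω to 0. Canonicalization asserts the SSE is unchanged up to the analytic
perturbation bound `2ε·sqrt(n·SSE) + nε²`.

`profile_omega` exposes the flat-Gini direction directly: it sweeps ω with
ρ = 1 and (δ, P) fixed and returns the SSE profile — the Gini is constant
along it while the curvature, hence the fit, changes.

An optional quantile-grid mode (`FitConfig.grid_points`) thins the objective
to an even rank subsample for very large n; it is off by default because the
per-observation objective is the definition of the method.

## Goodness of fit

`R² = 1 − SSE/SST` with SST about the mean of y (undefined and flagged when
y is constant); `MSE = mean((y−ŷ)²)`; `MAE = mean|y−ŷ|`; `MAS = max|y−ŷ|`;
`IIM = Σ y_i log₁₀(y_i/ŷ_i)` with y = 0 terms contributing 0 (continuity
limit) and a y > 0, ŷ = 0 term making IIM infinite (flagged, not raised —
horizontal-segment models legitimately predict ŷ = 0 where y = 0).
Individual IIM terms can be negative; the quality semantics are "smaller
absolute value is better". Statistics are reported unscaled. Note that some
published comparison tables print the raw error sum (SSE) in their MSE
column — e.g. an SCS fit of the benchmark dataset here gives SSE 0.3698 and
MSE 0.0037 over n = 100 points; when comparing against such tables, multiply
the MSE reported here by n.

## Synthetic data

The generator produces the three regimes the models are built for, as
first-class reproducible scenarios:

* `hypothetical` — n_small equal sizes plus one large; defaults (99, 1, 99)
  are the extreme-inequality benchmark (n = 100, mean 1.98, sample SD 9.80,
  actual Gini 0.495).
* `zero_inflated` — `floor(n·zero_fraction)` zeros plus positives from a
  classical Pareto (minimum 1, tail exponent b = 1.5 by default, a realistic
  heavy tail for event-size data) or a lognormal (μ = 0, σ = 1); seeded and
  deterministic.
* `model_conformant` — sizes `s_i = y(i/n) − y((i−1)/n)` first-differenced
  from a prescribed universal-model curve, so the empirical Lorenz points of
  the output lie exactly on that curve at `x_i = i/n`; the jump at x = 1
  (when ρ < 1) lands in the single largest observation. These samples make
  parameter recovery exactly solvable and are the fixtures for the
  round-trip tests.

What the generator does **not** emulate: sampling noise around a population
Lorenz curve, measurement error, and the full empirical irregularity of real
datasets. Passing recovery tests therefore demonstrate correctness of the
estimation machinery on data the model can represent, not robustness to
misspecification; fits to real data are assessed by the goodness-of-fit
battery instead.

## Problem sizes and runtimes

Default test and acceptance problem sizes are desk scale: the n = 100
benchmark, recovery grids of 120–400 points, dense-grid condition checks at
1000–2000 points, 100-point parameter sweeps for the quadrature oracles. A
full fit of all three models to a 100-point dataset takes on the order of a
second; the whole suite runs in well under a minute.

## Known limitations

* The universal model's jump at x = 1 means its implied size density has a
  point mass at the top; deriving implied densities from fitted curves is
  out of scope.
* The S model is flexible enough to approximate the two-segment benchmark
  shape with an extreme power term (a1 ~ 10³) when the optimizer is
  thorough; spreadsheet-solver fits reported in the comparison literature
  for that dataset correspond to a poorer local optimum.
* Printed-table parameters elsewhere are 2-dp roundings; Gini values
  recomputed from them can differ in the third decimal (the closed form is
  sensitive to P when P is large).
* No standard errors or confidence intervals for fitted parameters, and no
  formal model-selection criteria — the estimator is least squares on
  cumulative shares, whose error structure is strongly dependent across
  points.
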
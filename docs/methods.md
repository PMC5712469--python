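# Methods

## The simulated world

A "study" is a bivariate linear regression y = βx + ε analysed by OLS with
intercept. Fixed parameters (`SimConstants`):

| parameter | default | meaning |
|---|---|---|
| σ_x | 2 | sd of the predictor (β = 0.5, 1, 1.5, 2 correspond to r ≈ 0.1, 0.2, 0.3, 0.4) |
| σ_ε | 10 | sd of the regression error, so se(β̂)² ≈ σ_ε²/(N σ_x²) = 25/N |
| N law | round&#124;N(μ_N, 150²)&#124;, N > 30 | right-skewed study sizes; mean ≈ 165 at μ_N = 100, ≈ 500 at μ_N = 500 |
| α | 0.05 | significance threshold throughout (two-sided t-test in primary studies) |
| collider weights (γ, γ_y) | (0.5, −0.5) | z_j = γx + γ_y y + N(0, 10²) |
| retry cap | 9 | extra datasets an author may collect under the file-drawer |
| caliper widths | 3, 5, 10, 15% | multiplicative windows around z₀.₉₇₅ |

The heterogeneous effect condition draws a **study-level β ~ Uniform(0, 2)**
(τ² = 1/3). A discrete five-point mixture is available
(`BetaSpec.discrete`), but the continuous law is the default: it is the
specification whose bias-free Q-based I² averages 68.6% (μ_N = 100) and
86.9% (μ_N = 500) — the heterogeneity levels this design is built around —
whereas the discrete mixture (τ² = 0.5) yields ≈ 76.6% / 90.8%.

### Behaviour

An author whose first fit is non-significant **or negative** and who has
bias intent (Bernoulli draw per study at the cell's intent level) commits a
bias procedure:

* **file-drawer** — up to 9 fresh datasets, each with a newly drawn N and
  the *same* study-level β (retries re-sample the same population; letting
  β be redrawn per retry was evaluated and distorts the success-given-
  committed profile of the heterogeneous cells). The first significant
  positive estimate is published.
* **p-hacking** — the same dataset, refitted with the 7 non-empty subsets
  of 3 collider covariates in a fixed order (singletons, then pairs, then
  all three). A collider is caused by both x and y; conditioning on it
  biases the slope. With weights (0.5, −0.5) the population partial slope at
  β = 0 is +0.2, so the search is a workable route to positive
  significance — roughly 10 points less effective than the file-drawer,
  and deliberately unrelated to the standard error. (With weights
  (0.5, +0.5) the induced bias is −0.2 and the strategy essentially never
  succeeds; that variant is available via `SimConstants.gamma_y`.)

If no attempt qualifies, the attempt with the smallest one-sided p-value
toward a positive effect (p/2 if es > 0, else 1 − p/2) is published — the
author salvages the result closest to the goal — keeping K constant. A
study is *committed* if it executed a procedure and *successful* if the
published result is significant positive.

### Two equivalent generation routes

First attempts and file-drawer retries are drawn directly from the exact
finite-sample OLS law given N (slope ~ N(β, σ_ε²/S_xx) with
S_xx = σ_x²·χ²(N−1); s² = σ_ε²·χ²(N−2)/(N−2) independent), which is
hundreds of times faster than generating raw data. p-hacking always
operates on fully generated datasets; its batch engine evaluates all eight
models exactly from per-study centred cross-moment matrices. Unit tests
verify the two routes agree in distribution (KS tests on slope and
standard error) and that the batch engines match the per-study reference
implementation.

## Meta-analytic layer

Fixed-effect pooling with weights 1/se²; I² = max(0, (Q − (K−1))/Q)·100
from Cochran's Q; meta p-values are two-sided normal. The **deflation
factor** of a run is p_FE(published)/p_FE(first attempts), computed on the
log scale (`log_ndtr`) so that runs with |z| in the hundreds still yield
exact ratios instead of 0/0. It is identically 1 in bias-free cells.

## Test formulations

Sidedness and exact statistics are deliberately isolated, one function
each, because more than one defensible dialect exists:

* **FAT**: intercept t-test (df = K−2) of z on 1/se, one-sided (>0) by
  default; two-sided available. Hand-rolled closed form, cross-checked
  against statsmodels OLS to 1e-10.
* **p-uniform**: conditioning effect θ̂ = fixed-effect estimate from all
  studies; selection = the study's own two-sided p < α with es > 0;
  L = Σ−ln qᵢ against Gamma(m, 1), rejecting in the lower tail (qᵢ piled
  near 1 = just-significant excess). Log-scale tail ratios throughout.
* **TES**: E = Σ per-study two-sided normal-approximation power at θ̂; O
  counts significant studies of either sign (the test's sample is all
  studies; under the one-sided alternative the negative contribution is
  negligible but keeps E and O on the same scale at β = 0). One-sided via
  the signed root of the two-cell A statistic, p = Φ̄(sign(O−E)√A). The
  measured false-positive rate is ~0.02, conservative at every K.
* **caliper tests**: multiplicative window, over side closed at z_crit
  ("just significant" counts as over); exact one-sided binomial test.
  An additive dialect (± w in z units) is available via configuration.

Each test returns `applicable=False` on degenerate samples (no significant
positive study, empty caliper, constant precision) rather than raising, so
rates aggregate over the applicable runs only — at K = 100 the narrow
calipers are frequently empty, which is itself a finding about their
usable sample.

## Experiment design and aggregation

100 cells = 5 β-specs × 2 μ_N × 2 K × {no bias; 50%/100% intent ×
file-drawer/p-hacking}. Child RNG streams are `[master_seed,
canonical_cell_index, rep]`, so any subset of the grid reproduces
bit-identically in any execution order.

Replication planning uses n = ⌈(z₁₋α/₂ + z_power)² p(1−p)/δ²⌉: 3,729 per
bias-free cell (δ = 1 point around 5%) and 1,545 per bias cell (δ = 3
points around 77–80%) for a full study (~198k runs). The package defaults
are scaled to 500/200 (26,000 runs, a few minutes); constants of the
summary regressions then carry Monte Carlo standard errors of roughly one
percentage point.

Summary regressions (classical standard errors, per-run unit of analysis):
committed share on {N=500, β dummies} per intent level; success-given-
committed (runs with ≥1 committed study) on {N=500, β dummies, p-hacking};
deflation on {p-hacking, centred committed and successful shares in
10-point units}; per-test significance indicators on {K=1000, I²/10} for
bias-free runs (false-positive rate) and additionally {p-hacking, centred
shares} for bias runs (power). Centring uses the realised means of the
run set so constants stay interpretable under rescaled replication counts.

## What the generator does and does not emulate

It emulates selection pressure on a simple, correctly specified linear
model: homoskedastic normal errors, independent studies, one-sided
selection for positive significance, and two specific author behaviours.
It does not emulate optional stopping, outlier exclusion, subgroup
fishing, two-sided selection, non-normal errors, binary outcomes, or
correlated estimates from shared datasets. Passing tests therefore show
that the detection methods behave as measured under this DGP — not that
they perform equally on real literatures, where heterogeneity structure
and selection mechanisms are richer.

## Numerical choices

* p-values floored at the smallest subnormal double, ratios of extreme
  tail probabilities computed via `log_ndtr`.
* Sample-size rejection sampling rounds before truncating (strictly > 30,
  so min N = 31); p-values of primary fits use the t distribution with
  residual df, which matters near N = 31.
* File-drawer retries are generated all-at-once and the earliest
  qualifying draw selected — equivalent to sequential stopping because
  retries are independent.
* Degenerate OLS fits (zero residual variance) report a floored standard
  error rather than failing.

## Known limitations

* The deflation factor, computed exactly, is extremely small whenever the
  underlying effect or K is large (the selected sample shifts the
  fixed-effect z by several units); its regression constant (~0.07) is
  therefore dominated by the near-null cells. Alternative per-study-ratio
  summaries behave more smoothly and are easy to add, but the meta-level
  definition is the principled one and is kept.
* The conditional power model is linear in covariates while the underlying
  cell powers saturate at 1.0 in all full-intent cells; its constant is an
  extrapolation and should be read together with the per-cell rate table
  (`rates.csv`), not in isolation.
* The caliper tests' power constants at K = 100 depend strongly on where
  just-significant t-statistics land relative to the normal critical
  value; with t-distribution significance at small N they sit slightly
  above 1.96, diluting the narrowest calipers.
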
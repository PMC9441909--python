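# Methods

This note documents the statistical machinery, the synthetic-data
generator, the numerical choices, and the limitations of `smdsnet`.

## Measurement model and first-stage statistics

Each categorical item is treated as a discretised standard-normal latent
response (probit link).  For a binary item coded 0/1,
`P(x_j = 1) = 1 − Φ(τ_j)`; a K-category item has K − 1 increasing
cut-points with `P(x_j ≤ c) = Φ(τ_jc)`.  Estimation is limited-information
and two-stage, the standard approach for categorical SEM at this sample
size:

1. thresholds from the univariate margins (`τ̂ = Φ⁻¹` of cumulative
   proportions);
2. each pairwise tetrachoric/polychoric correlation by maximum likelihood
   given the thresholds.  For binary pairs this reduces to matching the
   (1,1) cell probability `Φ₂(−τ_j, −τ_k; ρ)` and is solved by a
   safeguarded Newton iteration vectorised over all pairs; general
   ordinal pairs minimise the multinomial deviance over ρ by bounded
   scalar search.  ρ is clamped to ±0.999 (boundary estimates are
   flagged); a 2×2 table with an empty cell receives the +0.5 continuity
   correction on all four cells.

The bivariate normal CDF is computed in-package by a vectorised
Gauss–Legendre scheme (single-integral reduction for |ρ| ≤ 0.925 and the
near-singular expansion otherwise, after Genz).  It agrees with
`scipy.stats.multivariate_normal.cdf` to ~1e−13 — scipy's implementation
is kept as the independent oracle in the test suite — but is orders of
magnitude faster for the ~10⁴ small rectangle probabilities one analysis
needs.

The joint asymptotic covariance Γ of all thresholds and correlations is
obtained from stacked per-observation estimating equations (an
M-estimator sandwich): threshold equations are cumulative-indicator
residuals, correlation equations are the pairwise likelihood scores, and
the block-triangular Jacobian of the system is evaluated analytically
from bivariate-normal densities.  A nonparametric bootstrap of the same
variances (provided as `bootstrap_asy_var`) serves as a validation oracle
in the tests.

## DWLS fitting, scaled statistic, fit indices

All structured models minimise
`F(θ) = (s − σ(θ))ᵀ W (s − σ(θ))` with W the inverse *diagonal* of the
asymptotic covariance of the stacked statistics s (diagonally weighted
least squares).  Optimisation uses L-BFGS-B with analytic gradients
(analytic Jacobians for factor and multigroup models; central differences
for the residual-network model, whose scaling diagonal makes the
analytic form unrewarding).  Convergence: relative objective change
below 1e−12 or 500 iterations.

* Standard errors are sandwich estimates using the full Γ.
* The test statistic is mean-adjusted (Satterthwaite-style):
  `T = T₀ / SF` with `SF = tr(U Ξ) / df`, where U is the DWLS residual
  projection operator and Ξ = Γ/n.  Under a true model E[T] ≈ df, which
  the suite verifies by simulation.  A mean-and-variance-adjusted variant
  is not implemented; with N ≈ 13,000 and df ≥ 17 the difference is
  immaterial for the decisions the pipeline takes.
* `RMSEA = sqrt(G · max(T − df, 0) / (df · N))` (G = number of groups,
  the multiple-group convention), with the 90% interval from inverting
  the noncentral-χ² coverage.  The denominator uses N, not N − 1.
* CFI compares noncentrality against the zero-correlation baseline with
  free thresholds; SRMR is the RMS of correlation residuals (threshold
  residuals excluded).
* Nested models are compared with the trace-based scaled difference
  statistic; the plain difference is also recorded.
* Model selection in the network searches uses a pseudo-BIC
  `T + k·ln N` defined on the *scaled* statistic.  The raw DWLS minimum
  is deflated relative to a likelihood deviance by roughly the scaling
  factor (≈ 0.7 here), so penalising it with ln N would implicitly raise
  the addition threshold by ~40%; the scaled statistic is the
  χ²-calibrated analogue.  The Ising branch uses the exact
  `−2ℓ + k·ln N`.

Robust score tests (modification indices) for a fixed parameter use the
profiled gradient direction with a sandwich variance, so their null
distribution is χ²(1) even though the weight matrix is diagonal; this is
what calibrates the α = 0.005 screens in the structure search and the
partial-invariance search.

## Residual network and Ising models

The residual network model keeps the single factor and adds a sparse
partial-correlation matrix Ω on item residuals:
`Σ = ΛΛᵀ + Δ(I − Ω)⁻¹Δ`, with Δ chosen so every latent response keeps
unit variance.  During optimisation the inverse of I − Ω uses an
eigenvalue floor (1e−6) so line searches that leave the PD cone see a
finite objective; the optimum itself is interior.  An empty structure
reproduces the plain one-factor fit to 1e−8 (tested).

The Ising model on {0,1}⁹ is fitted by exact Newton–Raphson ML: the
partition function, moments and Fisher information come from enumerating
all 2⁹ states (the implementation allows J ≤ 20).  Interactions use the
`Σ_{j<k} w_jk x_j x_k` convention (no double counting).  Wald tests use
the observed (= expected) information; score tests for absent edges
profile out the free parameters.  A constant item (separation) raises an
error, and bootstrap replicates that hit separation are dropped and
counted.

The five-step search is implemented verbatim: candidates are removals of
edges with p > α and additions of absent edges with modification-index
p < α; every candidate is refitted; the best BIC improvement is applied;
remaining candidates are re-evaluated against the updated model and
applied while they still improve; then screening starts afresh; the
search stops when nothing improves.  Exact BIC ties break
lexicographically on the edge pair, and an edge toggled more than three
times terminates the search with a warning.

Centrality follows the usual weighted-network conventions: strength
`Σ_j |w_ij|`; distances `1/|w|`; closeness `1/Σ_j d(i,j)` (computed over
the reachable set and flagged when the graph is disconnected, with the
harmonic variant reported alongside); betweenness by shortest-path
counting with fractional tie-splitting.  The rank bootstrap resamples
rows, refits the Ising model with the structure held fixed (thresholds
and weights both re-estimated), ranks nodes per index (1 = most central,
ties averaged), and reports percentile intervals rounded outward to
integer ranks.

## Multigroup invariance

All groups share the delta parametrization with every latent-response
variance fixed at 1, so group g's implied threshold statistic for item j
is `τ_j − λ_j α_g` and its implied correlation is `λ_j λ_k ψ_g`.
Identification per level: configural — all α_g = 0, ψ_g = 1, everything
else group-specific; metric — loadings shared, ψ free except the
reference; scalar — thresholds also shared (a *partition* of groups per
item supports partial invariance, including patterns like "varies by
gender only" in a gender × age model); latent means — additionally all
α_g = 0.  This reproduces the degrees-of-freedom ladder 54/62/70 (two
groups), 81/97/113 (three), 162/202/242 (six, full scalar) that the
constraint arithmetic implies.

Partial-invariance search frees the threshold cell (item, group) with the
largest robust modification index, refits, and stops at the first model
meeting the level's Δ criteria — so on synthetic data with several small
injected offsets it may stop before freeing every offset item (the
criteria are satisfied early); at most J − 2 items may be freed to
preserve anchoring.  Group means are reported either against the
reference group or in the standardized parametrization (grand mean 0,
average variance 1) whose pairwise mean differences are Cohen's d; the
two parametrizations give identical standardized contrasts (delta-method
SEs on the fitted (α, ψ) covariance), which is tested to 1e−6.

## Structural model

The construct-validity model is a correlated-factors model over all item
blocks (binary symptoms + ordinal auxiliary scales), fitted by the same
DWLS machinery on the joint polychoric summary; factor variances are
fixed at 1 and the 8×8 latent correlation matrix is free.  A slightly
indefinite estimate is shrunk toward the identity just enough to reach
the PSD cone.  `attenuation_check(r, ω₁, ω₂) = r·sqrt(ω₁ω₂)` gives the
classical expected sum-score correlation; for discretised items it is an
approximation — the factor-attributable part of a categorical sum score
is nonlinear in the factor — and overpredicts by up to ~0.03–0.04 for
the coarsest (binary) block.  Exact population sum-score correlations
can be computed from rectangle probabilities (the tests do), and the
suite checks the closed form within 0.06 while checking the exact value
tightly.

## Reliability

`omega_reliability` reports McDonald's ω on two scales: the latent scale
`(Σλ)² / ((Σλ)² + Σ(1 − λ²))` and the sum-score (categorical) scale — the
factor-attributable share of the model-implied covariance matrix of the
observed items, with item covariances from bivariate-normal rectangle
probabilities.  For the default nine-item profile these are ≈ 0.90 and
≈ 0.78: reported scale reliabilities near 0.77 for binary symptom scales
correspond to the sum-score scale.

## Multiple imputation

Fully conditional specification with 10 iterations and m = 10 by default
(both configurable): binary items are imputed by draws from an
approximate Bayesian logistic posterior (ridge-stabilised IRLS; perfect
separation falls back to a stronger penalty with a warning), ordinal
items by predictive mean matching with k = 5 donors, so imputed values
are always observed donor values.  Predictors are gender, age class and
the per-scale totals over each respondent's *observed* items, with the
target's own-scale total recomputed over its sibling items so the target
never predicts itself.  Pooling follows Rubin's rules with
Barnard–Rubin degrees of freedom; with m = 1 the between-imputation
variance is undefined and the total falls back to the within variance
with a warning.  Fit statistics are pooled by averaging across
imputations with the spread reported (a D2-style pooling of χ² is not
implemented).

## Synthetic-data generator

The generator emulates the survey structure the analysis assumes, and its
defaults are the emulated study's conditions:

* nine binary items with loadings
  (0.75, 0.81, 0.75, 0.57, 0.68, 0.69, 0.74, 0.67, 0.74) and thresholds
  (0.97, 1.06, 0.90, 0.64, 1.10, 1.03, 1.24, 0.62, 1.14);
* N = 13,377 split over gender × age groups (50.9% boys; 4,380 / 4,654 /
  4,343 by age).  Group latent means are explicit inputs (the source
  figure tabulates none): the defaults give gender gaps of ~0 / 0.26 /
  0.36 d at ages 11/13/15 with a mild age trend, and girls' SD 0.90 in
  the two-group setting;
* gender-variant thresholds for tolerance (+0.12 for girls vs boys),
  persistence (−0.23) and escape (−0.20), matching the published
  per-gender threshold values;
* within every group the residual variances are scaled to
  `1 − λ_j² s_g²` so latent responses keep unit variance — the exact
  generating counterpart of the fitted parametrization (without this the
  recovered group means are biased);
* optional residual dependence: residual covariance
  `Δ(I − Ω_gen)⁻¹Δ` on the latent-response scale, which keeps
  tetrachoric theory exact and makes the residual-network model the true
  model;
* seven auxiliary ordinal scales (4, 4, 3, 2, 2, 2, 5 items with 5, 5,
  5, 9, 9, 8, 6 categories) with equal loadings chosen to reproduce the
  stated reliabilities (ω = 0.71–0.93) and construct correlations from
  the published 8×8 latent correlation matrix (its lower triangle, which
  is positive definite; the inconsistent upper triangle is ignored);
  item cut-points default to equal-probability-spaced values;
* missingness per item: MCAR by default at rates spanning the reported
  0.67%–19% range (0.67% for screen time/gaming, 19% for well-being and
  online communication, intermediate elsewhere, 2% for symptom items,
  whose rate is not separately reported), or MAR driven by the observed
  gender label (boys at half the nominal rate).

What the generator does **not** emulate: school-level clustering and the
stratified sampling design, item-level response styles, cross-loadings,
age as a continuous variable, and any non-probit link.  Passing tests
therefore certify the estimators and decision rules under the assumed
measurement model, not robustness to survey-design violations.

## Problem sizes in the test suite

Recovery experiments run at the study scale N = 13,377 with reduced
replication counts (50 for CFA coverage, 50 + 50 for the structure
search, 100 for the invariance ladder); the scaled-statistic calibration
check uses 150 replications at n = 2,000; the imputation-validity check
uses 10 replications at n = 4,000 with m = 5.  These sizes keep the full
suite around three minutes while leaving the binomial margins of the
rate criteria comfortable.  The acceptance script averages each
recovered quantity over 3–5 seeded replications of the full
generate-and-refit path — pure Monte Carlo variance reduction around an
unbiased estimator.

## Known limitations

* Limited-information estimation only; no full-information (IRT-style)
  ML, and no non-diagonal-weight WLS.
* The scaled statistic is mean-adjusted only (no shift or
  mean-and-variance adjustment).
* The DWLS pseudo-BIC, the edge p-value convention (sandwich Wald), and
  the distance transform 1/|w| are documented conventions; other software
  in this space makes different unstated choices, so edge-set counts are
  comparable only qualitatively.
* The Ising fitter enumerates states and is limited to J ≤ 20.
* FCS imputation uses fixed scale-total predictors rather than fully
  conditional item-level models; with the generator's MCAR/MAR
  mechanisms this is sufficient for approximate unbiasedness (tested),
  but pathological MNAR patterns are out of scope.
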
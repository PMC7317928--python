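# Methods

This note documents the statistical model behind `stabsel`, the
numerical and design choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and the problem
sizes the test suite uses.

## Estimation model

Selection gradients are estimated by ordinary least squares on relative
fitness, the classical Lande–Arnold estimator. The response is
w = W / W̄ with W the binary trial outcome, so w takes the two values
0 and n/k (k successes among n pairs) and has mean exactly 1. This is a
linear probability model: its point estimates are the standardized
gradients practitioners report, but its error distribution is far from
Gaussian, so **no OLS standard error is ever used for inference** —
significance comes exclusively from permutation.

Two regressions are fitted per sex. β is taken from the first-order
model only; γ from the second-order model containing all linear,
squared, and cross-product terms. The squared-term coefficients are
doubled before being stored on the diagonal of γ (a quadratic
regression coefficient equals half the surface curvature);
cross-product coefficients enter off-diagonal as estimated. The doubling
convention can be verified internally: the shipped published canonical
eigenvalues sum to the trace of the published γ (with doubled
diagonals) to ≤ 0.005 for both sexes, which would fail if either the
diagonal were raw or the off-diagonals doubled.

The joint two-sex model concatenates both sexes' first- and second-order
terms plus all p_f × p_m between-sex products (66 parameters for five
traits per sex; the fit refuses to run unless n exceeds the parameter
count). Its between-sex block is the interaction matrix — cross-sex
correlational selection. Per-sex β in this model comes from a
first-order regression on the concatenated traits, mirroring the
two-stage convention of the one-sex analysis.

OLS is computed with numpy least squares / pseudo-inverse rather than a
modeling package: permutation inference refits the same design 10,000
times with permuted responses, which reduces to a single
(terms × n) @ (n × iterations) matrix product with the precomputed
pseudo-inverse. statsmodels is used in the test suite as an independent
cross-check of coefficients and r².

## Permutation inference

Fitness scores are shuffled across pairs as a block — each pair's trait
records stay together, only w moves — matching the design in which the
pair is the independent unit. The one-sided proportion p counts
pseudo-estimates **≤** the observed gradient (ties count), and the
two-tailed value is Manly's 2p / 2(1 − p) rule, 1.0 at p = 0.5 exactly.
Two conventions needed deciding:

- **The observed statistic is not added to the null set.** With
  shuffles-only nulls a Monte-Carlo p of exactly 0 is possible but
  uninformative, so proportions of 0 or 1 are clamped to 1/n_iter
  before doubling; the smallest reportable p is 2/n_iter.
- **Curvature along canonical axes** is tested with the eigenvector
  matrix held fixed at the observed decomposition. Re-diagonalizing a
  re-estimated γ inside each permutation would inflate |λ| under the
  null (eigenvalue-sorting bias), which is precisely what the
  fixed-axes procedure avoids. The rotated scores are computed once;
  each iteration refits w* on {yᵢ, yᵢ²} and records the doubled
  squared-term coefficients.

Default iterations: 10,000. The unit tests use 200–1000 for speed; the
calibration test uses 500 null datasets × 1000 iterations.

## Canonical analysis

γ is symmetrized as (γ + γᵀ)/2 before eigendecomposition (guarding
against rounding in transcribed matrices), eigenvalues are sorted
descending so the most stabilizing axes come last, and each eigenvector
row is sign-fixed so its largest-magnitude loading is positive.
Eigenvectors are defined only up to sign, published tables follow no
single sign rule, and θ flips sign with its axis — so tests compare
loadings up to sign, and the reference θ values are computed from the
published rows as printed. θ is reported from the projection mᵢ·β by
default: it is deterministic given printed tables and agrees with the
double-regression estimate for symmetrically distributed predictors
(verified at n = 20,000 within 0.005). Repeated eigenvalues would make
individual axes arbitrary within their eigenspace; tests avoid exact
ties and the decomposition documents this.

## Peak location and confidence region

The quadratic surface on a chosen 2-D score space (by default the two
most stabilizing canonical axes) is refit on residual-bootstrap
replicates y* = ŷ + r*. Depth filtering is applied to the
**coefficient vectors** (six per surface), not to the maxima: the
deepest `retain` fraction (default 0.95, i.e. round(0.95·B) vectors)
define the retained surfaces. Each retained surface is maximized over
the axis-aligned box of the observed scores — the claim being tested is
that the peak lies *within the sampled phenotypic space*, so the search
region is that space, and maxima landing on the box edge are flagged
and counted. The confidence region is the convex hull of the retained
maxima; the point estimate is their centroid (retained-only; averaging
all B maxima is the documented alternative reading).

Numerical details:

- Exact Tukey (halfspace) depth is exponential in dimension, so depth
  is approximated by random projections (default 10,000 seeded unit
  directions; the approximation is an upper bound on exact depth and
  non-increasing in the number of directions). An exact 2-D
  angular-sweep implementation is kept as the test oracle; at 10,000
  directions the approximation agrees with it to within 1/m on
  50-point clouds.
- Box-constrained maximization of a 2-D quadratic is solved exactly by
  candidate enumeration (interior stationary point, edge restrictions,
  corners); higher dimensions fall back to deterministic multi-start
  L-BFGS-B.
- Non-concave bootstrap refits are kept, not dropped: their constrained
  maxima sit on the boundary and are counted in the diagnostics.
  Dropping them would bias the region inward.
- Zero residual noise makes every refit identical; the region then
  collapses to the single true maximum and is flagged degenerate.

Empirical coverage of the nominal 95% region, measured on 200 replicate
well-specified datasets (quadratic surface, curvature −0.3, unit iid
Gaussian noise, n = 498, B = 500), is 0.985 — inside the 99% binomial
band around 0.95, and on the conservative side, as expected for a hull
of retained maxima.

## Thin-plate splines

Surfaces are visualized with the standard thin-plate spline (radial
basis r² log r plus an affine part), solving the penalized system
[[K + nλI, P], [Pᵀ, 0]]. At λ = 0 with distinct sites the spline
interpolates; as λ → ∞ it tends to the least-squares plane (both limits
are tested). The smoothing parameter is chosen by generalized
cross-validation, GCV(λ) = n·RSS / tr(I − A(λ))², minimized over a
log-spaced grid (default 10⁻⁸–10², 41 points); the influence matrix A
is computed by solving the system against the identity. No installed
Python package exposes penalized thin-plate splines with GCV, so this
is implemented directly and cross-checked in the tests against an
influence matrix rebuilt column by column through the fitting path.

## Synthetic data

The generator emulates the study design the analysis assumes: n
independent pairs, five standard-normal traits per sex, and a Bernoulli
outcome whose logit is a Gaussian-style stabilizing surface

    logit P = logit(b) + (z_m − p_m)' C_m (z_m − p_m)
              + (z_f − p_f)' C_f (z_f − p_f) + Σ c·z_f,i·z_m,j

with C negative semidefinite. Success is generated through a logistic
link so probabilities stay valid, while estimation downstream remains
OLS — reproducing the real mismatch between data-generating process and
estimator.

The canned study-like configuration places stabilizing curvature on two
oblique axes per sex (the published m₄/m₅ eigenvector rows), peaks at
the published peak coordinates, and the two reported cross-sex product
terms. Because the logit link compresses effects, the logit-scale
coefficients were calibrated once, by a fixed-point iteration against
the noise-free large-n OLS limit (300,000 trait draws, expected relative
fitness as the response), so that the gradients *recovered by OLS at
standardized scale* match the published values: axis curvatures
(−0.279, −0.317) male and (−0.175, −0.610) female, cross-sex gradients
(−0.076, −0.085), and expected success fraction 216/498. The resulting
constants are frozen in `stabsel.synthetic`.

What the generator does **not** emulate: measurement error in the
morphometrics, non-normal or skewed trait distributions, trait
correlations within or between sexes (identity covariance by default;
configurable), assortative pairing, and any post-copulatory episode of
selection. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to their violation.

## Problem sizes used by the test and acceptance suites

- Permutation calibration: 500 null datasets × 1000 iterations, n = 100.
- Gradient/interaction recovery: one simulated 20,000-pair experiment.
- Region coverage: 200 replicates, n = 498, B = 500 bootstrap refits,
  10,000 depth directions.
- Worked-example linkage: exact, 5 × 5 matrices.

## Known limitations

- The linear probability model can predict fitness outside [0, 1];
  gradients remain valid as best linear/quadratic approximations to the
  selection surface, but predicted surfaces should be read locally.
- The interaction matrix reuses the Lande–Arnold interpretation for
  between-sex products by analogy; it is a description of selection on
  the cross-sex covariance, not a mechanistic model of genital fit.
- Depth-based retention uses an approximate depth; with very small B
  the ranking near the 95% cut can differ from exact depth. This
  perturbs which borderline surfaces are retained, not the hull's
  gross shape.
- The raw centroid-size column may be log-transformed upstream if
  desired; no transform is applied by default.
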
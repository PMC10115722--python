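# Methods

## Models

The substantive model is the unidimensional graded response model (GRM),
reducing to the 2PL for K = 2.  Item i contributes K−1 cumulative logistic
curves `P(U_i >= k | eta) = logistic(alpha_ik + beta_i eta)` with strictly
decreasing intercepts `alpha_i1 > ... > alpha_i,K-1`, so category
probabilities (first differences of the cumulative curves) are positive
everywhere.  The ordering is enforced at construction of `ItemParameters`;
during optimization it is maintained by reparameterization instead (below).
The complete-independence null model is the zero-factor special case with
intercepts only.

An equivalent location–step parameterization (`beta_i`, location `b_i`,
zero-sum steps `d_k`, with `alpha_ik = -beta_i (b_i - d_k)`) is used to lay
out the generating designs; the conversion is exact and invertible for
nonzero slopes.

## Latent prior and quadrature

The latent prior is standard (multivariate) normal.  It is discretized on
a rectangular grid: 49 equally spaced nodes per dimension on [−6, 6],
weights proportional to the normal density and renormalized to sum to one,
matching long-standing IRT software practice.  Multidimensional grids are
tensor products; for correlated factors the weights use the joint density
at the tensor nodes.  The node count and range are configurable; refining
49 → 101 nodes moves small-test pattern probabilities by less than 1e−7
for slopes up to 3, so the default is comfortably inside the regime where
quadrature error is negligible relative to sampling error.

## FIML estimation

The grouped multinomial likelihood is maximized by the Bock–Aitkin EM
algorithm.  The E-step computes each observed pattern's posterior weight
over the grid nodes and accumulates expected per-item category counts; the
M-step maximizes each item's expected complete-data log-likelihood.  For
K = 2 this inner problem is concave in (alpha, beta) and all items are
updated simultaneously by safeguarded Newton steps with step halving.  For
K > 2 the intercepts are reparameterized as `alpha_1` free and
`alpha_k = alpha_{k-1} - exp(gamma_k)`, which makes the ordering
unconstrained, and each item is maximized by L-BFGS-B with an analytic
gradient.

Start values are deterministic — unit slopes and null-model (closed-form)
intercepts — so fits are reproducible without a seed.  Convergence is
declared when the largest absolute parameter change falls below `tol`
(default 1e−4), a parameter-change criterion chosen over a log-likelihood
criterion because slope/intercept accuracy is what the margins consume
downstream.  Slopes are capped at |beta| ≤ 20 with a logged warning to
stop divergence on degenerate data.  Non-convergence at `max_iter` returns
a flagged result rather than raising.  Missing responses are a hard error;
an item with an empty observed category is an error instructing category
collapse (no silent re-coding).

The null model is closed form: `alpha_ik` is the logit of the observed
proportion of responses at or above k.  Boundary proportions (0 or 1) are
an error with guidance to pass a smoothing constant (default none).

## Margins, Xi2, Delta2, M2

The moment basis is cumulative: indicators `1{U_i >= k}` univariately and
products `1{U_i >= k} 1{U_j >= l}` for pairs i < j, giving
s = n(K−1) + C(n,2)(K−1)² moments (465 for n = 30, K = 2; 7080 for K = 5).
For K = 2 this is the standard dichotomous margin vector, and the df
bookkeeping s − dim(theta) reproduces 405 (K = 2) and 6930 (K = 5) for the
30-item designs.  M2 is invariant under any nonsingular linear transform
of the basis (verified as a test), so the choice between cumulative and
category indicators is immaterial.

`Delta2` collects analytic derivatives of every moment with respect to
every free parameter, evaluated by quadrature (logistic-density terms in
the integrand); the null model's Jacobian has intercept columns only.
`Xi2` has entries `E[m_a m_b] − E[m_a] E[m_b]` where cross-expectations
are joint cumulative moments of up to four distinct items.  Products that
share items collapse via `1{U >= k} 1{U >= l} = 1{U >= max(k, l)}`, so the
bulk of the matrix is a single weighted outer product of curve rows and
only the overlapping pairs (cached index structure per (n, K)) are
recomputed.  Both matrices are evaluated at the fitted parameters, i.e.
model-implied, per the standard construction.

M2 is the projected quadratic form in the residual margins.  `Xi2` is
inverted by Cholesky with a 1e−10 ridge fallback (logged); the inner
cross-product uses a pseudo-inverse with relative rank tolerance 1e−8, and
any rank deficit reduces the degrees of freedom correspondingly with a
warning.  Tiny negative values from floating-point cancellation are
clipped at zero (the form is positive semidefinite analytically).
p-values come from the central chi-square survival function.

RMSEA is `sqrt(max(0, (M2 − df)/(df N)))`; its confidence interval inverts
the noncentral chi-square CDF in the noncentrality (Brent's method to
1e−8), with bounds `sqrt(lambda/(N df))` and the lower bound clamped at
zero.  As the confidence level shrinks to zero both bounds converge to the
median-noncentrality value, essentially the point estimate.  TLIRT is the
raw ratio `(X0/df0 − Xm/dfm)/(X0/df0 − 1)` with the null model's own
df0 = s − n(K−1); it is undefined (an error) when the null model already
fits at one per df, and it is not clamped to (0, 1).  The API accepts any
pair of chi-square statistics, so a G²/X²-based index can be formed on
short tests for comparison; G²/X² themselves refuse tests whose K^n cells
exceed the enumeration limit (default 1e6) and point to M2.

## Generating designs

The 30-item design crosses slopes (1.0, 1.5, 2.0) with locations −1.0(0.5)1.0
for items 1–15 and duplicates them for items 16–30; K = 5 uses steps
(1.2, 0.4, −0.4, −1.2).  Three regimes are simulated, all fitted
unidimensionally:

* **null** — the unidimensional GRM itself (correct specification);
* **misspec1** — an independent-cluster two-factor model (first half of
  the items on factor 1, second half on factor 2) with latent correlation
  .8;
* **misspec2** — the two-factor structure plus TKL model error.

For the TKL procedure, slopes are first mapped to factor loadings with the
logistic-to-probit constant c = 1.702:
`lambda = (beta/c)/sqrt(1 + (beta/c)^2)`, uniqueness `1 − lambda^2`,
thresholds `tau = −alpha sqrt(uniqueness)/c`.  Fifty minor-factor loading
columns are drawn normal with mean zero and geometrically decaying spread
(each column's SD 80% of the preceding; the first column's scale is
irrelevant because of the rescaling that follows).  Each item's minor row
is rescaled so the minor factors absorb exactly 10% of that item's unique
variance, the uniqueness shrinks by the same amount so the item's total
variance stays one, and loadings are mapped back to slopes
(`beta = c lambda / sqrt(uniqueness)`) with thresholds held at their
probit-metric values.  Allocating the error proportion from the *unique*
variance is the classic TKL convention; it is also the reading that
reproduces the reference behavior of the model-error cells (fit-index
levels drift far too low if 10% of the *total* variance is reassigned
instead).  The per-item allocation is exact rather than on average, for
determinism.  Minor loadings are drawn fresh each replication.  Majors
stay correlated at .8; minors are orthogonal.

The generator draws latent vectors from the (possibly singular) latent
covariance — the positive-semidefinite boundary, e.g. latent correlation
exactly 1, is handled by an eigendecomposition factor — and samples
categories from the cumulative curves by inverse transform.  What the
generator does *not* emulate: real questionnaires have missing data,
unbalanced category usage, guessing, local dependence beyond the injected
factors, and non-normal traits.  Passing tests therefore certify the
statistical machinery under the stated designs, not robustness to those
features.

## Replication harness and problem sizes

Each replication generates data, fits the substantive and null models by
FIML, and computes M2 for both plus RMSEA and TLIRT.  Per-replication
seeds derive from the cell's master seed by a counter-based scheme
(`default_rng([seed, rep])`), so cells are bit-for-bit reproducible and
safe to parallelize.  Non-converged replications are recorded and excluded
from summaries with a warning.  Summaries report the M2 mean and variance,
rejection rates at .01/.05/.10, means and empirical 5th/95th percentiles
of RMSEA and TLIRT, and TLIRT-cutoff rejection rates at .96–.99.

The package's own study runs at reduced scale: 100 replications for the
K = 2 cells and 50 for the model-error cell (the reference design uses
500), with Monte Carlo tolerances widened accordingly.  The 30-item K = 5
cells are not run routinely — each replication's 7080-square Xi2 is an
overnight-scale computation — and a 10-item K = 5 null cell stands in at
desk scale, checking that M2 stays calibrated (mean ≈ df) and TLIRT stays
at 1 for polytomous data.

## Known limitations

* Unidimensional (or zero-factor) fitting only; multidimensional
  estimation is out of scope, though multidimensional *generation* is not.
* No item-parameter standard errors, no missing-data handling, no
  bifactor/testlet reductions, and none of the corrected or diagonally
  weighted least-squares statistic variants.
* TLIRT's sampling distribution near a cutoff is sensitive to small shifts
  in the M2 distribution; cutoff-based rejection rates at N = 500 carry
  materially more Monte Carlo uncertainty than the index means.
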
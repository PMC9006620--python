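# Methods

## Data model and simulator

Observations sit on an equispaced G x G grid with unit interpoint
distance, indexed by integer coordinates (x, y), 1 <= x, y <= G.
Training data use G = 15 (observational designs) or G = 18
(checkerboard experiments); locations are sampled without replacement
and with equal probability from the grid cells, so all pairwise
distances are strictly positive. Outcome and regressors are drawn as

    B_j ~ MVN(f_bj(x, y), Sigma_b),  independently over j
    A   ~ MVN(f_a(x, y) + B beta, Sigma_a)

with four spatial structures:

| structure | mean surface                         | covariance                                 |
|-----------|--------------------------------------|--------------------------------------------|
| none      | 0                                    | sigma2 * I                                 |
| linear    | (x, y)' gamma, gamma ~ U[-0.5, 0.5]^2 | sigma2 * I                                 |
| edge      | beta_edge * d_edge, beta_edge ~ N(0, 50) | sigma2 * I                             |
| gaussCor  | 0                                    | sigma2 * (tau I + (1 - tau) exp(-(d/r)^2)) |

Defaults: sigma2 = 1, range r = 7.5, nugget tau = 0.25. The edge
distance is d_edge(x, y) = min(x, y, G+1-x, G+1-y), so border rows sit
one unit from the (conceptual) field edge. Every spatially structured
variable draws its own gradient / edge coefficient / correlated noise,
making regressors mutually independent. Linear and edge structures
inflate the marginal variance of a variable; gaussCor redistributes
variance spatially without inflating it (both properties are asserted
by tests).

Multivariate scenarios make 50% of the regressors spatial and draw 20%
of the beta components nonzero *within each group*, from N(0,
beta_sd^2); this keeps the expected spatial share of an unbiased
selector at exactly 50%, the reference point of the red-shift metric.
Univariate null/alternative settings use beta = 0 and beta ~ N(0,
0.25). Study sizes follow the simulation design: n = 100 (univariate
and low-dimensional, p in {10, 20, 50}), n = 50 with p in {100, 200,
300} (high-dimensional), test sets of n = 10 on a 5 x 5 grid so
spacing matches the training sample.

Checkerboard experiments partition the 18 x 18 grid into square
subplots of side 9, 6 or 3 and treat alternating subplots; the n = 100
observed cells are sampled uniformly without replacement (the sampling
scheme on the grid is our assumption; treatment is a property of the
cell). Side 6 gives 9 subplots, hence unequal arms (4 vs 5) and a mild
treatment-edge confounding that the even layouts avoid.

What the simulator does *not* emulate: anisotropic or temporal
correlation, non-Gaussian outcomes, raster/image regressors, real
field-trial layouts with buffer rows or repeated cultivars. Passing
tests therefore demonstrate correct behavior under Gaussian fields with
the structures above, not performance on any particular real field.

## Covariance estimation

The error model is Sigma(sigma2, r, tau) = sigma2 (tau I + (1-tau)
K(r)), K(r)_ik = exp(-(d_ik/r)^2). Parameters are estimated by
profiled ML or REML (REML is the default): mean coefficients and
sigma2 are profiled analytically, leaving a 2-D problem in (r, tau).
Because V = tau I + (1-tau) K(r) shares eigenvectors with K(r), one
eigendecomposition per candidate r makes the tau-profile a cheap 1-D
scan: we evaluate a 31-point logit-spaced tau grid (bounds [1e-4,
1-1e-4]) per r, sweep r over a 10-point log-spaced grid on [0.1, 2 *
max pairwise distance], and refine both coordinates by one parabolic
interpolation step. This is a global search over the whole admissible
box, chosen because the likelihood is ill-posed: range, nugget and
variance estimates are strongly correlated and individually very
variable (tests assert only wide-interval recovery, e.g. median r-hat
in [4, 12] for true r = 7.5 on the full grid). Eigendecompositions at
grid ranges are cached per design, which makes the repeated
re-estimations inside the penalized fits cheap.

`neg_log_likelihood` evaluates the same (restricted) likelihood by
dense Cholesky at explicit parameters — an independent route used to
cross-check the profiled optimizer and tested against the direct
multivariate-normal density.

Whitening uses the symmetric inverse square root W = U diag(1/sqrt(w))
U'; the contract W Sigma W' = I is enforced to 1e-8 and matrices with
eigenvalue ratio below 1e-10 are rejected as singular. MVN sampling
floors eigenvalues at 1e-10 * sigma2, since gaussCor matrices on dense
grids are numerically near-singular.

## GLS

`SpatialGLS.fit` alternates covariance estimation on the current model
(coefficients profiled inside the likelihood) with a whitened
least-squares step, stopping when the mean squared change in fitted
values falls below 1e-6 (max 25 iterations; the covariance step
profiles the coefficients, so convergence is typically immediate).
Wald tests use t statistics with n - p - 1 degrees of freedom,
ignoring the estimated covariance parameters — the common practice,
anti-conservative in principle; the type-I calibration under the null
is verified empirically at study scale. Predictions on new data are
beta0 + B_new beta only: the spatial error term is a property of the
training field and is never extrapolated. If covariance estimation
fails the fit falls back to OLS with a `cov_failed` flag; the
benchmark records such replicates as method failures (their R^2 scores
are set to 0 in study tables, never silently replaced by OLS).

For checkerboard analyses, `add_row_col_dummies` appends indicators
for grid rows/columns 2..G present in the sample (level 1 is the
reference; absent levels are dropped with a log note).

## GLS elastic net

The penalized criterion follows the coordinate-descent convention:
1/(2n) * ||W(A - beta0 1 - B beta)||^2 + lambda (alpha ||beta||_1 +
(1-alpha)/2 ||beta||_2^2), alpha fixed at 0.5. A criterion stated on
the raw residual-sum-of-squares scale with penalty weights 0.5 lambda'
(L1) and 0.25 lambda' (squared L2) is the same problem with lambda =
lambda'/n. Two deliberate normalizations:

* **Whitening uses the correlation factor** (unit diagonal) rather than
  the full Sigma^-1/2. The overall variance scalar would only rescale
  the quadratic term against the fixed penalty, silently changing the
  effective lambda between iterations and against the plain elastic
  net; with unit-diagonal whitening, a fit on data without spatial
  structure coincides with the plain elastic net at the same lambda
  whenever the estimated correlation is (near) identity.
* **Standardization happens after whitening**: regressor columns are
  scaled to unit variance on the whitened, intercept-projected scale,
  and coefficients are reported on the original scale — the default of
  the standard elastic-net software this mirrors. Equivalently, the
  penalty applies to the standardized coefficients.

The unpenalized intercept multiplies the whitened constant column
c = W 1. It is handled exactly: (Aw, Bw) are projected onto the
orthogonal complement of c, the reduced problem is solved by
coordinate descent (scikit-learn's ElasticNet, tolerance 1e-8), and
beta0 = c'(Aw - Bw beta)/(c'c) is recovered in closed form.

The outer loop starts at Sigma = identity (so the first iterate is
exactly the plain elastic net), re-estimates the covariance by REML
from the residuals A - beta0 - B beta with an intercept-only mean
model (conditioning on the changing selected support would bias
sigma2), and stops when the mean squared change in the unwhitened
predictions drops below 2.5e-4 (max 30 outer iterations;
non-convergence is reported, not raised).

Penalty tuning computes held-out mean-centered R^2 along a 100-point
log-spaced lambda path (from the smallest all-zero lambda down to 0.01
of it) and applies the one-standard-error rule: the largest lambda
whose mean CV R^2 is at least the best mean minus the standard error
at the best lambda. For the iterative fit, the path descends with warm
starts — each lambda's fit seeds the next one's covariance — an
internal speed-up; the reported fit at the chosen lambda always starts
from the identity.

The spatial-eigenvector comparator augments B with eigenvectors of the
doubly-centered proximity matrix M C M, M = I - 11'/n, C_ij =
exp(-d_ij / d-bar) with d-bar the average nearest-neighbor distance
(diagonal zero), keeping eigenvalues above 0.25 of the largest. The
proximity kernel and threshold are a dialect choice of the eigenvector
literature; eigenvector coefficients are excluded from selection
metrics and from prediction.

## Evaluation

* Random CV folds have sizes differing by at most one; blocked folds
  are k-means clusters of the raw coordinates (10 restarts, best
  inertia), with unequal fold sizes accepted — spatial contiguity, not
  balance, is the point. Study designs use 10 folds (n = 100) and 5
  folds (n = 50), i.e. fold size 10.
* R^2 centers observed and predicted vectors by their own means before
  comparing (within-field contrasts matter, not baselines); poor
  models can score negative. CV R^2 averages the per-fold values; a
  failed fold fit contributes 0.
* Test-set evaluation trains on the data minus one fold at the lambda
  tuned on the full data, so the training size matches the CV.
* Moran's I uses inverse-distance weights w_ij = 1/d_ij (not
  row-standardized; the global s_w normalization is part of the
  statistic), the conditional variant uses residuals from predictions
  that omit all spatial terms, and every reported value has the null
  expectation -1/(n-1) subtracted so training sets, folds and test
  sets are comparable. The 1/d kernel is kept even though it is
  insensitive to edge effects. Test-set weights are rebuilt on the
  test coordinates.
* Selection metrics: sensitivity TP/(TP+FN), true discovery proportion
  TP/(TP+FP), and the spatial share of the selections (red-shift
  metric, 50% = unbiased). Undefined ratios (empty selections,
  constant vectors) propagate as missing values, never as zeros — the
  single exception being the R^2-of-failed-fit rule above.

## Benchmark scale and reproducibility

Replicate streams derive from (master_seed, crc32-hashed study labels,
replicate index) via numpy SeedSequence, so results are independent of
execution order. Default study sizes are desk-scale (100 univariate /
50 high-dimensional replicates, reduced scenario grids via flags);
full-scale runs (1000 / 200 replicates) are a CLI flag away. The
shipped acceptance script uses 1000 replicates for the null
calibration, 500 for the confounded null, and 50 for each
high-dimensional selection study.

## Known limitations

* Degrees of freedom for GLS Wald tests ignore covariance-parameter
  estimation; calibration is verified empirically, not theoretically.
* The red-shift of the plain elastic net under Gaussian-correlated
  regressors is weak at these study sizes: the excess of spatial
  features among false discoveries is partly offset by the lower
  recovery rate of true spatial predictors (their smooth components
  are nearly collinear across regressors at n = 50), so the overall
  spatial share hovers near the 50% boundary. Under linear gradients
  the red-shift is strong (~65%) and its correction by the GLS elastic
  net (~50%) is clearly visible.
* k-means folds are not guaranteed equal-sized; Moran's I on very
  small folds is noisy even after expectation adjustment.
* The iterative penalized fit is a heuristic alternation; its
  objective is not guaranteed to decrease across covariance updates
  (only within each elastic-net step), and non-convergence, while
  rare, is possible and flagged.
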
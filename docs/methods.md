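# Methods

## Model

`phenomap` fits a sparse Bayesian factor-regression model. For sample
i with expression vector `y_i` (p genes, log scale, centered per gene by
default) and covariate vector `x_i` (intercept plus c columns):

```
y_i = W u_i + xi_i,       xi_i  ~ N_p(0, Sigma),  Sigma = diag(sigma_1^2 .. sigma_p^2)
u_i = Beta x_i + eps_i,   eps_i ~ N_q(0, Phi),    Phi   = diag(phi_1^2 .. phi_q^2)
```

The q latent scores `u_i` (context-specific mapping variables, CMVs)
carry all feature-feature correlation: conditional on `u_i` the genes
are independent, with heteroscedastic noise. The covariates act on the
data only through the CMV means `Beta x_i`, which is what makes a CMV a
joint omics-phenome axis rather than a purely molecular one.

Marginally over `u_i`, `y_i ~ MVN(W Beta x_i, W Phi W' + Sigma)`; this
marginal likelihood (evaluated by the Woodbury identity, only q x q
factorizations) is used for model comparison.

### Priors

* Loadings: ARD — `w_jk | lambda_jk ~ N(0, 1/lambda_jk)`,
  `lambda_jk ~ Gamma(a, b)` (shape/rate). Default `a = b = 1`, giving
  each loading a unit-scale Student-t(2) marginal. This default is
  deliberately scale-bearing, not vague: the likelihood is invariant
  under rescaling a CMV (`W_k -> c W_k`, `u_k -> u_k / c`), and with a
  nearly scale-free loading prior (e.g. Gamma(0.01, 0.01), whose
  marginal is ~ 1/|w|^1.02) nothing pins that scale. In that regime the
  chain drifts to tiny CMV scales, where the CMV-variance prior rate
  `b_phi` dominates the inverse-gamma posterior rate and the drawn
  `phi_k^2` systematically exceeds the realized CMV residual variance —
  which inflates the conditional variance of `Beta` and visibly
  de-calibrates the covariate z-scores (measured null 5% call rate: 0 of
  180 at Gamma(0.01, 0.01) versus 0.061 at Gamma(1, 1)). The unit-scale
  default anchors loadings at O(1) and leaves everything else to the
  data.
* Regression coefficients: row-wise Zellner g-prior,
  `beta_k ~ MVN(0, g * phi_k^2 * (X'X)^-1)`, default `g = n`
  (unit-information). Estimation is invariant to covariate scaling.
* Variances: gamma priors on the precisions, i.e. inverse-gamma on
  `sigma_j^2` and `phi_k^2`, shape = rate = 0.01 (vague, proper). These
  are fine for Sigma and Phi because both are likelihood-identified once
  the loading scale is pinned.
* Spike-and-slab mode: one Bernoulli(pi) indicator per CMV column;
  active columns have `w_jk ~ N(0, v1)` (v1 = 1), inactive
  `w_jk ~ N(0, v0)` (v0 = 0.005). Defaults pi = 0.5. Used for automatic
  selection of the number of CMVs; indicators are drawn with the column
  integrated out so columns can escape the spike.

### Gibbs sampler

All conditionals are conjugate; one sweep draws, in order: U (Gaussian,
shared q x q precision `W' Sigma^-1 W + Phi^-1`), Lambda (Gamma(a + 1/2,
b + w^2/2)), W row-wise (Gaussian, batched q x q Cholesky over genes),
Sigma (inverse-gamma with the per-gene residual sum), Beta row-wise
(Gaussian shrunk by g/(g+1) around the least-squares fit of `u_k.` on
X), and Phi (inverse-gamma absorbing both the CMV residuals and the
g-prior quadratic form `beta_k' X'X beta_k / g`, with shape
`a_phi + (n + c + 1)/2`). Defaults: 10,000 sweeps, 5,000 burn-in, thin
5. Variances are floored at 1e-12 and Cholesky factorizations retry
with escalating jitter (1e-10 to 1e-6).

The conditionals were re-derived from the joint density and are
certified two ways rather than trusted: (1) a joint-distribution
("getting it right") test comparing marginal-conditional simulation
(parameters from the prior, data from the model) with
successive-conditional simulation (alternating Gibbs sweeps and data
redraws) on ten monitored moments — a correct sampler keeps all |z| < 4,
and the test provably has power, since deliberately mis-shaping the
Lambda conditional (shape a instead of a + 1/2) drives |z| above 30;
(2) an exact-oracle comparison on a p=2, n=4, q=1 toy in which
everything except one loading, one noise variance and the latent CMVs is
held fixed, so the marginal posterior is a 2-D integral evaluable by
dense quadrature — the long-run Gibbs mean matches it to ~0.003 (the
test tolerance is 0.02). The joint-distribution check runs its own
moderate-tail hyperparameters (all shapes/rates 3, g = 5): monitored
moments must have finite sampling variance under the prior, which the
vague defaults do not provide; this calibrates the test, not the model.

### Identifiability and post-processing

The likelihood is invariant under (i) permuting CMVs, (ii) flipping a
CMV's sign in W, U and Beta together, and (iii) rescaling a CMV. A raw
chain therefore wanders over these orbits and elementwise summaries
would be meaningless. `align_chain` maps every retained draw to a
canonical representative: columns are greedily matched to the
maximum-a-posteriori draw by absolute loading correlation (the reference
is ordered by decreasing explained variance of Y and signed so each
column's largest-magnitude loading is positive), then each CMV is
rescaled to unit standard deviation across samples (W, Beta, Phi,
Lambda transformed consistently). Every reported quantity — scaled
scores, marginal likelihood, clustering inputs, predictive checks — is a
function of these scale-invariant representatives, so the
canonicalization is a summary convention, not a change to the posterior.
Rotational ambiguity is not removed explicitly; the ARD prior and
diagonal Phi discourage it, and the recovery tests confirm aligned
posterior-mean loadings correlate > 0.98 per column with the truth on
the standard design. Exact orthogonality of CMVs is neither assumed nor
enforced — the model makes them conditionally independent given X, which
is weaker.

Scaled scores are `z = posterior mean / posterior SD`, elementwise, with
entries whose SD falls below 1e-10 flagged undefined rather than
reported as infinite.

## Choosing the number of CMVs

**Regularized BIC.** `BIC = 2*ll - C*log(n)`, with `ll` the marginal
log-likelihood at the maximum-a-posteriori retained draw — the MAP
plug-in (rather than a maximum-likelihood estimate) is what regularizes
the criterion — and `C` the parameter count
`p*q + q*(c+1) + p + q`. The grid fit uses an independent child seed per
q; the highest BIC wins, ties toward smaller q. An alternative
"effective" count that charges only loadings with |z_W| >= 2 is also
computed and reported in the `BicTable`, but it is not the default: on
the standard synthetic design each surplus CMV column raises the plug-in
2*ll by roughly 115 while that count charges it only ~40, so the
criterion becomes monotone increasing in q; the full count recovers the
true q in 10/10 replicates and picks the grid minimum on pure-noise
data.

**Spike-and-slab.** One fit at a generous `q_max` with column
indicators; the effective q is the number of columns with posterior
inclusion probability >= 0.5. Recovers the true q in 10/10 replicates
of the standard design and returns 1 on noiseless rank-1 data.

## Significance calling

Covariate-CMV and feature-CMV associations are called when |z| exceeds
the two-sided standard-normal quantile of the chosen level: 5% for
covariates (1.96) and 0.01% for features (3.89) by default — the much
stricter feature level reflects the ~1000-fold larger number of feature
tests. The z-scores are treated as standard-normal pivots without
multiplicity correction, matching the thresholds' intent; an optional
Benjamini-Hochberg layer is available (`adjust="bh"`) but off by
default. The intercept is never reported as a phenotype. Under a null
simulation (all Beta = 0) the covariate call rate measures 0.05 over 20
replicates, and g/(g+1) shrinkage makes the test very slightly
conservative by construction.

## Functional subtyping

Inputs are assembled from the posterior-mean CMVs plus quantitative
phenotypes: either all CMVs with every significantly associated
phenotype ("universal" subtypes) or one CMV with only its own
significant phenotypes (context-specific subtypes; possibly the CMV
alone). All columns are unit-scaled (mean 0, SD 1, n-1 denominator) so
CMVs and phenotype values are commensurable. Categorical phenotypes do
not enter the joint clustering.

Consensus k-means: per repetition (default 1000), 80% of samples are
drawn without replacement and clustered by k-means with a fresh seeded
k-means++ initialization; the consensus matrix is co-assignment counts
divided by co-sampling counts. Hard labels come from average-linkage
hierarchical clustering of (1 - consensus). Per k in the grid (default
2..7) two stability metrics are computed: the cophenetic coefficient of
the consensus dissimilarities and the mean silhouette width of the
labels on the input matrix (singletons contribute 0). The selected k
maximizes the rank-sum of the two metrics (ties toward smaller k); both
metrics are reported individually so a user can overrule the combination
rule, which is a package choice — the two metrics are stated to be
evaluated jointly but without an explicit rule. k-means++ rather than
uniform-random initialization is likewise a package choice: with single
initializations per repetition, uniform-random starts hit poor local
optima often enough to visibly destabilize the consensus matrix between
runs, while k-means++ makes it reproducible at equal cost.

Robustness: for each subtype, the Euclidean distance between its
centroid and the centroid of an equal-sized uniformly random sample of
rows, averaged over permutations (default 1000); a subtype is robust
when this exceeds 1 on unit-scaled input. The equal-sized-random-subset
null is one reading of an underspecified procedure and is flagged as
such here: a homogeneous cloud scores near 0, a cluster displaced by 5
unit-scaled units scores well above 1.

Drug response grouping: per drug separately, the unit-scaled -log10
GI50 values (larger = more sensitive) are split into three groups by
exact 1-D 3-means — optimal 1-D k-means clusters are contiguous in
sorted order, so an exhaustive two-breakpoint search over the sorted
values is exact — labeled H/M/L by decreasing group mean.

## Centroid classifiers

Per-gene center/scale are fitted on the training cohort and stored.
Nearest-shrunken-centroid training is cross-validated (stratified,
default 5 folds, reduced with a warning if a class is smaller) over a
shrinkage grid; among shrinkage values that retain every signature gene,
the one with least CV misclassification wins (ties toward less
shrinkage — in practice 0, since the signature is taken as given).
Centroids are the standardized per-gene class means. New samples are
standardized with the stored training parameters (raw correlation
available by flag), correlated with each centroid over the shared
signature genes (missing genes dropped pairwise; below 50% overlap is an
error), and assigned to the argmax; Pearson correlation makes the
assignment invariant to per-sample affine transforms of expression.

## Synthetic data

`simulate_dataset` draws exactly from the generative model: standard
normal covariates; active covariates get coefficient `effect_size` on
every CMV, inactive exactly 0; each loading column has
`ceil((1 - sparsity) * p)` nonzero entries with magnitudes
N(effect_size, 0.1^2) and random signs; per-gene noise variances
`noise_scale^2 * Uniform(0.5, 1.5)`; optional planted sample clusters
shift the CMV means by random centers scaled by `cluster_separation`
(default 5, i.e. between/within SD ratio 5). The frozen **standard
design** used throughout validation is p=300, n=80, q=3, c=3, two active
covariates, effect 1.0, sparsity 0.8, noise 1.0 — moderate dimensions
with unit-scale signal against unit-scale noise, chosen so that effects
are detectable but not trivial and a ten-replicate battery runs in
minutes on one CPU.

What the generator does *not* emulate: probe/batch effects, count-based
noise, heavy-tailed or missing expression values, correlated or
categorical covariate structures beyond dummy coding, and outlying
samples. Passing the validation battery therefore certifies the
inference machinery under the model's own assumptions — correctness of
the sampler, calibration of the scores, consistency of the selection
rules — not robustness to real-microarray artifacts.

## Fit and convergence diagnostics

Posterior-predictive fit: for each retained draw a replicate dataset is
simulated from that draw's parameters (same X) and the mean absolute
deviation (MAD) between observed and replicate feature-feature
covariance matrices is computed, both matrices on unit-scaled features
(divided by the observed per-feature SD) so the conventional "below 1,
near 0" reading of the values is scale-meaningful. On the standard
design fitted at the true q the median MAD is ~0.12; fitting at q - 2
gives a strictly larger median in 10/10 replicates, so the statistic
also discriminates underfitting. Above a feature cap (default 500) a
seeded random feature subset is used.

Convergence: windowed means of any per-draw scalar trace (log posterior,
or the elementwise mean of a parameter block) plus a split-half
mean-comparison z with batch-means standard errors; |z| < 3 on a
converged run.

## Problem sizes in the validation suite

The test battery runs reduced-but-honest sizes chosen to keep the whole
suite in a few minutes of one CPU: 4000 sweeps (2000 burn-in) for the
recovery battery, 1500 sweeps for the selection and null batteries, 5000
draws per simulator in the joint-distribution check, 200,000 sweeps for
the quadrature toy, 250 consensus repetitions in the planted-cluster
test (the package default remains 1000). Sign conventions, thresholds
and seeds are fixed in the tests; the acceptance script re-derives its
seeds from a single command-line seed.

## Known limitations

* Single quantitative omics matrix only; no multi-omics, counts, or
  missing expression values.
* No survival modeling: CMVs and subtype labels are exported for
  external survival tools, but censored outcomes cannot be modeled
  jointly with this likelihood.
* Rotation of CMV columns is only softly identified (ARD + diagonal
  Phi); in low-signal regimes, column matching across draws can blur
  summaries even after alignment.
* The regularized-BIC parameter count and the permutation-robustness
  null are package decisions among several defensible readings; both
  alternatives are exposed (`effective=True`, custom `threshold`).
* MCMC runtime grows linearly in p, n and the grid size; the BIC grid
  search refits the model per candidate q, so the spike-and-slab route
  is preferable when p is large.
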
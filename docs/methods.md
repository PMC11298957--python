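# Methods

This note documents the statistical models implemented in `twinpath`, the
numerical choices behind them, what the synthetic-data generators emulate,
and the known limitations.

## The classical twin design

The package operates on region-level phenotypes measured in monozygotic
(MZ) and dizygotic (DZ) twin pairs — in the motivating application,
per-region fMRI activation strengths (t-values), but any paired
quantitative trait works.  Phenotypic variance is decomposed into

- **A** — additive genetic variance (shared 1.0 by MZ, 0.5 by DZ pairs),
- **C** — common (family) environment (shared 1.0 by both),
- **D** — dominance genetic variance (shared 1.0 by MZ, 0.25 by DZ pairs),
- **E** — unique environment plus measurement error (unshared).

C and D are confounded given only MZ/DZ pairs, so the fitted family is
{ACE, ADE, AE, CE, DE, E}.  The model-implied pair covariance is

    Var(y)            = a² + c² + d² + e²
    Cov_MZ(y₁, y₂)    = a² + c² + d²
    Cov_DZ(y₁, y₂)    = ½ a² + c² + ¼ d²

### Likelihood and optimisation

`TwinVarianceModel` maximises the two-group bivariate-normal likelihood of
the raw pair vectors with a single mean shared across twin order and
zygosity groups.  (Whether separate group means or pre-standardised
phenotypes should be used is application-dependent; both can be arranged
by transforming the table upstream, and the shared-mean form is the
default because the generating model here has one population mean.)

Numerical choices:

- Variance components are parameterised as squared free path
  coefficients, so nonnegativity needs no constrained optimiser.
- The likelihood is evaluated from per-group sufficient statistics
  (sums, sums of squares, sums of within-pair products), making each
  evaluation O(1) in the pair count; this is what keeps the permutation
  test affordable.
- Nelder–Mead with a moment-based (Falconer-style) start plus seeded
  random restarts (default 10).  The surface is well-behaved; in
  benchmarking, single-start and ten-start solutions agreed to ~1e-12,
  so permutation refits default to fewer starts.
- e² is floored at 1e-8 times the pooled sample variance to keep the
  likelihood proper.
- The E model is solved in closed form (grand mean, pooled ML variance).
- AIC = −2lnL + 2·(free components + 1 for the mean).  Only AIC
  differences are interpreted, so the mean-counting convention is
  internally consistent.
- Likelihood-ratio p values use the plain χ² reference by default,
  matching common SEM-software behaviour even though variance components
  sit on the boundary under the null; the 50:50 χ²-mixture reference is
  available via `compare_fits(..., boundary="mixture")`.

## Selection logic

For each region the initial model is ADE when the DZ intraclass
correlation is **less than half** the MZ correlation, otherwise ACE.
Correlations are clamped below at zero before the half-rule; negative
ICC estimates carry no heritable signal, and clamping is the unique
simple convention consistent with every row of the bundled reference
table (including rows where both correlations are negative).

The best model is the lowest-AIC member of {initial model, its nested
submodels, E}, ties broken toward fewer parameters.  A genetic winner (a
model freeing A or D) additionally requires rMZ > rDZ; failing that it is
demoted to the best non-genetic candidate rather than excluded, so every
region stays classified.  Categories:

- **genetic** — best model frees A or D, beats E at α = 0.05, rMZ > rDZ;
- **environmental** — best model is CE and beats E at α = 0.05;
- **other** — everything else (including best model E).

ICC is the one-way ANOVA ICC(1,1) by default — the canonical twin-pair
estimator, invariant to within-pair order and able to go negative — with
one-tailed significance from the F test on (n−1, n) df.  Double-entry
Pearson is available as a config option.  Fisher's Z compares MZ and DZ
correlations: z = (atanh r_MZ − atanh r_DZ) / √(1/(n_MZ−3) + 1/(n_DZ−3)).

## Permutation significance

The null is built by pooling all individuals, re-pairing them uniformly
at random, and reassigning MZ/DZ labels preserving group sizes.  This
destroys both within-pair resemblance and zygosity structure — the most
conservative exchangeable null consistent with "permuting the zygosity
labels and shuffling the pairs"; a weaker variant that preserves pairings
and only swaps group labels would leave within-pair resemblance intact.
The statistic is ΔAIC = AIC(E) − AIC(best genetic model), refitted per
draw; p uses the add-one formula (1 + #{null ≥ observed})/(1 + B), which
cannot be zero.  Default B = 10,000; tests and the acceptance script use
a few hundred, which is sufficient for calibration checks at α = 0.05.
Benjamini–Hochberg FDR is applied within each family of tests reported
together.

## Common-pathway model

`CommonPathwayModel` fits the multivariate CP structure: m latent common
factors load on p phenotypes through a loading matrix Λ, each factor's
unit variance is split into its own A/D(/C)/E shares, and each phenotype
keeps specific A/D(/C)/E components.  The implied 2p × 2p twin-pair
covariance has within-twin block ΛΛ' + diag(specific totals) and
cross-twin block Λ diag(r_gf) Λ' + diag(zygosity-weighted specifics),
with r_gf the weighted genetic + shared-environment share of factor f.

Identification choices (the literature admits several conventions):

- factor variances fixed at 1 — loadings carry the scale;
- per-factor shares parameterised as squared paths normalised to sum to
  one (counted as 2 free parameters per factor);
- echelon (lower-triangular) loading pattern for m > 1, removing
  rotational indeterminacy;
- first nonzero loading of each factor made nonnegative.

Because any echelon solution is one rotation of the underlying subspace,
cluster memberships derived from loadings are asserted only against
synthetic ground truth, never against published memberships obtained
under an unknown rotation.

Optimisation is L-BFGS-B from a principal-axis moment start with seeded
restarts, followed by a Nelder–Mead polish (the surface has scale-ridges
from the factor-share redundancy; the polish reliably lands the last few
1e-4 of log-likelihood).  With p = 1, m = 1 the CP family collapses onto
the univariate model and the fits agree to better than 1e-4 in −2lnL.

`select_n_factors` grows m until AIC stops improving (or the nested χ²
fails, config-selectable).  `shared_genetic_factor` fits m = 1 and tests
the factor's genetic shares by a likelihood-ratio test against the same
model with a pure-E factor (df = 2); loading signs are reported so that
oppositely-directed phenotypes are visible.

## Clustering by loadings

Phenotypes are represented by their loading rows and clustered with
k-means (squared Euclidean, 100 seeded restarts per k).  The number of
clusters comes from the gap statistic: B uniform-box reference sets
(default 100) drawn over the data's bounding box, gap(k) = E[log W*_k] −
log W_k, s_k = sd(log W*_k)·√(1+1/B), and the first-SE-max rule (smallest
k with gap(k) ≥ gap(k+1) − s_{k+1}).  Reference sets can be supplied
explicitly, which is how the implementation is cross-checked against an
independent computation in the tests.

## Expression decoding

- **Differential stability**: per gene, the mean pairwise Pearson
  correlation of regional expression between donors; the top 5% (floor of
  0.05·G, e.g. 501 of 10,020) is retained, ties broken by stable gene
  order.
- **Leave-one-region-out decoding**: linear SVM (libsvm, C = 1,
  one-vs-one for multiclass); features are z-scored on the training fold
  only, then the held-out region is predicted.  Train-fold
  standardisation is stated explicitly because results depend on it.
- **Background-resampled binary decoding** balances target regions
  against an equal-sized random draw from a background pool per
  iteration; mean absolute linear weights are accumulated across
  iterations and the top 1% (ceiling) of genes reported.  Multiclass
  weight extraction is deliberately unsupported — marker genes for
  multiple clusters come from the t-test route instead.
- **Permutation chance**: labels permuted uniformly; chance is the null
  mean and p the add-one tail probability.  With unbalanced classes the
  chance level is an empirical quantity, not 1/k.
- **Cluster-specific genes**: two-sample pooled-variance t tests of one
  cluster against the rest, thresholds t > 3.7 and p < 0.001 (Welch
  variant config-exposed).

## Synthetic data

Generators draw twin pairs directly from the model-implied normal
distributions (univariate and CP structures).  Dominance is induced at
the pair level through the covariance structure rather than through an
explicit allelic model; the analysis only ever consumes second moments,
so the two are equivalent here.  Default group sizes are 113 MZ / 58 DZ
pairs, a realistic twin-fMRI sample; recovery and calibration suites use
larger or smaller n as stated per test.

The expression generator partitions its informative genes into disjoint
per-cluster signature blocks, each elevated by the effect size; this
guarantees that every cluster pair differs by the full shift on the
union of their blocks, i.e. the between-cluster contrast equals the
nominal effect size.  Donor replicates share a configurable fraction of
their noise variance, so uninformative genes have inter-donor
correlation ≈ that fraction and informative genes more — enough to
exercise the stability filter.

What the generators do **not** emulate: spatial autocorrelation between
neighbouring regions, non-Gaussian tails of activation measures,
donor-specific normalisation artefacts, and any voxel-level structure.
Passing tests therefore demonstrate correctness of the estimators and
decision logic under the assumed model, not robustness to those
real-data features.

## Problem sizes used in the checks

Recovery checks use 5,000+5,000 pairs (univariate, ±0.05 tolerance) and
1,500+1,500 pairs (two-factor CP, ±0.1 on loadings).  Permutation
calibration uses 200 replicates of 60+40 pairs at 200 draws each.
Decoding checks use 4 clusters × 5 regions × 150 genes with a 4-SD
effect and 500 permutations.  These sizes give Monte-Carlo error
comfortably below the stated tolerances while keeping the default test
run quick.

## Known limitations

- No covariates inside the likelihood (residualise phenotypes upstream);
  no sex-limitation or bivariate Cholesky models.
- The CP optimiser is generic; very large p (≫ 10 phenotypes) would
  want analytic gradients.
- Boundary-of-parameter-space inference is approximated by the plain χ²
  (or 50:50 mixture) reference, not a full simulation-based null — the
  permutation module exists precisely to avoid relying on it.
- The ICC estimator and tail convention of any given published table may
  differ; both are config-exposed rather than assumed.
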
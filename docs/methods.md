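# Methods

## Model and estimation

The core model is a multi-kernel (kernel-averaging) RKHS regression

    y_i = mu + sum_k g_k,i + eps_i,
    g_k ~ N(0, K_k sigma2_k),   eps_i ~ N(0, sigma2_e / w_i),

where each `K_k` is one of six genomic kernels and `w_i` is an optional
per-record reliability.  Fitting one additive relationship kernel recovers
GBLUP; fitting `G`, `D` and `G#D` jointly partitions marked genetic variance
into additive, dominance and additive-by-dominance parts.  With variances
fixed at ratio `lambda = sigma2_e / sigma2_g`, the posterior mean of `g`
coincides with the kernel ridge solution `K (K + lambda I)^{-1} y`, which
the test suite uses as a closed-form oracle for the sampler.

### Gibbs sampler

Each kernel is eigendecomposed once, `K_k = U_k L_k U_k'`, dropping
eigenvalues below `1e-8 x` the largest; the genetic effect is parameterized
as `g_k = B_k delta_k` with `B_k = U_k L_k^{1/2}` and
`delta_k ~ N(0, I sigma2_k)`.  Because `B_k'B_k = L_k` is diagonal, the
blocked full conditional of `delta_k` is Gaussian with diagonal covariance,
so one sweep costs two matrix-vector products per kernel and the sampler
remains well-defined for singular kernels (e.g. `G#D`, which is nearly an
identity matrix on weakly related individuals).  Variance full conditionals
are scaled inverse chi-squared; the intercept has a flat prior.

Reliability weights are handled exactly by the transform
`S = diag(sqrt(w))`: the chain runs on `S y` with kernels `S K S`
(homoskedastic residuals), and genetic values are back-transformed.  With
all weights equal to one this is bitwise identical to the unweighted
sampler.

Masked responses (individuals to predict) are imputed from their full
conditional `N(mu + g_i, sigma2_e / w_i)` each sweep (data augmentation).
The marginal posterior of all parameters is exactly the observed-data
posterior, so masked rows contribute nothing to the likelihood while their
genetic values are sampled jointly with the training rows; prediction is
the posterior-mean genetic value of the masked rows.

### Priors and tunables

* `PriorSpec.df = 5`, `scale_multiplier = 0.5`: every variance (per kernel
  and residual) has a scaled inverse chi-squared prior with scale
  `0.5 x Var(observed y)`.  An absolute `scale` override exists for pure
  prior draws (no observed data), where `Var(y)` is undefined.
* `ChainConfig`: reference chain 50,000 / 20,000 / thin 10 (3,000 retained
  draws); the cross-validation default is a desk-scale 6,000 / 1,000 /
  thin 5 chain, which changes CV correlations by less than Monte-Carlo
  noise (checked in the suite).
* Variance ratios (`V_k/V_P`, `V_k/V_K`, `H2`) are computed per retained
  draw and then summarized (mean of ratios, not ratio of means), matching
  the convention of reporting posterior densities of ratios; kernel-relative
  weights sum to one in every draw by construction.

A known consequence of this prior at desk scale: with the same scale on
every component, weakly identified variances (notably `sigma2_GD`, whose
kernel is almost an identity matrix and therefore confounded with residual
noise) are pulled toward the prior mean, inflating `H2`.  The recovery
checks quantify this: at n = 1,000 with truth
(V_G, V_D, V_GD, V_E) = (0.1, 0.1, 0.3, 0.5), five-seed average posterior
means land within 0.15 of truth for all seven reported ratios, with `H2`
carrying the largest bias (about +0.14).

## Kernels

* `G` — VanRaden method 1: dosages column-centered by `2p`, cross-product
  over `sum 2pq`.  Observed post-QC allele frequencies are used.
* `D` — heterozygosity-indicator parameterization: indicator centered by
  its HWE expectation `2pq`, normalized by `sum 2pq(1 - 2pq)`.
* Gaussian kernels are built on the raw codings (0/1/2 and +-0.5) without
  per-marker standardization; the bandwidth absorbs scale, and calibration
  makes the choice immaterial.
* Bandwidth calibration bisects on `log theta` (the mean off-diagonal is
  continuous and strictly decreasing in `theta`), bracket
  `[1e-12, 1e3] / mean squared distance`, default tolerance 0.001, at most
  200 iterations, fully deterministic.  For two individuals at squared
  distance `d` the solution is the closed form `-ln(target)/d`.
* The epistatic Gaussian kernel pairs bandwidths within similarity class:
  `GK_AD_local = GK_A_local # GK_D_local` and likewise for global.  Crossing
  local with global bandwidths is equally defensible a priori; matching
  classes keeps each product kernel interpretable as one similarity scale.
* Every constructed kernel must satisfy `min eigenvalue >= -1e-8 x
  trace/n`; Hadamard products are PSD by the Schur product theorem.

## Genotype handling

Dosage matrices (0/1/2, missing as NA/-9/blank) are read from PLINK
"raw"-style additive exports or a plain delimited matrix.  QC removes
markers with minor allele frequency strictly below the threshold (default
0.05; markers exactly at the threshold are kept) and monomorphic markers.
Nothing is ever dropped for missingness: every missing dosage is imputed as
the sum of two Bernoulli draws at the marker's observed allele frequency
(Binomial(2, p)), locus by locus.  Adjacent-marker LD is summarized as the
squared Pearson correlation of dosages for each adjacent pair, skipping
pairs that involve a monomorphic marker.

## Synthetic studies

The generator provides ground truth for every estimation and prediction
check.  What it emulates, and what it does not:

* **Genotypes.** LE mode draws each marker independently,
  `Binomial(2, p_j)` with `p_j ~ Uniform(0.2, 0.5)` (mean MAF 0.35).  LD
  mode runs a first-order latent-uniform copying chain per haplotype:
  the latent uniform is copied from the previous locus with probability
  `ld_copy_prob`, else redrawn, which preserves marginal frequencies
  exactly and yields tunable adjacent r^2 (`ld_copy_prob = 0` reduces
  exactly to LE; a calibration helper finds the copy probability for a
  target r^2 such as 0.18).
* **Relatedness.** Real dairy populations contain large sib groups, and it
  is pair-level relatedness variance — not short-range LD — that makes the
  off-diagonals of `G` and `D` converge as the marker panel grows: with
  unrelated individuals both matrices are sums of iid locus-block
  contributions, so their off-diagonal correlation is invariant to marker
  count (empirically flat from p = 150 to p = 10,000 for any copy
  probability).  `family_size > 1` therefore groups individuals into
  full-sib families (four chain-generated parental haplotypes per family,
  recombinant gametes at `recomb_rate` per marker interval).  The
  marker-count experiment uses families of four in its LD arm and
  reproduces the expected trend (off-diagonal correlation rising from
  ~0.4 at p = 500 to ~0.9 at p = 10,000 at n = 1,000), while its LE arm
  stays flat.  The default for all other analyses is `family_size = 1`.
* **Traits.** `kernel_space` mode draws each genetic component directly
  from its kernel distribution (`g_A ~ N(0, G V_G)` etc.), making the
  fitted model exactly true — the canonical recovery fixture.
  `effect_space` mode draws per-marker additive and dominance effects and
  pairwise A-by-D interaction effects at 500 sampled locus pairs, then
  rescales each component to its target variance; it provides
  model-misspecified traits (the fitted kernels are then only
  approximations of the true architecture).  The liability adds
  parity/herd/year/season factor effects and Gaussian noise; the binary
  record thresholds the liability at its empirical quantile so realized
  incidence matches the target exactly in-sample.
* **Responses.** PCP are OLS residuals of the binary record on the
  dummy-coded fixed-effect design (aliased columns dropped with a
  warning).  EBV are emulated as `r g + eps` with
  `Var(eps) = r(1-r) Var(g)`, so `cor(ebv, g)^2 = r` in expectation and
  `Var(ebv) = r Var(g)` (shrinkage); reliabilities are drawn uniformly on
  a configurable interval (default 0.2-0.5, matching the low reliabilities
  typical of health-trait EBV).
* **Not emulated:** pedigree-BLUP EBV production over a multi-generation
  pedigree, genotyping-chip error models, multi-trait architectures, and
  selection.  Passing tests demonstrate correctness of the estimation
  machinery under the simulated architectures, not that real health-trait
  data carry any particular variance composition.

## Cross-validation

Folds are near-equal random partitions (sizes differ by at most one), a
fresh permutation per repeat, deterministic given the seed.  Kernels are
built once on all individuals and only test-fold phenotypes are masked —
an intentional, documented information-sharing choice matching the n x n
kernel construction of the analysis design.  Correlation is computed per
fold and averaged; pooled per-repeat correlations are also reported.  Folds
with undefined correlation (constant predictions or responses) are recorded
as missing with a warning and excluded from means.  Reliability weights are
applied inside CV training fits whenever the response is EBV-type.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to keep the full suite in a
few minutes while leaving each conclusion statistically meaningful:
bandwidth calibration at n = 500, p = 2,000; oracle equivalence at n = 300
with 2,000 retained draws; variance-ratio recovery at n = 1,000, p = 500
over five seeds with 6,000-iteration chains; the marker-count experiment at
n = 1,000 up to p = 10,000 over five seeds; the CV null at n = 505.  The
reference 50,000-iteration chain settings remain the package defaults for
real analyses.

## Known limitations

* Variance partitions inherit the non-orthogonality of `G`, `D` and `G#D`
  under LD and relatedness; components should be read as approximate
  contributions, and `sigma2_GD` in particular is only weakly separable
  from residual variance when `G#D` is near-identity.
* The Gibbs sampler logs no convergence gate; chain settings are the
  user's responsibility (the defaults are conservative).
* The EBV emulation treats reliability as exact and noise as Gaussian and
  independent across animals; real EBV errors are correlated through the
  pedigree.
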
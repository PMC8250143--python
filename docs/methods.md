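# Methods

## Model

`gsblup` fits Gaussian linear mixed models in which every random effect
carries a user-supplied covariance among its levels:

    y = Xβ + Σⱼ Zⱼuⱼ + e,    uⱼ ~ N(0, σⱼ² Kⱼ),    e ~ N(0, σₑ² I)

`y` is an n-vector of phenotypes, `X` the fixed-effect design (intercept,
environments, numeric covariates), `Zⱼ` a 0/1 incidence matrix connecting
records to the rⱼ levels of grouping factor j (many-to-one, so replicated
records are supported), and `Kⱼ` a known symmetric positive-semidefinite
relationship matrix: a pedigree-derived numerator relationship matrix **A**,
a marker genomic relationship matrix **G** = WW′/p, a Gaussian or exponential
kernel on marker distances, a Kronecker product K₁⊗K₂ for hybrid
(specific-combining-ability) effects, or any matrix the caller provides.

### The covariance transformation

Each correlated effect is absorbed into the design: with Lⱼ such that
LⱼLⱼ′ = Kⱼ (Cholesky factor, or ΓΛ^½ from the eigendecomposition when Kⱼ is
singular), Zⱼ* = ZⱼLⱼ and uⱼ* ~ N(0, σⱼ² I) give Zⱼ*uⱼ* the same
distribution as Zⱼuⱼ.  The model becomes an ordinary independent-effects
mixed model, fitted by REML.  BLUPs on the transformed scale,
ûⱼ* = σ̂ⱼ² Zⱼ*′ V̂*⁻¹ (y − Xβ̂) with V̂* = Σⱼ σ̂ⱼ² Zⱼ*Zⱼ*′ + σ̂ₑ² I, map back
through ûⱼ = Lⱼûⱼ*.

### REML criterion and optimizer

The restricted likelihood is profiled over β and σₑ².  Writing
λⱼ = σⱼ²/σₑ² and H = I + Σⱼ λⱼ Zⱼ*Zⱼ*′:

    β̂   = (X′H⁻¹X)⁻¹ X′H⁻¹y
    σ̂ₑ² = r′H⁻¹r / (n − p),   r = y − Xβ̂
    ℓ_R  = −½ [ (n−p)(1 + log 2πσ̂ₑ²) + log|H| + log|X′H⁻¹X| ]

ℓ_R is maximized over the log-ratios log λⱼ by Nelder–Mead (start at
log λⱼ = 0; restarts from ±2 on non-convergence; λⱼ confined to
[10⁻¹⁰, 10¹⁰] by clipping, so variance estimates at the bound are boundary
fits and flagged in the trace).  All algebra is dense: H is n×n and each
criterion evaluation costs one Cholesky of H, with Zⱼ*Zⱼ*′ precomputed per
design.  This is exact and fast for the intended regime (n up to a few
thousand); it does not pursue sparse-matrix performance for n ≫ 10⁴.

This convention matches the REML log-likelihood that lme4 reports, so fitted
log-likelihoods are directly comparable to values from lme4-based genetics
packages (the test suite includes an lme4 cross-check that agrees to ~7
significant digits).  Note the criterion contains no |X′X| normalization:
reparameterizing X by an invertible column transform A shifts ℓ_R by the
constant −log|det A| while leaving the profile shape, the argmax, and every
estimate unchanged.

### Prediction of unphenotyped genotypes

For each term, the full covariance over fitted (1) and new (2) levels is
partitioned and the new effects predicted by the conditional mean

    û₂ = K₂₁ K₁₁⁻¹ û₁,

applied per term (no cross-term covariance).  Fitted levels pass through
with their fitted BLUPs, so mixed requests (as in cross-validation) work
directly.  The supplied K₁₁ block must match the covariance used at fit
time within 1e-8 relative; K₁₁ systems are solved by Cholesky with the PSD
clipping policy below, never an explicit inverse.  Predicted phenotypes add
the fixed part: ŷ₂ = x₂′β̂ + Σⱼ û₂ⱼ.  The predictor conditions on û₁
operationally (plug-in); no joint-V alternative or prediction variances are
offered.

## Relationship matrices

- **A** (pedigree): Henderson's tabular recursion in topological order,
  A_ii = 1 + 0.5·A_sd, A_ij = 0.5(A_js + A_jd); unknown parents are
  unrelated non-inbred founders.  Validated against Monte-Carlo allele
  dropping (10⁶ replicates, agreement within 0.01).
- **G** (markers): G = WW′/p with W column-centered and scaled by the sample
  (n−1) standard deviation; zero-variance columns are dropped with a warning
  and p reduced; missing cells are imputed by the column mean before
  centering.
- **Kernels**: distances are computed on raw genotype codes and scaled as
  s_ij = d_ij/√m, so s² = d²/m is the Gaussian argument
  K = exp(−θ·s²) and the exponential kernel uses K = exp(−θ·s).  The
  flattened "d/m" notation seen in some sources is ambiguous between d/m and
  d/√m; this package adopts the √m scaling so that the Gaussian argument is
  exactly the mean squared per-marker difference.
- **Kronecker**: K₁⊗K₂ with K₁-major label order and "parent1:parent2"
  labels, aligning with hybrid identifiers.

### Numerical policy for PSD matrices

Eigenvalues in [−1e-8·λ_max, 0) are clipped to zero (eigen route) or handled
by a 1e-8·λ_max jitter (explicit Cholesky requests); anything more negative
is a hard error naming the offending eigenvalue.  `factorize(method="auto")`
uses a plain Cholesky when K is numerically positive definite and otherwise
falls back to the eigen route, so rank-deficient kernels (routine for
Kronecker and Gaussian kernels) are handled without user intervention.
Cholesky and eigen routes agree in the criterion and all BLUPs to 1e-6.

## Bandwidth selection

θ > 0 maps to ρ = exp(−θ) ∈ (0,1); the automatic grid takes 25 equally
spaced ρ in [0.02, 0.98] (endpoints avoid the all-ones and near-diagonal
degenerate kernels) and transforms back.  The full model (kernel term plus
any other random terms) is refitted at each θ and the restricted
log-likelihood profiled; the smallest θ among ties wins; each fit warm-starts
from the previous optimum's λ.  An optional refinement pass inserts 10
points between the grid neighbours of the first-pass argmax.  The profile is
often shallow: when pairwise marker distances concentrate (many independent
markers), θ trades off against the kernel variance and is weakly identified
on a single draw — the selection is consistent on average, which is how the
recovery checks are phrased.

## Cross-validation

Splitting is by genotype id, not record: `kfold` partitions the distinct ids
into k folds differing by at most one in size, deterministically from an
explicit integer seed.  Per fold, the model is refitted on the complement,
held-out genotypes are predicted through the conditional-mean machinery, and
Pearson r and MSE (divisor n) are reported for training (in-sample fitted
values Xβ̂ + ΣZⱼûⱼ) and testing sets, with avg/sd summary rows.

## Heritability helper

`heritability(model, terms)` computes h² = Σσ̂ⱼ²(terms) / (Σσ̂ⱼ²(terms) + σ̂ₑ²)
verbatim for the caller-selected terms.  Published combining-ability
analyses sometimes report an h² from this formula that is not reproducible
from their own printed variance components; the helper makes no attempt to
reconcile such inconsistencies — it evaluates the formula as printed.

## Synthetic data

The generators mirror the generative model exactly: uⱼ = σⱼLⱼzⱼ with
standard-normal zⱼ, plus iid residual.  Marker panels are independent
Bernoulli (0/1, DArT-like) or Binomial(2, q) dosage columns with allele
frequencies uniform in the MAF range — no linkage disequilibrium, no
selection, no marker–pedigree coupling by default, so tests that pass on
these fixtures demonstrate correctness of the estimation machinery, not
robustness to LD or population structure.  Pedigrees are random-mating with
parents drawn from the previous generation (cycle-free by construction).
The hybrid fixture enumerates an n₁×n₂ factorial, phenotypes a random
subset of crosses in several locations, and draws GCA/SCA effects from
(K₁, K₂, K₁⊗K₂).  Default variance components (0.22, 0.21 genetic vs 0.035
residual) reflect a standardized yield trait in a wheat-scale panel of a few
hundred lines; the hybrid defaults reflect a maize combining-ability study
where GCA of the first group dominates.

## Problem sizes used in checks

The heavy checks run at n = 1000 (variance recovery, 20 replicates),
n = 300 (cross-validation, bandwidth, new-genotype prediction, averaged over
10 draws where a single draw is noisy), and 10⁶ replicates for the
gene-dropping validation of A — sizes chosen so each check is statistically
informative at its stated tolerance while the whole suite stays fast on one
CPU.

## Known limitations

- Dense algebra only; memory and time scale as O(n²)–O(n³).
- Gaussian responses only; no generalized mixed models.
- No standard errors for BLUPs or fixed effects; no prediction intervals.
- One kernel term at a time in bandwidth selection; θ is not optimized
  jointly with the variance components (grid profile only).
- MSE uses divisor n; training metrics are in-sample (no leave-one-out
  shortcut).
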
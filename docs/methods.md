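# Methods

## Model and estimator

For `q` centered traits with unit variance and `p` SNPs, the package works
under the multivariate linear mixed model `y = Xβ + ε` on standardized
genotypes, with per-SNP random effects `β_j = (β_j1, …, β_jq) ~ N(0, Σ_bj)`
and independent residuals `Var(ε) = I_n ⊗ Σ_s`,
`Σ_s = diag(σ²_ε1, …, σ²_εq)`. Residual covariances between traits are fixed
at 0, which is what summary statistics from non-overlapping GWAS samples can
identify. With heritabilities `h²_gk = Σ_j (Σ_bj)_kk` the residual variances
are `σ²_εk = 1 − h²_gk`; only ratios matter, so equal total variance across
traits is the real assumption.

Individual-level data enter only through sufficient statistics: SNP–trait
correlations `r_k` (from public summary statistics) and the LD matrix `R`
(from a reference panel of `n_r` subjects, block-wise). Because `r` and `R`
come from different samples, the LD matrix is regularized to
`R_s = (1−s)R + sI`, `s ∈ (0,1]` (default 0.5), making the quadratic form
strictly convex; equivalently the solver uses `X̃ = √((1−s)/n_r) X_r`. The
penalized objective adds the Gaussian prior and a weighted L1 term,

```
f(β) = −2 Σ_j β_j'Σ_s⁻¹ diag(n) r_j
     + Σ_j Σ_l β_j' diag(n) (X̃_j'X̃_l + s·1[j=l]) Σ_s⁻¹ β_l
     + Σ_j β_j'Σ_bj⁻¹β_j + 2λ‖Wβ‖₁ ,
```

an elastic-net problem whose quadratic part couples SNPs through LD (within
trait) and traits through `Σ_bj⁻¹` (within SNP). `n` is the per-trait GWAS
sample-size vector.

### Coordinate descent

The exact coordinate minimizer for `β_jk` is soft-thresholding:

```
β_jk ← S(A_jk, λ w_jk) / D_jk,
D_jk = n_k (X̃_j'X̃_j + s) σ_εk⁻² + (Σ_bj⁻¹)_kk,
A_jk = −c Σ_{h≠k} (Σ_bj⁻¹)_kh β_jh + n_k σ_εk⁻² r_jk
       − n_k σ_εk⁻² Σ_{l≠j} X̃_j'X̃_l β_lk .
```

The cross-trait factor `c` is 1: that is the gradient of the prior term
`β_j'Σ_bj⁻¹β_j`, and only `c = 1` makes the sweep a descent method for the
stated objective (verified against an independent convex minimizer in the
tests). A published variant of the update uses `c = 1/2`, which corresponds
to halving the off-diagonal prior terms; it is available behind
`cross_term_factor=0.5` and is checked against its own (modified) objective.

Implementation choices:

* **SNP-major sweeps** — all traits within a SNP before the next SNP, so the
  cross-trait term always sees fresh within-SNP coefficients.
* **Residual caches** — `X̃'X̃ β` is maintained per block with rank-one
  column updates rather than recomputed; the fitted solutions are verified
  to be exact coordinate fixed points against a dense recomputation.
* **Active-set cycling** — after one full sweep per λ the solver iterates
  over SNPs with nonzero coefficients, then re-verifies with a full sweep
  before declaring convergence. Same fixed point, large speedup.
* **Warm starts** along the descending λ path; `β = 0` at the first λ.
* **Convergence** — maximum absolute coefficient change < 1e-4
  (standardized-genotype scale), at most 100 sweeps per λ; both
  configurable; non-convergence is flagged in the result, not fatal.
* **Infinite penalty weights** (adaptive LASSO with a zero source estimate)
  are implemented as skips, pinning the coefficient at exactly 0.
* The inner sweep is compiled with numba; everything else is numpy.

A KKT certificate (`kkt_check`) reports stationarity violations on the
coefficient scale (residual divided by the curvature `D_jk`), so the test
tolerance 1e-6 is meaningful independently of `n`.

Adaptive weights are `w_jk = |β̂_jk|^(−γ)`, with the source either the GWAS
effect estimates (tunable γ) or the coefficients of a previous
constant-weight fit (γ = 1).

## Genetic covariance models

**Constant model.** Every SNP contributes `Σ_b/p`, e.g. totals
`[[0.47, 0.27], [0.27, 0.45]]` for the two psychiatric-trait-like reference
scenarios. Inputs are validated for positive semi-definiteness.

**Annotation model.** Cross-trait stratified LD-score regression on products
of Z scores:
`E[Z_j1 Z_j2] = √(n1 n2) Σ_C ℓ(j,C) θ_C (+ √(n1 n2) b12)`, with LD scores
`ℓ(j,C) = Σ_l a_lC R²_jl` computed block-wise from the same panel used
downstream. The sample-overlap intercept `b12` is fitted only on request
(default 0). Heritability effects use the companion single-trait form
`E[Z²_jk] = 1 + n_k Σ_C ℓ(j,C) τ_kC`. The regression is unweighted least
squares by default (weights can be supplied); standard errors by block
jackknife are out of scope (point estimates only). Per-SNP predictions
`h²_k(j) = Σ_C a_jC τ_kC`, `ρ_g(j) = Σ_C a_jC θ_C` may be negative, so they
are repaired before use:

1. negative heritabilities floored at 0 (and the SNP's covariance forced to
   0 when either trait's heritability is 0);
2. covariances beyond the PSD bound replaced by
   `max(0, √(h²_1(j) h²_2(j)) − 0.001)` in magnitude — the predicted sign is
   kept under the default `signed` policy, with a literal non-negative
   variant available (`sign_policy="nonnegative"`);
3. per-trait sums rescaled to the target heritabilities, the covariance by
   the geometric mean `√(c₁c₂)` of the two factors, which preserves per-SNP
   genetic correlations of unrepaired SNPs and PSD.

For inversion, matrices whose smallest eigenvalue falls below a floor get
`1e-3·h²_gk/p` added to the diagonal; SNPs with zero contribution for both
traits therefore receive a heavy ridge penalty instead of an undefined one.

## Tuning without individual-level validation data

Full-sample correlations are split into *pseudo* training and validation
statistics. With `nB = round(0.1 · mean_k n_k)` and `nA_k = n_k − nB`:

```
rA_k = r_k + √(nB / (nA_k n_k)) · s(r_k) · X_r'g / √n_r ,   g ~ N(0, I_{n_r})
rB_k = (n_k r_k − nA_k rA_k) / nB ,
```

where `s(r_k)` is the empirical standard deviation of `r_k` (the
trait-variance correction that avoids assuming Var(y)=1 in the sampling
covariance of `r`). This scaling is the unique one under which the
perturbation covariance is `(nB/(nA_k n_k)) s²(r_k) R`, i.e. `rA` and `rB`
have the sampling variances of correlation estimates from `nA_k` and `nB`
subjects; it is verified by a 1,000-replicate Monte-Carlo covariance test.
The recombination identity `nA_k rA_k + nB rB_k = n_k r_k` holds exactly.
The Gaussian draw `g` is shared across traits by default so the cross-trait
structure of the noise matches the shared reference LD (an independent-`g`
option exists).

The λ (and covariance-model) selection maximizes

```
f(λ) = β_λ'r_B / √(β_λ'X₀'X₀ β_λ / n₀)
```

stacked over traits, a monotone surrogate of the PRS–trait correlation in a
validation sample; per-trait diagnostics are emitted so the stacking choice
is auditable. All-zero solutions are excluded via a −∞ sentinel; ties break
toward the largest λ (sparsest model). The λ grid is log-spaced from
`λ_max = max_jk |n_k σ_εk⁻² r_jk| / w_jk` (20 points by default) and is
extended downward until at least 5% of SNPs have nonzero coefficients for
every trait (warning if unreachable). A single λ is shared across traits;
per-trait selection exists as an extension flag. After selection,
coefficients are re-estimated on the full-sample statistics at the selected
λ. Pseudovalidation via shrunken correlations is deliberately not provided.

## Simulation framework

Two dichotomous traits with architecture modeled on schizophrenia/bipolar
disorder. Scenario axes (reference / alternative): heritabilities
(0.47, 0.45) / (0.10, 0.09); polygenicity (0.49, 0.47) with P(causal for
both) = 0.35 / (0.12, 0.10) with 0.08 (single-trait probabilities by
subtraction); genetic correlation 0.59 / 0.44 in the four-matrix mode;
sample-overlap noise correlation 0 / 0.16 / 0.32; prevalences 1% and 2%.

* **Causal mixture** — i.i.d. multinomial over {both, trait 1 only, trait 2
  only, neither}; in annotation mode, SNPs with non-positive predicted
  heritability for a trait are demoted to non-causal for it.
* **Effects** — Gaussian given status. In the four-matrix mode the per-SNP
  variance is constant within status class, `v_k = h²_gk / m_k` with `m_k`
  the *realized* number of causal SNPs (this removes one source of
  Monte-Carlo error relative to scaling in expectation), and the dual-causal
  covariance is `c = r_g √(h²_g1 h²_g2) / m_both` (PSD-feasible for all the
  scenario settings; clamped with a warning otherwise). In annotation mode
  the per-SNP matrices are `[[α₁h²_1(j), αρ(j)], [αρ(j), α₂h²_2(j)]]` with
  `α_k` scaling realized causal contributions to the target heritabilities
  and `α = √(α₁α₂)`.
* **Summary statistics** — per LD block, `r_lk ~ N(R_l β_lk, R_l/n_k)`,
  sampled via eigendecomposition with negative eigenvalues floored at 0
  (decompositions cached per block). Sample overlap induces
  `Cov[r_l1, r_l2] = ρ_o R_l / √(n₁n₂)`; the symmetric `√(n₁n₂)` denominator
  is the deliberate reading of the overlap covariance for unequal sample
  sizes.
* **Cohorts** — liability `L_ik = G_ik + E_ik` with `G = Xβ` on standardized
  genotypes (or i.i.d. standard-normal genotype stand-ins for very large
  cohorts), `Var(E_k) = 1 − h²_gk`, affection above the upper-`K_k` normal
  quantile of the theoretical unit-variance liability (empirical
  standardization optional). Evaluation: Pearson correlation with the true
  predictor and Mann–Whitney AUC.
* **Genotypes** — block-wise latent Gaussian copula: AR(1) latent process
  (coefficient `ld_decay`, default 0.9) thresholded by Hardy–Weinberg
  probabilities at MAFs uniform on [0.05, 0.5]. A `SyntheticPopulation`
  fixes MAFs and block layout so reference, validation, and test panels
  describe the same population.

What the generator does **not** emulate: realistic long-range LD and
MAF–LD coupling, allele-frequency spectra with rare variants, cross-block
LD, population stratification, imputation error, and annotation structure of
real genomes. Passing tests therefore demonstrate correctness of the
estimator and calibration of the generator under these idealized conditions,
not performance on real cohorts.

## Problem sizes and numerical choices

The validation suite runs at desk scale by design: solver oracles on p ≤ 10
instances; decoupling/KKT on 600-SNP fixtures; the end-to-end comparison of
the multivariate fit against its decoupled counterpart on 20,000 SNPs,
5,000 training-equivalent subjects, and 2,000-subject test cohorts over 10
replicates; calibration targets on cohorts up to 200,000 subjects with
effects materialized only for causal SNPs. Key tolerances: coordinate
convergence 1e-4 (1e-9 to 1e-12 where certificates are asserted), KKT 1e-6
on the coefficient scale, block LD symmetrization at machine precision,
PSD checks at −1e-10. Degenerate inputs: monomorphic SNPs are rejected at
panel construction; SNPs outside all block intervals go to the nearest
interval (strict mode errors); duplicated SNP ids keep the first occurrence
with a warning; zero-variance PRSs evaluate to NaN with a warning rather
than raising.

## Known limitations

* Residual (environmental) correlation between traits is fixed at 0.
* The annotation repair margin (0.001) is on the scale of *total* per-SNP
  contributions; with millions of SNPs it zeroes most repaired covariances,
  which matches its published use but is blunt at small p.
* No block-jackknife standard errors for the LD-score regressions.
* An extra multiplier on the prior term (decoupling prior strength from the
  L1 penalty) is not implemented.
* The X chromosome, meta-analysis, genomic control, and INFO filtering are
  out of scope.
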
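# mtlassosum

Sparse **multi-trait polygenic risk scores (PRSs) from GWAS summary
statistics**, for genetically correlated traits such as schizophrenia and
bipolar disorder.

Polygenic risk scores built from one trait's GWAS leave predictive signal on
the table when the trait shares genetic architecture with others.
`mtlassosum` implements a penalized multivariate regression on summary
statistics — *Multivariate Lassosum* — that estimates SNP coefficients for
`q` correlated traits jointly, selecting SNPs with a LASSO (or adaptive
LASSO) penalty while coupling the traits through per-SNP genetic covariance
matrices. It is aimed at statistical geneticists who have per-trait summary
statistics (effect sizes/SEs, p values, or Z scores), an LD reference panel
in PLINK format, and no individual-level validation data.

## Model

Traits follow the multivariate mixed model `y = X β + ε` on standardized
genotypes `x_ij = (w_ij − 2p_j)/√(2p_j(1−p_j))`, with per-SNP random effects
`β_j ~ N(0, Σ_bj)` and diagonal residual covariance
`Σ_s = diag(1 − h²_g1, …, 1 − h²_gq)`. Writing `r_k` for the SNP–trait
correlations recovered from trait `k`'s summary statistics and `R` for the
block-wise LD matrix of a reference panel (regularized to
`R_s = (1−s)R + sI`), the coefficients minimize

```
f(β) = −2 Σ_j β_j' Σ_s⁻¹ diag(n) r_j
       + Σ_j Σ_l β_j' diag(n) (X̃_j'X̃_l + s·1[j=l]) Σ_s⁻¹ β_l
       + Σ_j β_j' Σ_bj⁻¹ β_j  +  2λ ‖Wβ‖₁ ,        X̃ = √((1−s)/n_r) X_r
```

by cyclic coordinate descent with exact soft-threshold updates, warm-started
along a descending λ path. The per-SNP matrices `Σ_bj` are either constant
(`Σ_b/p`) or predicted from genomic annotations via cross-trait stratified
LD-score regression, `E[Z_j1 Z_j2] = √(n1 n2) Σ_C ℓ(j,C) θ_C`, with
positive-semidefiniteness repair and rescaling to target heritabilities.
λ is tuned without individual-level data by splitting the full-sample
statistics into *pseudo* training/validation parts and maximizing
`f(λ) = β_λ'r_B / √(β_λ'X₀'X₀β_λ / n₀)`.

A full simulation framework (block-correlated genotypes, causal mixtures,
region-wise summary-statistic sampling with optional GWAS sample overlap,
liability-threshold case/control cohorts) generates the study conditions the
method is validated under.

## Worked example

```python
import numpy as np
import mtlassosum as mt
from mtlassosum.ldref import partition_blocks

# one synthetic population; reference panel and test cohort sampled from it
pop = mt.SyntheticPopulation(p_snps=2000, block_size=200, seed=7)
rng = np.random.default_rng(7)
ref_panel = pop.sample_panel(800, rng)
blocks = partition_blocks(ref_panel, intervals=pop.block_intervals(), s=0.5)
test_panel = pop.sample_panel(1500, rng)

# two correlated traits with the reference architecture (h2 = 0.47/0.45, rg = 0.59)
scenario = mt.SimulationScenario.reference(p_snps=2000, n_gwas=(20000, 20000))
status = mt.assign_causal_status(2000, scenario, rng)
effects = mt.draw_effects(status, scenario, rng)
r = mt.draw_region_sumstats(effects.beta, blocks, scenario.n_gwas, rng)
ss = mt.wrap_sumstats(r, scenario.n_gwas, blocks)

# constant genetic covariance model; tune lambda on pseudo summary statistics
h2, cov = scenario.constant_totals
model = mt.constant_model(h2, cov, p=2000)
beta, lam, report = mt.tune_and_refit(ss, blocks, model, ref_panel, seed=7)
print(f"selected lambda = {lam:.2f}; nonzero = {(beta != 0).mean(axis=0)}")

# score an independent test cohort and evaluate against the true predictor
cohort = mt.simulate_liability_cohort(effects.beta, scenario, rng, panel=test_panel)
metrics = mt.evaluate(mt.score_prs(beta, test_panel), cohort)
print("cor(PRS, true G) =", np.round(metrics["cor_with_G"], 3))
print("AUC              =", np.round(metrics["auc"], 3))
```

This prints:

```
selected lambda = 51.22; nonzero = [0.8935 0.8875]
cor(PRS, true G) = [0.894 0.873]
AUC              = [0.869 0.928]
```

The selected model keeps ~89% of SNPs (the scenario is highly polygenic),
its scores correlate at 0.87–0.89 with the true genetic predictors, and they
discriminate affected from unaffected subjects (traits with 1% and 2%
prevalence) with AUCs of 0.87 and 0.93.

Real data enter through `read_sumstats` / `harmonize` (delimited summary
statistics with configurable column names), `read_plink` (bed/bim/fam
reference panels with missing-rate and MAF QC), and BED-like LD block
interval files. The same pipeline is exposed as a CLI:

```bash
mtlassosum fixture --p 2000 --n 500 --seed 1 --out panel
mtlassosum simulate --ref-panel panel --blocks panel.blocks.tsv --seed 2 --out sim
mtlassosum fit --sumstats sim/sumstats_trait1.tsv --sumstats sim/sumstats_trait2.tsv \
    --ref-panel panel --blocks panel.blocks.tsv --seed 3 --out fit
```

## Documentation

`docs/methods.md` describes the estimator, the covariance models, the tuning
construction, the simulation framework and its deliberate simplifications,
and all numerical choices (tolerances, PSD repairs, tie-breaking).
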
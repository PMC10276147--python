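"""Simulation framework: causal architectures, summary statistics, cohorts.

The generator emulates a two-trait study design modeled on schizophrenia and
bipolar disorder: a causal mixture where each SNP affects both traits, one, or
neither; correlated per-SNP effects drawn either from a four-component
constant-covariance mixture or from annotation-based per-SNP contributions;
region-wise summary statistics ``r_lk ~ N(R_l beta_lk, R_l / n_k)`` with
optional cross-trait noise correlation ``rho_o`` from GWAS sample overlap; and
dichotomous traits from a liability threshold model ``L = G + E`` with
prevalence-determined affection thresholds.

Reference scenario (defaults): heritabilities (0.47, 0.45), polygenicity
(0.49, 0.47) with P(causal for both) = 0.35, genetic correlation 0.59,
prevalences (1%, 2%).  The low-heritability and low-polygenicity alternatives
use (0.10, 0.09) and (0.12, 0.10) with P(both) = 0.08; the sample-overlap
sensitivity settings are rho_o = 0.16 and its doubled value 0.32.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ldref import GenotypePanel, LDBlockSet, partition_blocks, write_plink

logger = logging.getLogger(__name__)

STATUS_NONE, STATUS_T1, STATUS_T2, STATUS_BOTH = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of one simulation scenario (two traits).

    ``polygenicity`` is the per-trait proportion of causal SNPs; together with
    ``p_causal_both`` it determines the single-trait causal probabilities by
    subtraction.  ``rg`` is the target genetic correlation in the four-matrix
    mixture mode; in annotation mode the realized correlation follows from the
    annotation model.  ``rho_o`` is the cross-trait summary-statistic noise
    correlation induced by GWAS sample overlap.
    """

    h2: tuple[float, float] = (0.47, 0.45)
    polygenicity: tuple[float, float] = (0.49, 0.47)
    p_causal_both: float = 0.35
    rg: float = 0.59
    covariance_mode: str = "four_matrix"
    rho_o: float = 0.0
    prevalence: tuple[float, float] = (0.01, 0.02)
    n_gwas: tuple[int, int] = (23330, 23330)
    n_ref: int = 3000
    n_test: int = 3000
    p_snps: int = 423552
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = self.causal_probs
        if any(v < 0 for v in probs.values()):
            raise ValueError(f"inconsistent polygenicity settings: {probs}")
        if not all(0.0 < h < 1.0 for h in self.h2):
            raise ValueError("heritabilities must lie in (0, 1)")
        if not all(0.0 < k < 1.0 for k in self.prevalence):
            raise ValueError("prevalences must lie in (0, 1)")
        if abs(self.rg) > 1.0:
            raise ValueError("|rg| must not exceed 1")

    @property
    def causal_probs(self) -> dict[str, float]:
        both = self.p_causal_both
        t1 = self.polygenicity[0] - both
        t2 = self.polygenicity[1] - both
        return {"both": both, "t1": t1, "t2": t2, "none": 1.0 - both - t1 - t2}

    @property
    def constant_totals(self) -> tuple[np.ndarray, float]:
        """Totals for the matching constant covariance model."""
        h = np.asarray(self.h2)
        return h, float(self.rg * np.sqrt(h[0] * h[1]))

    @classmethod
    def reference(cls, **overrides) -> "SimulationScenario":
        return cls(**overrides)

    @classmethod
    def low_heritability(cls, **overrides) -> "SimulationScenario":
        return cls(h2=(0.10, 0.09), **overrides)

    @classmethod
    def low_polygenicity(cls, **overrides) -> "SimulationScenario":
        return cls(polygenicity=(0.12, 0.10), p_causal_both=0.08, **overrides)

    @classmethod
    def overlap_sensitivity(cls, doubled: bool = False, **overrides) -> "SimulationScenario":
        return cls(rho_o=0.32 if doubled else 0.16, **overrides)

    def with_(self, **overrides) -> "SimulationScenario":
        return replace(self, **overrides)


@dataclass
class EffectDraw:
    """Realized causal statuses, effect sizes, and scaling factors."""

    status: np.ndarray
    beta: np.ndarray
    alpha1: float
    alpha2: float

    @property
    def alpha(self) -> float:
        return float(np.sqrt(self.alpha1 * self.alpha2))


@dataclass
class LiabilityCohort:
    """Liability-threshold cohort: true genetic predictors and affection status."""

    G: np.ndarray
    liability: np.ndarray
    affected: np.ndarray
    thresholds: np.ndarray


class SyntheticPopulation:
    """A fixed synthetic population from which genotype panels are sampled.

    Genotypes come from a block-wise latent Gaussian copula: within each block
    the latent variable follows an AR(1) process with coefficient ``ld_decay``
    across adjacent SNPs, thresholded into 0/1/2 minor-allele counts by
    Hardy-Weinberg probabilities at minor-allele frequencies drawn uniformly
    from ``maf_range``.  The MAFs and block layout are fixed at construction so
    that independent panels (reference, validation, test cohorts) describe the
    same population.
    """

    def __init__(
        self,
        p_snps: int,
        block_size: int = 500,
        ld_decay: float = 0.9,
        maf_range: tuple[float, float] = (0.05, 0.5),
        seed: int | None = None,
        scale: str = "maf",
    ):
        if p_snps <= 0 or block_size <= 0:
            raise ValueError("p_snps and block_size must be positive")
        if not 0.0 <= ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        rng = np.random.default_rng(seed)
        self.p_snps = p_snps
        self.block_size = block_size
        self.ld_decay = ld_decay
        self.maf = rng.uniform(maf_range[0], maf_range[1], size=p_snps)
        self.maf = np.minimum(self.maf, 0.5 - 1e-6)
        self.scale = scale
        self.block_spans = [
            (a, min(a + block_size, p_snps)) for a in range(0, p_snps, block_size)
        ]
        # half-open position intervals matching the blocks (1 kb per SNP)
        self.snp_ids = np.array([f"snp{j:07d}" for j in range(p_snps)])
        self.pos = np.arange(p_snps, dtype=np.int64) * 1000 + 500

    def sample_panel(self, n_subjects: int, rng: np.random.Generator) -> GenotypePanel:
        phi = self.ld_decay
        geno = np.empty((n_subjects, self.p_snps), dtype=np.int8)
        for a, b in self.block_spans:
            m = b - a
            z = np.empty((n_subjects, m))
            eps = rng.standard_normal((n_subjects, m))
            z[:, 0] = eps[:, 0]
            c = np.sqrt(1.0 - phi**2)
            for j in range(1, m):
                z[:, j] = phi * z[:, j - 1] + c * eps[:, j]
            p = self.maf[a:b]
            lo = stats.norm.ppf((1.0 - p) ** 2)
            hi = stats.norm.ppf(1.0 - p**2)
            geno[:, a:b] = (z > lo).astype(np.int8) + (z > hi).astype(np.int8)
        # guard against monomorphic columns in small samples
        counts = geno.sum(axis=0)
        mono_low = counts == 0
        mono_high = counts == 2 * n_subjects
        for idx, val in ((np.nonzero(mono_low)[0], 1), (np.nonzero(mono_high)[0], 1)):
            for j in idx:
                geno[rng.integers(n_subjects), j] = val
        return GenotypePanel(
            genotypes=geno,
            snp_ids=self.snp_ids,
            chrom=np.full(self.p_snps, "1"),
            pos=self.pos,
            a1=np.full(self.p_snps, "A"),
            a2=np.full(self.p_snps, "G"),
            scale=self.scale,
        )

    def block_intervals(self) -> pd.DataFrame:
        rows = [
            {"chrom": "1", "start": int(self.pos[a] - 500), "end": int(self.pos[b - 1] + 500)}
            for a, b in self.block_spans
        ]
        return pd.DataFrame(rows)


def make_fixture_panel(
    n_subjects: int,
    p_snps: int,
    block_size: int = 500,
    ld_decay: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
    s: float = 0.5,
    out_prefix: str | Path | None = None,
    scale: str = "maf",
) -> tuple[GenotypePanel, LDBlockSet]:
    """One-shot synthetic panel plus matching LD block set.

    With ``out_prefix`` the panel is also written as PLINK bed/bim/fam and the
    block layout as a BED-like interval TSV, so downstream commands can consume
    them as ordinary files.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    pop_seed, sample_seed = ss.spawn(2)
    pop = SyntheticPopulation(
        p_snps, block_size=block_size, ld_decay=ld_decay, maf_range=maf_range,
        seed=pop_seed, scale=scale,
    )
    panel = pop.sample_panel(n_subjects, np.random.default_rng(sample_seed))
    blocks = partition_blocks(panel, intervals=pop.block_intervals(), s=s)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_plink(panel, out_prefix)
        pop.block_intervals().to_csv(
            out_prefix.parent / (out_prefix.name + ".blocks.tsv"),
            sep="\t", header=False, index=False,
        )
    return panel, blocks


def assign_causal_status(
    p_snps: int,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    predictions: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """I.i.d. multinomial causal assignment over {none, t1, t2, both}.

    In annotation mode ``predictions = (h2_1(j), h2_2(j))`` demotes statuses:
    a SNP with predicted heritability <= 0 for a trait is never causal for it.
    """
    probs = scenario.causal_probs
    status = rng.choice(
        [STATUS_BOTH, STATUS_T1, STATUS_T2, STATUS_NONE],
        size=p_snps,
        p=[probs["both"], probs["t1"], probs["t2"], probs["none"]],
    ).astype(np.int8)
    if predictions is not None:
        h1, h2 = predictions
        no1 = np.asarray(h1) <= 0.0
        no2 = np.asarray(h2) <= 0.0
        status[no1 & (status == STATUS_T1)] = STATUS_NONE
        status[no1 & (status == STATUS_BOTH)] = STATUS_T2
        status[no2 & (status == STATUS_T2)] = STATUS_NONE
        status[no2 & (status == STATUS_BOTH)] = STATUS_T1
    return status


def draw_effects(
    status: np.ndarray,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    contributions: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> EffectDraw:
    """Draw per-SNP effect pairs given causal statuses.

    Four-matrix mode: causal effects are Gaussian with a constant per-SNP
    variance within status class, ``v_k = h2_k / m_k`` with ``m_k`` the
    realized number of SNPs causal for trait k, and covariance
    ``c = rg sqrt(h2_1 h2_2) / m_both`` for dual-causal SNPs, so realized
    expected heritabilities and the genetic correlation hit their targets.

    Annotation mode (``contributions = (h1, h2, rho)``): per-SNP covariance
    matrices ``[[a1 h1(j), a rho(j)], [a rho(j), a2 h2(j)]]`` with scaling
    factors ``a_k = h2_k / sum_{j causal for k} h_k(j)`` and
    ``a = sqrt(a1 a2)``; non-PSD matrices are repaired by clamping the
    covariance, with a warning.
    """
    status = np.asarray(status)
    p = len(status)
    causal1 = (status == STATUS_T1) | (status == STATUS_BOTH)
    causal2 = (status == STATUS_T2) | (status == STATUS_BOTH)
    both = status == STATUS_BOTH
    m1, m2, mb = int(causal1.sum()), int(causal2.sum()), int(both.sum())
    if m1 == 0 or m2 == 0:
        raise ValueError("a trait has no causal SNPs; increase p_snps or polygenicity")
    beta = np.zeros((p, 2))
    h1t, h2t = scenario.h2

    if contributions is None:
        v1 = h1t / m1
        v2 = h2t / m2
        c = scenario.rg * np.sqrt(h1t * h2t) / mb if mb else 0.0
        cmax = np.sqrt(v1 * v2)
        if abs(c) > cmax:
            logger.warning("draw_effects: clamping mixture covariance to the PSD bound")
            c = np.sign(c) * cmax
        z = rng.standard_normal((p, 2))
        # 2x2 Cholesky applied only where needed
        beta[both, 0] = np.sqrt(v1) * z[both, 0]
        beta[both, 1] = (c / np.sqrt(v1)) * z[both, 0] + np.sqrt(
            max(v2 - c**2 / v1, 0.0)
        ) * z[both, 1]
        only1 = status == STATUS_T1
        only2 = status == STATUS_T2
        beta[only1, 0] = np.sqrt(v1) * z[only1, 0]
        beta[only2, 1] = np.sqrt(v2) * z[only2, 1]
        alpha1 = v1  # per-SNP variance plays the role of the scaling factor
        alpha2 = v2
    else:
        h1, h2, rho = (np.asarray(x, np.float64) for x in contributions)
        h1 = np.maximum(h1, 0.0)
        h2 = np.maximum(h2, 0.0)
        s1 = h1[causal1].sum()
        s2 = h2[causal2].sum()
        if s1 <= 0 or s2 <= 0:
            raise ValueError("predicted contributions of causal SNPs sum to zero")
        alpha1 = h1t / s1
        alpha2 = h2t / s2
        alpha = np.sqrt(alpha1 * alpha2)
        v1 = alpha1 * h1
        v2 = alpha2 * h2
        cv = alpha * rho
        bound = np.sqrt(v1 * v2)
        clip = np.abs(cv) > bound
        if (clip & both).any():
            logger.warning(
                "draw_effects: clamping %d non-PSD per-SNP covariances",
                int((clip & both).sum()),
            )
            cv = np.where(clip, np.sign(cv) * bound, cv)
        z = rng.standard_normal((p, 2))
        bmask = both & (v1 > 0)
        beta[bmask, 0] = np.sqrt(v1[bmask]) * z[bmask, 0]
        beta[bmask, 1] = (cv[bmask] / np.sqrt(v1[bmask])) * z[bmask, 0] + np.sqrt(
            np.maximum(v2[bmask] - cv[bmask] ** 2 / v1[bmask], 0.0)
        ) * z[bmask, 1]
        only1 = (status == STATUS_T1) & (v1 > 0)
        only2 = (status == STATUS_T2) & (v2 > 0)
        beta[only1, 0] = np.sqrt(v1[only1]) * z[only1, 0]
        beta[only2, 1] = np.sqrt(v2[only2]) * z[only2, 1]
        # dual-causal SNPs with zero trait-1 variance still get their trait-2 part
        rest2 = both & (v1 <= 0) & (v2 > 0)
        beta[rest2, 1] = np.sqrt(v2[rest2]) * z[rest2, 1]
    return EffectDraw(status=status, beta=beta, alpha1=float(alpha1), alpha2=float(alpha2))


def draw_region_sumstats(
    beta: np.ndarray,
    blocks: LDBlockSet,
    n: tuple[float, float] | np.ndarray,
    rng: np.random.Generator,
    rho_o: float = 0.0,
) -> np.ndarray:
    """Sample region-wise summary statistics ``r_lk ~ N(R_l beta_lk, R_l/n_k)``.

    With sample overlap, the two traits' noise components share the cross
    covariance ``rho_o R_l / sqrt(n_1 n_2)``; ``rho_o = 0`` makes them
    conditionally independent given their expected values.  Sampling uses an
    eigendecomposition of each block's LD matrix with negative eigenvalues
    floored at zero; decompositions are cached on the block set.
    """
    beta = np.atleast_2d(np.asarray(beta, np.float64).T).T
    n = np.asarray(n, np.float64)
    q = beta.shape[1]
    if q != len(n):
        raise ValueError("beta and n disagree on the number of traits")
    if rho_o != 0.0 and q != 2:
        raise ValueError("sample-overlap correlation is defined for two traits")
    cache = getattr(blocks, "_eig_cache", None)
    if cache is None:
        cache = {}
        blocks._eig_cache = cache
    r = np.empty_like(beta)
    for bi, ((a, b), R) in enumerate(zip(blocks.blocks, blocks.ld)):
        if bi not in cache:
            w, V = np.linalg.eigh(R)
            cache[bi] = (V, np.sqrt(np.maximum(w, 0.0)))
        V, sqw = cache[bi]
        m = b - a
        mean = R @ beta[a:b]
        z = rng.standard_normal((m, q))
        if rho_o != 0.0:
            z1 = z[:, 0].copy()
            z[:, 1] = rho_o * z1 + np.sqrt(1.0 - rho_o**2) * z[:, 1]
        noise = V @ (sqw[:, None] * z)
        r[a:b] = mean + noise / np.sqrt(n)
    return r


def simulate_liability_cohort(
    beta: np.ndarray,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    panel: GenotypePanel | None = None,
    n_subjects: int | None = None,
    empirical_threshold: bool = False,
    chunk: int = 20000,
) -> LiabilityCohort:
    """Liability-threshold cohort: ``L_ik = G_ik + E_ik``, affected above threshold.

    ``G_ik = sum_j beta_jk x_ij`` uses the panel's standardized genotypes, or
    i.i.d. standard-normal standardized genotypes when no panel is given (only
    columns with nonzero effects are materialized, in subject chunks).
    ``Var(E_k) = 1 - h2_k`` and the threshold is the upper-``K_k`` quantile of
    the theoretical unit-variance liability (``empirical_threshold``
    standardizes the realized liability instead).
    """
    beta = np.atleast_2d(np.asarray(beta, np.float64).T).T
    q = beta.shape[1]
    h2 = np.asarray(scenario.h2[:q], np.float64)
    K = np.asarray(scenario.prevalence[:q], np.float64)
    if panel is not None:
        from .tuning import score_prs

        G = score_prs(beta, panel)
    else:
        if n_subjects is None:
            raise ValueError("n_subjects required when no panel is given")
        active = np.nonzero((beta != 0.0).any(axis=1))[0]
        G = np.empty((n_subjects, q))
        for a in range(0, n_subjects, chunk):
            b = min(a + chunk, n_subjects)
            X = rng.standard_normal((b - a, len(active)))
            G[a:b] = X @ beta[active]
    n = G.shape[0]
    E = rng.standard_normal((n, q)) * np.sqrt(1.0 - h2)
    L = G + E
    thresholds = stats.norm.isf(K)
    if empirical_threshold:
        Ls = (L - L.mean(axis=0)) / L.std(axis=0, ddof=0)
        affected = Ls > thresholds
    else:
        affected = L > thresholds
    return LiabilityCohort(G=G, liability=L, affected=affected, thresholds=thresholds)


def evaluate(prs: np.ndarray, cohort: LiabilityCohort) -> dict:
    """Per-trait Pearson correlation with the true predictor, and AUC.

    AUC is the Mann-Whitney probability that a randomly chosen affected
    subject has a higher PRS than an unaffected one.  Zero-variance PRSs (or
    single-class cohorts) give NaN with a warning.
    """
    prs = np.atleast_2d(np.asarray(prs, np.float64).T).T
    q = prs.shape[1]
    cor = np.full(q, np.nan)
    auc = np.full(q, np.nan)
    for k in range(q):
        if prs[:, k].std() == 0.0:
            logger.warning("evaluate: zero-variance PRS for trait %d", k)
        else:
            cor[k] = float(np.corrcoef(prs[:, k], cohort.G[:, k])[0, 1])
            y = cohort.affected[:, k]
            if 0 < y.sum() < len(y):
                auc[k] = float(roc_auc_score(y, prs[:, k]))
            else:
                logger.warning("evaluate: single-class cohort for trait %d", k)
    return {"cor_with_G": cor, "auc": auc}
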
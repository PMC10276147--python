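"""End-to-end orchestration of the simulate / tune / fit / evaluate pipeline.

These helpers wire the modules together the way a full analysis would run:
draw a synthetic population, generate region-wise summary statistics for two
correlated traits, tune the LASSO penalty on pseudo summary statistics,
re-estimate coefficients on the full-sample statistics at the selected
penalty, and score an independent test cohort.  They are used by the
command-line interface, the test suite, and the results-reproduction script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .covariance import GeneticCovarianceModel, constant_model
from .ldref import GenotypePanel, LDBlockSet
from .simulate import (
    SimulationScenario,
    SyntheticPopulation,
    assign_causal_status,
    draw_effects,
    draw_region_sumstats,
    evaluate,
    simulate_liability_cohort,
)
from .solver import PenaltySpec, fit
from .sumstats import PseudoSplit, SummaryStatistics, pseudo_split
from .tuning import lambda_grid, select_model

logger = logging.getLogger(__name__)


def wrap_sumstats(
    r: np.ndarray,
    n: np.ndarray,
    blocks: LDBlockSet,
    trait_names: list[str] | None = None,
) -> SummaryStatistics:
    """Package simulated correlation vectors as harmonized summary statistics."""
    gp = blocks.panel
    r = np.atleast_2d(np.asarray(r).T).T
    q = r.shape[1]
    return SummaryStatistics(
        snp_ids=gp.snp_ids,
        chrom=gp.chrom,
        pos=gp.pos,
        ref_allele=gp.a2,
        alt_allele=gp.a1,
        r=r,
        n=np.asarray(n, dtype=np.int64),
        trait_names=trait_names or [f"trait{k + 1}" for k in range(q)],
    )


def tune_and_refit(
    ss: SummaryStatistics,
    blocks: LDBlockSet,
    model: GeneticCovarianceModel,
    panel0: GenotypePanel,
    nB_fraction: float = 0.1,
    n_points: int = 20,
    floor: float = 0.05,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, "object"]:
    """Pseudo-split tuning followed by re-estimation on the full statistics.

    Returns (beta, selected lambda, selection report).
    """
    split = pseudo_split(ss, blocks, nB_fraction=nB_fraction, seed=seed)
    penalty, path = lambda_grid(
        split, blocks, model, n_points=n_points, floor=floor, s=blocks.s,
        tol=tol, max_iter=max_iter,
    )
    report = select_model({"model": path}, split.rB, panel0)
    lam = report.selected_lambda
    # warm-started refit on the full-sample statistics down to the selected lambda
    lams = penalty.lambdas[penalty.lambdas >= lam]
    refit = fit(
        ss, blocks, model,
        PenaltySpec(lambdas=lams, s=penalty.s, weights=penalty.weights),
        tol=tol, max_iter=max_iter,
    )
    return refit.beta[-1], lam, report


@dataclass
class ComparisonResult:
    """Multivariate vs decoupled-univariate predictive performance."""

    cor_mv: np.ndarray
    cor_uni: np.ndarray
    auc_mv: np.ndarray
    auc_uni: np.ndarray
    lambda_mv: float
    lambda_uni: float

    @property
    def mv_wins(self) -> bool:
        return float(np.nanmean(self.cor_mv)) > float(np.nanmean(self.cor_uni))


def run_reference_comparison(
    seed: int,
    p_snps: int = 20000,
    n_equiv: int = 5000,
    n_ref: int = 1000,
    n_test: int = 2000,
    n_points: int = 15,
    scenario: SimulationScenario | None = None,
    population: SyntheticPopulation | None = None,
    panels: tuple[GenotypePanel, LDBlockSet, GenotypePanel] | None = None,
    tol: float = 1e-4,
) -> ComparisonResult:
    """One scaled-down replicate of the reference-scenario comparison.

    Draws effects under the reference architecture, simulates region-wise
    summary statistics at ``n_equiv`` training-equivalent subjects, tunes and
    fits the multivariate model (constant covariance matching the scenario)
    and its decoupled counterpart (cross-trait covariance zeroed), and scores
    both on an independent liability-threshold test cohort.  Pre-built panels
    can be passed to amortize genotype generation across replicates.
    """
    if scenario is None:
        scenario = SimulationScenario.reference(
            n_gwas=(n_equiv, n_equiv), n_ref=n_ref, n_test=n_test, p_snps=p_snps
        )
    root = np.random.SeedSequence(seed)
    s_panels, s_status, s_eff, s_sum, s_split, s_cohort = root.spawn(6)
    if panels is None:
        if population is None:
            population = SyntheticPopulation(p_snps, seed=s_panels.spawn(1)[0])
        pr, pt = s_panels.spawn(2)
        ref_panel = population.sample_panel(n_ref, np.random.default_rng(pr))
        from .ldref import partition_blocks

        blocks = partition_blocks(ref_panel, intervals=population.block_intervals(), s=0.5)
        test_panel = population.sample_panel(n_test, np.random.default_rng(pt))
    else:
        ref_panel, blocks, test_panel = panels

    status = assign_causal_status(p_snps, scenario, np.random.default_rng(s_status))
    effects = draw_effects(status, scenario, np.random.default_rng(s_eff))
    n = np.array([n_equiv, n_equiv], dtype=np.int64)
    r = draw_region_sumstats(
        effects.beta, blocks, n, np.random.default_rng(s_sum), rho_o=scenario.rho_o
    )
    r = np.clip(r, -0.999999, 0.999999)
    ss = wrap_sumstats(r, n, blocks)

    h2, cov = scenario.constant_totals
    model_mv = constant_model(h2, cov, p_snps)
    model_uni = model_mv.diagonalized()

    split_seed = int(s_split.generate_state(1)[0] % (2**31))
    beta_mv, lam_mv, _ = tune_and_refit(
        ss, blocks, model_mv, ref_panel, seed=split_seed, n_points=n_points, tol=tol
    )
    beta_uni, lam_uni, _ = tune_and_refit(
        ss, blocks, model_uni, ref_panel, seed=split_seed, n_points=n_points, tol=tol
    )

    cohort = simulate_liability_cohort(
        effects.beta, scenario, np.random.default_rng(s_cohort), panel=test_panel
    )
    from .tuning import score_prs

    metrics_mv = evaluate(score_prs(beta_mv, test_panel), cohort)
    metrics_uni = evaluate(score_prs(beta_uni, test_panel), cohort)
    return ComparisonResult(
        cor_mv=metrics_mv["cor_with_G"],
        cor_uni=metrics_uni["cor_with_G"],
        auc_mv=metrics_mv["auc"],
        auc_uni=metrics_uni["auc"],
        lambda_mv=lam_mv,
        lambda_uni=lam_uni,
    )
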
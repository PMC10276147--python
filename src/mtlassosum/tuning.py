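"""Lambda grids, the pseudo-validation selection criterion, and PRS scoring.

The penalty path starts at ``lambda_max``, the smallest lambda at which the
all-zero solution is stationary (``max_jk |A0_jk| / w_jk`` with ``A0`` the
linear term at beta = 0), and is extended downward until the proportion of
SNPs with nonzero coefficients reaches a floor (default 5%) for every trait.

Model and lambda selection maximizes, over the fitted path, the criterion

``f(lambda) = beta' rB / sqrt((1/n0) beta' X0'X0 beta)``

stacked over traits, where rB are validation (pseudo) correlations and X0 the
standardized genotypes of an independent reference sample; this is a monotone
surrogate of the correlation between the PRS and the trait in a validation
sample.  The all-zero solution is excluded via a -inf sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import GeneticCovarianceModel
from .errors import InputDataError
from .ldref import GenotypePanel, LDBlockSet
from .solver import FitResult, PenaltySpec, _as_r_n, fit

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Per-(model, lambda) criterion values and the selected configuration."""

    table: pd.DataFrame
    selected_model: str
    selected_lambda: float
    selected_beta: np.ndarray

    @property
    def criterion(self) -> float:
        row = self.table[
            (self.table["model"] == self.selected_model)
            & (self.table["lambda"] == self.selected_lambda)
        ]
        return float(row["criterion"].iloc[0])


def lambda_max(data, model: GeneticCovarianceModel, weights: np.ndarray | None = None) -> float:
    """Smallest lambda yielding the all-zero solution."""
    r, n = _as_r_n(data)
    A0 = np.abs(n / model.residual * r)
    if weights is not None:
        with np.errstate(invalid="ignore"):
            A0 = np.where(np.isfinite(weights), A0 / weights, 0.0)
    return float(A0.max())


def lambda_grid(
    data,
    blocks: LDBlockSet,
    model: GeneticCovarianceModel,
    n_points: int = 20,
    floor: float = 0.05,
    lambda_min_ratio: float = 0.01,
    s: float | None = None,
    weights: np.ndarray | None = None,
    max_extensions: int = 8,
    **fit_kwargs,
) -> tuple[PenaltySpec, FitResult]:
    """Build a log-spaced descending lambda grid and fit the path along it.

    The grid runs from ``lambda_max`` down to ``lambda_max * lambda_min_ratio``
    and is extended downward (same log step) until the smallest lambda gives a
    nonzero-coefficient proportion of at least ``floor`` for every trait; if
    the floor is unreachable a warning is logged and the best-effort grid
    returned.  Fitting is warm-started, so the path is returned alongside the
    grid to avoid recomputation.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    s = blocks.s if s is None else s
    lmax = lambda_max(data, model, weights)
    ratio, n_total = lambda_min_ratio, n_points
    for attempt in range(max_extensions + 1):
        grid = np.geomspace(lmax, lmax * ratio, n_total)
        penalty = PenaltySpec(lambdas=grid, s=s, weights=weights)
        result = fit(data, blocks, model, penalty, **fit_kwargs)
        if np.all(result.nonzero[-1] >= floor):
            return penalty, result
        # extend by another full lambda_min_ratio span (warm-started refit)
        ratio *= lambda_min_ratio
        n_total += n_points - 1
    logger.warning(
        "lambda_grid: sparsity floor %.2f unreachable (min proportions %s); "
        "returning best-effort grid",
        floor,
        result.nonzero[-1],
    )
    return penalty, result


def score_prs(
    beta: np.ndarray,
    panel: GenotypePanel,
    standardize_index: np.ndarray | None = None,
) -> np.ndarray:
    """Per-subject PRS per trait, ``PRS_ik = sum_j beta_jk x_ij``.

    With ``standardize_index`` the scores are shifted/scaled to mean 0 and
    variance 1 within that reference subject group.
    """
    beta = np.atleast_2d(np.asarray(beta, np.float64).T).T
    if beta.shape[0] != panel.n_snps:
        raise InputDataError("coefficients and panel have different SNP counts")
    prs = np.zeros((panel.n_subjects, beta.shape[1]))
    chunk = 2048
    for a in range(0, panel.n_snps, chunk):
        b = min(a + chunk, panel.n_snps)
        prs += panel.standardized(a, b) @ beta[a:b]
    if standardize_index is not None:
        ref = prs[standardize_index]
        sd = ref.std(axis=0, ddof=0)
        if np.any(sd == 0.0):
            raise InputDataError("zero-variance PRS in the standardization group")
        prs = (prs - ref.mean(axis=0)) / sd
    return prs


def selection_criterion(
    beta: np.ndarray,
    rB: np.ndarray,
    panel0: GenotypePanel,
) -> float:
    """Validation criterion ``beta'rB / sqrt((1/n0) sum_k ||X0 beta_k||^2)``.

    Returns -inf for an all-zero coefficient matrix (degenerate denominator),
    which excludes it from any argmax.
    """
    beta = np.atleast_2d(np.asarray(beta, np.float64).T).T
    rB = np.atleast_2d(np.asarray(rB, np.float64).T).T
    if beta.shape != rB.shape:
        raise InputDataError("beta and rB shapes differ")
    if beta.shape[0] != panel0.n_snps:
        raise InputDataError("beta and validation panel have different SNP counts")
    if not np.any(beta):
        return -np.inf
    num = float(np.sum(beta * rB))
    prs = score_prs(beta, panel0)
    denom = float(np.sqrt((prs**2).sum() / panel0.n_subjects))
    if denom == 0.0:
        return -np.inf
    return num / denom


def select_model(
    fits: dict[str, FitResult],
    rB: np.ndarray,
    panel0: GenotypePanel,
) -> SelectionReport:
    """Evaluate the criterion over every (model, lambda) and pick the argmax.

    Ties are broken toward the largest lambda (sparsest model), then the first
    model label in insertion order.
    """
    if not fits:
        raise InputDataError("no fitted paths to select from")
    rows = []
    best = (-np.inf, None)
    for label, result in fits.items():
        for i, lam in enumerate(result.lambdas):
            crit = selection_criterion(result.beta[i], rB, panel0)
            rows.append(
                {
                    "model": label,
                    "lambda": float(lam),
                    "criterion": crit,
                    **{
                        f"nonzero_{k}": result.nonzero[i, k]
                        for k in range(result.beta.shape[2])
                    },
                }
            )
            if np.isfinite(crit) and crit > best[0]:
                best = (crit, (label, i))
    if best[1] is None:
        raise InputDataError("no admissible model: all criteria are -inf")
    label, i = best[1]
    return SelectionReport(
        table=pd.DataFrame(rows),
        selected_model=label,
        selected_lambda=float(fits[label].lambdas[i]),
        selected_beta=fits[label].beta[i].copy(),
    )
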
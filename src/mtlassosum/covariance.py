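"""Per-SNP genetic covariance models.

The solver's quadratic prior needs, for every SNP j, a q x q matrix
``Sigma_bj`` of genetic variance/covariance contributions whose per-trait sums
over SNPs equal the trait heritabilities ``h2_gk``, plus residual variances
``sigma2_ek = 1 - h2_gk`` (total trait variance fixed at 1).  Two model
families are provided:

* a constant model where every SNP contributes ``totals / p`` — the classical
  assumption that standardized genotypes contribute equally;
* an annotation-based model where per-SNP heritabilities and genetic covariance
  are linear in genomic annotations, with coefficients estimated by cross-trait
  stratified LD-score regression on products of Z scores,
  ``E[Z_j1 Z_j2] = sqrt(n1 n2) sum_C l(j,C) theta_C (+ sqrt(n1 n2) b12)``,
  and companion single-trait regressions ``E[Z_jk^2] = 1 + n_k sum_C l(j,C)
  tau_kC``.  Raw per-SNP predictions may violate positive semi-definiteness;
  they are repaired (heritabilities floored at 0, covariances clamped to
  ``max(0, sqrt(h1(j) h2(j)) - margin)`` in magnitude) and rescaled so the
  per-trait totals match target heritabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputDataError
from .ldref import LDBlockSet

logger = logging.getLogger(__name__)


@dataclass
class GeneticCovarianceModel:
    """Per-SNP genetic covariance matrices and residual variances.

    ``sigma_b`` has shape (p, q, q); per-trait diagonal sums define the
    heritabilities and ``residual = 1 - h2``.  The precision cache inverts a
    copy of each matrix whose eigenvalues are floored at a small positive
    value, so SNPs contributing (near) zero heritability are heavily
    ridge-penalized instead of producing singular systems.
    """

    sigma_b: np.ndarray
    heritabilities: np.ndarray = field(init=False)
    residual: np.ndarray = field(init=False)
    eps_scale: float = 1e-3

    def __post_init__(self) -> None:
        self.sigma_b = np.asarray(self.sigma_b, dtype=np.float64)
        if self.sigma_b.ndim != 3 or self.sigma_b.shape[1] != self.sigma_b.shape[2]:
            raise ValueError("sigma_b must have shape (p, q, q)")
        if not np.allclose(self.sigma_b, np.swapaxes(self.sigma_b, 1, 2), atol=1e-10):
            raise ValueError("sigma_b matrices must be symmetric")
        diag = np.einsum("jkk->jk", self.sigma_b)
        self.heritabilities = diag.sum(axis=0)
        if np.any(self.heritabilities <= 0.0) or np.any(self.heritabilities >= 1.0):
            raise ValueError("per-trait heritabilities must lie in (0, 1)")
        self.residual = 1.0 - self.heritabilities
        self._precision: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return self.sigma_b.shape[0]

    @property
    def n_traits(self) -> int:
        return self.sigma_b.shape[1]

    @property
    def eps_floor(self) -> np.ndarray:
        """Per-trait diagonal floor used to invert degenerate matrices."""
        return self.eps_scale * self.heritabilities / self.n_snps

    @property
    def precision(self) -> np.ndarray:
        """Cached per-SNP inverses ``Sigma_bj^{-1}`` after the invertibility floor."""
        if self._precision is None:
            sig = self.sigma_b.copy()
            w = np.linalg.eigvalsh(sig)
            if np.any(w[:, 0] < -1e-10):
                raise ValueError("sigma_b contains non-PSD matrices; repair them first")
            floor = self.eps_floor
            degenerate = w[:, 0] < floor.min()
            if degenerate.any():
                sig[degenerate] += np.diag(floor)
            self._precision = np.linalg.inv(sig)
            self._precision = (self._precision + np.swapaxes(self._precision, 1, 2)) / 2.0
        return self._precision

    def diagonalized(self) -> "GeneticCovarianceModel":
        """Copy with cross-trait covariances zeroed (decoupled univariate prior)."""
        sig = self.sigma_b.copy()
        diag = np.einsum("jkk->jk", sig).copy()
        sig[:] = 0.0
        np.einsum("jkk->jk", sig)[:] = diag
        return GeneticCovarianceModel(sigma_b=sig, eps_scale=self.eps_scale)

    def subset_trait(self, k: int) -> "GeneticCovarianceModel":
        return GeneticCovarianceModel(
            sigma_b=self.sigma_b[:, k : k + 1, k : k + 1], eps_scale=self.eps_scale
        )


def constant_model(
    h2: tuple[float, ...] | np.ndarray,
    cov: float | np.ndarray,
    p: int,
) -> GeneticCovarianceModel:
    """Constant-per-SNP model: every ``Sigma_bj = totals / p``.

    ``h2`` gives the per-trait heritability totals; ``cov`` either the single
    cross-trait covariance total (q = 2) or a full symmetric (q, q) matrix of
    totals whose diagonal is overridden by ``h2``.
    """
    h2 = np.asarray(h2, dtype=np.float64)
    q = len(h2)
    if np.any(h2 <= 0.0) or np.any(h2 >= 1.0):
        raise ValueError("heritabilities must lie in (0, 1)")
    totals = np.zeros((q, q))
    if np.isscalar(cov) or np.ndim(cov) == 0:
        if q == 1:
            totals = np.diag(h2)
        elif q == 2:
            totals = np.array([[h2[0], float(cov)], [float(cov), h2[1]]])
        else:
            totals = np.full((q, q), float(cov))
            np.fill_diagonal(totals, h2)
    else:
        totals = np.asarray(cov, dtype=np.float64).copy()
        np.fill_diagonal(totals, h2)
    if np.linalg.eigvalsh(totals)[0] < -1e-12:
        raise ValueError("total genetic covariance matrix is not positive semi-definite")
    sigma = np.repeat(totals[None, :, :] / p, p, axis=0)
    return GeneticCovarianceModel(sigma_b=sigma)


@dataclass
class AnnotationTable:
    """Per-SNP annotation values and their LD scores.

    ``a`` is (p, C) with a mandatory all-ones baseline column; ``ld_scores``
    holds ``l(j,C) = sum_l a_lC R_jl^2`` computed from the same panel/blocks
    used downstream (block-wise, cross-block LD treated as zero).
    """

    a: np.ndarray
    names: list[str]
    ld_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.ndim != 2 or self.a.shape[1] != len(self.names):
            raise ValueError("annotation matrix/names mismatch")
        if not any(np.allclose(self.a[:, c], 1.0) for c in range(self.a.shape[1])):
            raise InputDataError("a baseline (all-ones) annotation column is required")

    @property
    def n_snps(self) -> int:
        return self.a.shape[0]

    def with_ld_scores(self, blocks: LDBlockSet) -> "AnnotationTable":
        if blocks.n_snps != self.n_snps:
            raise InputDataError("annotation table and block set are not aligned")
        ld = np.empty_like(self.a)
        for (a0, b0), R in zip(blocks.blocks, blocks.ld):
            ld[a0:b0] = (R**2) @ self.a[a0:b0]
        return AnnotationTable(a=self.a, names=self.names, ld_scores=ld)


def read_annotations(path: str | Path, baseline: str = "baseline") -> AnnotationTable:
    """Read a headered TSV of per-SNP annotations (baseline column mandatory)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.lower() not in ("snp", "chrom", "pos")]
    if baseline not in cols:
        raise InputDataError(f"annotation file lacks the mandatory {baseline!r} column")
    return AnnotationTable(a=df[cols].to_numpy(np.float64), names=cols)


@dataclass
class CrossTraitLdscFit:
    """Coefficients from cross-trait stratified LD-score regression."""

    theta: np.ndarray
    tau: np.ndarray  # (q, C)
    b12: float
    trait_intercepts: np.ndarray
    annotation_names: list[str]

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.tau))):
            raise ValueError("non-finite LD-score regression coefficients")


def _checked_lstsq(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise InputDataError(f"rank-deficient annotation design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_cross_trait_ldsc(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    annot: AnnotationTable,
    with_intercept: bool = False,
    weights: np.ndarray | None = None,
) -> CrossTraitLdscFit:
    """Estimate annotation effects on genetic covariance and heritabilities.

    theta comes from least squares of ``Z_j1 Z_j2`` on ``sqrt(n1 n2) l(j,C)``
    (plus a ``sqrt(n1 n2) b12`` sample-overlap intercept only if requested,
    b12 = 0 otherwise); ``tau_kC`` analogously from ``Z_jk^2 - 1`` on
    ``n_k l(j,C)``.  Unweighted by default; pass ``weights`` for 1/l-style
    weighting.
    """
    if annot.ld_scores is None:
        raise InputDataError("annotation table needs LD scores; call with_ld_scores first")
    ell = annot.ld_scores
    z1 = np.asarray(z1, np.float64)
    z2 = np.asarray(z2, np.float64)
    if not (len(z1) == len(z2) == annot.n_snps):
        raise InputDataError("Z scores and annotations are not aligned on SNPs")
    if annot.n_snps < ell.shape[1] + 1:
        raise InputDataError("need at least C+1 SNPs to fit C annotation effects")
    w = np.ones(annot.n_snps) if weights is None else np.sqrt(np.asarray(weights))

    root_n = np.sqrt(n1 * n2)
    X = root_n * ell
    names = list(annot.names)
    if with_intercept:
        X = np.column_stack([X, np.full(annot.n_snps, root_n)])
        names = names + ["b12"]
    coef = _checked_lstsq(X * w[:, None], (z1 * z2) * w, names)
    theta = coef[: ell.shape[1]]
    b12 = float(coef[-1]) if with_intercept else 0.0

    taus, intercepts = [], []
    for zk, nk in ((z1, n1), (z2, n2)):
        Xk = nk * ell
        if with_intercept:
            Xk = np.column_stack([Xk, np.ones(annot.n_snps)])
            ck = _checked_lstsq(Xk * w[:, None], zk**2 * w, names)
            taus.append(ck[: ell.shape[1]])
            intercepts.append(float(ck[-1]))
        else:
            ck = _checked_lstsq(Xk * w[:, None], (zk**2 - 1.0) * w, list(annot.names))
            taus.append(ck)
            intercepts.append(1.0)
    return CrossTraitLdscFit(
        theta=theta,
        tau=np.vstack(taus),
        b12=b12,
        trait_intercepts=np.array(intercepts),
        annotation_names=list(annot.names),
    )


def predict_snp_contributions(
    fit: CrossTraitLdscFit, annot: AnnotationTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw per-SNP predictions (h2_1(j), h2_2(j), rho_g(j)); may be negative."""
    if annot.names != fit.annotation_names:
        raise InputDataError("annotation columns do not match the fitted model")
    h1 = annot.a @ fit.tau[0]
    h2 = annot.a @ fit.tau[1]
    rho = annot.a @ fit.theta
    return h1, h2, rho


def repair_and_scale(
    h1: np.ndarray,
    h2: np.ndarray,
    rho: np.ndarray,
    targets: tuple[float, float],
    margin: float = 0.001,
    sign_policy: str = "signed",
    eps_scale: float = 1e-3,
) -> GeneticCovarianceModel:
    """PSD repair and rescaling of raw per-SNP contributions (two traits).

    Negative predicted heritabilities are floored at 0 (forcing the SNP's
    covariance to 0); covariances exceeding the PSD bound are replaced by
    ``max(0, sqrt(h1(j) h2(j)) - margin)`` in magnitude, keeping the predicted
    sign under the default policy (``sign_policy="nonnegative"`` keeps the
    repair literal-non-negative).  Matrices are then rescaled so per-trait sums
    equal the target totals, with the covariance scaled by the geometric mean
    of the two trait factors, which preserves both per-SNP genetic
    correlations of unrepaired SNPs and positive semi-definiteness.
    """
    t1, t2 = targets
    if not (0.0 < t1 < 1.0 and 0.0 < t2 < 1.0):
        raise ValueError("target heritabilities must lie in (0, 1)")
    if sign_policy not in ("signed", "nonnegative"):
        raise ValueError("sign_policy must be 'signed' or 'nonnegative'")
    h1 = np.maximum(np.asarray(h1, np.float64), 0.0)
    h2 = np.maximum(np.asarray(h2, np.float64), 0.0)
    rho = np.asarray(rho, np.float64).copy()
    bound = np.sqrt(h1 * h2)
    zero_h = (h1 == 0.0) | (h2 == 0.0)
    rho[zero_h] = 0.0
    viol = np.abs(rho) > bound
    if viol.any():
        logger.info("repair_and_scale: clamping %d covariances to the PSD bound",
                    int(viol.sum()))
        repaired = np.maximum(0.0, bound[viol] - margin)
        if sign_policy == "signed":
            repaired = np.sign(rho[viol]) * repaired
        rho[viol] = repaired

    s1, s2 = h1.sum(), h2.sum()
    if s1 <= 0.0 or s2 <= 0.0:
        raise InputDataError("repaired per-SNP heritabilities sum to zero")
    c1, c2 = t1 / s1, t2 / s2
    h1 *= c1
    h2 *= c2
    rho *= np.sqrt(c1 * c2)
    sigma = np.empty((len(h1), 2, 2))
    sigma[:, 0, 0] = h1
    sigma[:, 1, 1] = h2
    sigma[:, 0, 1] = sigma[:, 1, 0] = rho
    return GeneticCovarianceModel(sigma_b=sigma, eps_scale=eps_scale)


def write_model(model: GeneticCovarianceModel, outdir: str | Path,
                snp_ids: np.ndarray | None = None) -> None:
    """Serialize a two-trait model as per-SNP TSV plus JSON totals."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model.n_traits != 2:
        raise ValueError("TSV serialization is defined for two traits")
    df = pd.DataFrame(
        {
            "h2_1": model.sigma_b[:, 0, 0],
            "h2_2": model.sigma_b[:, 1, 1],
            "rho": model.sigma_b[:, 0, 1],
        }
    )
    if snp_ids is not None:
        df.insert(0, "snp", snp_ids)
    df.to_csv(outdir / "covariance_model.tsv", sep="\t", index=False)
    with open(outdir / "covariance_totals.json", "w") as fh:
        json.dump(
            {
                "heritabilities": model.heritabilities.tolist(),
                "covariance": float(model.sigma_b[:, 0, 1].sum()),
                "residual": model.residual.tolist(),
            },
            fh,
            indent=2,
        )


def read_model(path: str | Path) -> GeneticCovarianceModel:
    df = pd.read_csv(Path(path) / "covariance_model.tsv", sep="\t")
    sigma = np.empty((len(df), 2, 2))
    sigma[:, 0, 0] = df["h2_1"]
    sigma[:, 1, 1] = df["h2_2"]
    sigma[:, 0, 1] = sigma[:, 1, 0] = df["rho"]
    return GeneticCovarianceModel(sigma_b=sigma)
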
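"""GWAS summary statistics: reading, harmonization, and pseudo splits.

The package works on SNP-trait correlations ``r_jk = t_j / sqrt(n_j - 2 +
t_j^2)`` recovered from published association statistics (beta/SE, signed p
value, or Z score).  Harmonization aligns every trait's correlations to a
reference panel's counted allele and SNP order, so that the solver, the LD
matrices, and the covariance model all index the same SNPs.

Pseudo training/validation summary statistics let the LASSO penalty be tuned
without individual-level validation data: the full-sample correlations are
perturbed with reference-panel noise so that the training part behaves like
correlations estimated from ``nA_k`` subjects, and the validation part is the
exact algebraic complement ``rB_k = (n_k r_k - nA_k rA_k) / nB``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputDataError
from .ldref import AMBIGUOUS_PAIRS, LDBlockSet

logger = logging.getLogger(__name__)

#: canonical column names understood downstream
STANDARD_COLUMNS = ("snp", "chrom", "pos", "a1", "a2", "beta", "se", "p", "sign", "z", "n")


@dataclass
class SummaryStatistics:
    """Harmonized SNP-trait correlations aligned to a reference panel.

    ``r`` is the p x q matrix of correlations ``r_jk`` (each strictly inside
    (-1, 1)); ``n`` the per-trait GWAS sample sizes.  SNP order matches the
    companion :class:`~mtlassosum.ldref.LDBlockSet`.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    r: np.ndarray
    n: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.r = np.atleast_2d(np.asarray(self.r, dtype=np.float64).T).T
        self.n = np.asarray(self.n)
        if np.any(np.abs(self.r) >= 1.0):
            raise InputDataError("|r_jk| must be < 1")
        if np.any(self.n <= 0) or not np.issubdtype(self.n.dtype, np.integer):
            raise InputDataError("sample sizes must be positive integers")
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise InputDataError("duplicate SNP ids in harmonized summary statistics")
        if self.r.shape != (len(self.snp_ids), len(self.n)):
            raise ValueError("r must be (n_snps, n_traits)")

    @property
    def n_snps(self) -> int:
        return self.r.shape[0]

    @property
    def n_traits(self) -> int:
        return self.r.shape[1]

    def to_frames(self) -> list[pd.DataFrame]:
        """One per-trait table per trait, re-ingestible by :func:`harmonize`."""
        out = []
        for k in range(self.n_traits):
            out.append(
                pd.DataFrame(
                    {
                        "snp": self.snp_ids,
                        "chrom": self.chrom,
                        "pos": self.pos,
                        "a1": self.alt_allele,
                        "a2": self.ref_allele,
                        "r": self.r[:, k],
                        "n": np.full(self.n_snps, self.n[k]),
                    }
                )
            )
        return out


@dataclass
class PseudoSplit:
    """Pseudo training/validation summary statistics.

    For every SNP j and trait k the recombination identity
    ``nA_k rA_jk + nB rB_jk = n_k r_jk`` holds exactly up to float rounding.
    """

    rA: np.ndarray
    rB: np.ndarray
    nA: np.ndarray
    nB: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nB <= 0:
            raise ValueError("nB must be positive")
        if np.any(self.nA <= 0):
            raise ValueError("all nA_k must be positive")


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_label: str = "trait",
    n_default: float | None = None,
) -> pd.DataFrame:
    """Read one trait's GWAS summary statistics from delimited text.

    ``column_map`` maps canonical names (``snp, a1, a2, n, beta, se, p, sign,
    z, chrom, pos``) to the file's column names; canonical names already
    present in the file need not be mapped.  Mandatory fields are the SNP id,
    both alleles, a sample size (or ``n_default``), and at least one usable
    association statistic.  Rows missing mandatory fields are dropped and
    counted in the log.
    """
    df = pd.read_csv(path, sep=r"\s+")
    column_map = dict(column_map or {})
    rename = {}
    lower = {c.lower(): c for c in df.columns}
    for canon in STANDARD_COLUMNS:
        src = column_map.get(canon)
        if src is not None:
            if src not in df.columns:
                raise ConfigurationError(f"column {src!r} (for {canon!r}) not in {path}")
            rename[src] = canon
        elif canon in lower:
            rename[lower[canon]] = canon
    df = df.rename(columns=rename)

    for canon in ("snp", "a1", "a2"):
        if canon not in df.columns:
            raise ConfigurationError(f"mandatory column {canon!r} unresolvable in {path}")
    if "n" not in df.columns:
        if n_default is None:
            raise ConfigurationError(f"no sample-size column in {path} and no n_default given")
        logger.info("read_sumstats(%s): using global N=%s", path, n_default)
        df["n"] = n_default
    has_stat = ("beta" in df.columns and "se" in df.columns) or "z" in df.columns or (
        "p" in df.columns and ("sign" in df.columns or "beta" in df.columns)
    )
    if not has_stat and "r" not in df.columns:
        raise ConfigurationError(
            f"no usable association statistic (beta+se, p+sign, or z) in {path}"
        )

    mandatory = ["snp", "a1", "a2", "n"]
    stat_cols = [c for c in ("beta", "se", "p", "sign", "z", "r") if c in df.columns]
    before = len(df)
    df = df.dropna(subset=mandatory + stat_cols)
    dropped = before - len(df)
    if dropped:
        logger.warning("read_sumstats(%s): dropped %d rows with missing fields", path, dropped)
    if df.empty:
        raise InputDataError(f"no usable rows in {path}")
    dup = df["snp"].duplicated()
    if dup.any():
        logger.warning("read_sumstats(%s): %d duplicated SNP ids, keeping first", path, dup.sum())
        df = df[~dup]
    df = df.reset_index(drop=True)
    df.attrs["trait_label"] = trait_label
    return df


def to_correlation(table: pd.DataFrame, mode: str = "auto") -> np.ndarray:
    """SNP-trait correlations from association statistics.

    ``r_j = t_j / sqrt(n_j - 2 + t_j^2)`` where ``t_j`` is beta/SE
    (``beta_se``), the signed normal quantile of a two-sided p value
    (``p_sign``), or the Z score (``z``).
    """
    if mode == "auto":
        if "r" in table.columns:
            return table["r"].to_numpy(dtype=np.float64)
        if "beta" in table.columns and "se" in table.columns:
            mode = "beta_se"
        elif "z" in table.columns:
            mode = "z"
        elif "p" in table.columns:
            mode = "p_sign"
        else:
            raise ConfigurationError("cannot infer correlation mode from available columns")
    n = table["n"].to_numpy(dtype=np.float64)
    if np.any(n <= 2):
        raise ValueError("per-SNP sample size must exceed 2")
    if mode == "beta_se":
        t = table["beta"].to_numpy(np.float64) / table["se"].to_numpy(np.float64)
    elif mode == "p_sign":
        p = table["p"].to_numpy(np.float64)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p values must lie in (0, 1]")
        if "sign" in table.columns:
            sgn = np.sign(table["sign"].to_numpy(np.float64))
        else:
            sgn = np.sign(table["beta"].to_numpy(np.float64))
        t = sgn * stats.norm.isf(p / 2.0)
    elif mode == "z":
        t = table["z"].to_numpy(np.float64)
    else:
        raise ConfigurationError(f"unknown correlation mode {mode!r}")
    return t / np.sqrt(n - 2.0 + t**2)


def harmonize(
    traits: list[pd.DataFrame],
    panel: LDBlockSet,
    drop_ambiguous: bool = True,
    trait_names: list[str] | None = None,
) -> tuple[SummaryStatistics, LDBlockSet]:
    """Intersect and allele-align trait tables with a reference panel.

    Each table needs columns ``snp, a1, a2, n`` and either a precomputed ``r``
    column or statistics usable by :func:`to_correlation`.  Effect signs are
    flipped when a trait's effect allele is the panel's non-counted allele;
    SNPs with mismatching allele pairs, and (by default) strand-ambiguous A/T
    and C/G SNPs, are dropped.  The output SNP order equals panel order and the
    returned block set is the panel restricted to the surviving SNPs.
    """
    if not traits:
        raise InputDataError("at least one trait table required")
    if trait_names is None:
        trait_names = [
            t.attrs.get("trait_label", f"trait{k + 1}") for k, t in enumerate(traits)
        ]
    gp = panel.panel
    keep = np.ones(gp.n_snps, dtype=bool)
    if drop_ambiguous:
        amb = gp.ambiguous_mask()
        if amb.any():
            logger.info("harmonize: dropping %d strand-ambiguous SNPs", int(amb.sum()))
        keep &= ~amb

    panel_a1 = np.char.upper(gp.a1.astype(str))
    panel_a2 = np.char.upper(gp.a2.astype(str))
    r_cols, n_per_trait = [], []
    for table in traits:
        dup = table["snp"].duplicated()
        if dup.any():
            logger.warning("harmonize: %d duplicated SNP ids in a trait, keeping first",
                           int(dup.sum()))
            table = table[~dup]
        r = to_correlation(table)
        lookup = pd.DataFrame(
            {
                "a1": np.char.upper(table["a1"].to_numpy(dtype=str)),
                "a2": np.char.upper(table["a2"].to_numpy(dtype=str)),
                "r": r,
                "n": table["n"].to_numpy(np.float64),
            },
            index=table["snp"].to_numpy(dtype=str),
        )
        aligned = lookup.reindex(gp.snp_ids.astype(str))
        present = aligned["r"].notna().to_numpy()
        same = (aligned["a1"].to_numpy() == panel_a1) & (aligned["a2"].to_numpy() == panel_a2)
        swapped = (aligned["a1"].to_numpy() == panel_a2) & (aligned["a2"].to_numpy() == panel_a1)
        mismatch = present & ~(same | swapped)
        if mismatch.any():
            logger.warning("harmonize: dropping %d SNPs with allele mismatch", int(mismatch.sum()))
        keep &= present & (same | swapped)
        r_aligned = aligned["r"].to_numpy(np.float64)
        r_aligned[swapped] = -r_aligned[swapped]
        r_cols.append(r_aligned)
        n_per_trait.append(aligned["n"].to_numpy(np.float64))

    if not keep.any():
        raise InputDataError("empty SNP intersection between traits and panel")
    idx = np.nonzero(keep)[0]
    r = np.column_stack([col[idx] for col in r_cols])
    n = np.array([int(round(np.nanmedian(col[idx]))) for col in n_per_trait])
    sub_blocks = panel.subset(keep)
    ss = SummaryStatistics(
        snp_ids=gp.snp_ids[idx],
        chrom=gp.chrom[idx],
        pos=gp.pos[idx],
        ref_allele=gp.a2[idx],
        alt_allele=gp.a1[idx],
        r=r,
        n=n,
        trait_names=list(trait_names),
    )
    return ss, sub_blocks


def pseudo_split(
    ss: SummaryStatistics,
    panel: LDBlockSet,
    nB_fraction: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    shared_g: bool = True,
) -> PseudoSplit:
    """Split full-sample correlations into pseudo training/validation parts.

    The validation size is ``nB = round(nB_fraction * mean_k n_k)`` and
    ``nA_k = n_k - nB``.  Training correlations are perturbed as

    ``rA_k = r_k + sqrt(nB / (nA_k n_k)) * s(r_k) * X_r' g / sqrt(n_r)``

    with ``g`` a standard normal draw over the ``n_r`` reference subjects
    (shared across traits by default, preserving cross-trait LD structure of
    the noise) and ``s(r_k)`` the empirical standard deviation of ``r_k``,
    giving the perturbation covariance ``(nB / (nA_k n_k)) s^2(r_k) R``.
    """
    n = ss.n.astype(np.float64)
    nB = int(round(nB_fraction * n.mean()))
    if nB <= 0:
        raise ValueError("nB_fraction too small: pseudo validation sample is empty")
    if nB >= n.min():
        raise ValueError("nB must be smaller than every trait's GWAS sample size")
    nA = ss.n - nB
    gp = panel.panel
    if gp.n_snps != ss.n_snps:
        raise InputDataError("panel and summary statistics are not aligned")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_r = gp.n_subjects
    q = ss.n_traits
    if shared_g:
        g = np.repeat(rng.standard_normal((n_r, 1)), q, axis=1)
    else:
        g = rng.standard_normal((n_r, q))
    xtg = np.empty((ss.n_snps, q))
    for a, b in panel.blocks:
        xtg[a:b] = panel.panel.standardized(a, b).T @ g
    xtg /= np.sqrt(n_r)
    s_r = ss.r.std(axis=0, ddof=1)
    scale = np.sqrt(nB / (nA.astype(np.float64) * n)) * s_r
    rA = ss.r + scale * xtg
    rB = (n * ss.r - nA * rA) / nB
    return PseudoSplit(rA=rA, rB=rB, nA=nA, nB=nB, seed=seed)


def write_pseudo_split(split: PseudoSplit, ss: SummaryStatistics, outdir: str | Path) -> None:
    """Serialize a pseudo split as two TSVs plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in (("rA", split.rA), ("rB", split.rB)):
        pd.DataFrame(mat, columns=ss.trait_names).assign(snp=ss.snp_ids).set_index(
            "snp"
        ).to_csv(outdir / f"{name}.tsv", sep="\t")
    with open(outdir / "pseudo_split.json", "w") as fh:
        json.dump(
            {"nA": split.nA.tolist(), "nB": split.nB, "seed": split.seed,
             "traits": ss.trait_names},
            fh,
            indent=2,
        )
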
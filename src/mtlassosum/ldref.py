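"""Reference genotype panels and block-wise linkage disequilibrium.

A :class:`GenotypePanel` holds hard-called genotypes from a reference cohort as
minor-allele counts ``w_ij`` in {0, 1, 2}.  Standardized genotypes are
``x_ij = (w_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))`` with ``p_j`` the empirical
frequency of the counted allele; columns are therefore exactly mean-zero while
their variance is 1 only under Hardy-Weinberg proportions.  Downstream code
never assumes unit variance: the solver uses the actual diagonal of the block
LD matrices.

SNPs are partitioned into contiguous LD blocks (either from an interval file in
the Berisa-Pickrell style or a fixed SNP-count window), and LD is summarized by
per-block correlation matrices ``R_l = X_l' X_l / n_r``.  Cross-block LD is
ignored by construction, following the Lassosum convention of region-wise LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputDataError

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> counted (A1) allele dosage; 0b01 is missing.
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def _byte_decode_table() -> np.ndarray:
    """256 x 4 lookup: one packed bed byte -> four A1-allele dosages."""
    table = np.empty((256, 4), dtype=np.int8)
    for b in range(256):
        for i in range(4):
            table[b, i] = _CODE_TO_DOSAGE[(b >> (2 * i)) & 0b11]
    return table


_DECODE = _byte_decode_table()


@dataclass
class GenotypePanel:
    """Reference genotypes, counted-allele dosages with no missing values.

    Parameters
    ----------
    genotypes
        ``(n_r, p)`` int8 array of counted-allele (minor-allele) dosages.
    snp_ids, chrom, pos, a1, a2
        Per-SNP metadata; ``a1`` is the counted allele, ``a2`` the other one.
    scale
        ``"maf"`` standardizes by ``sqrt(2 p (1 - p))`` (allele-frequency
        convention); ``"sd"`` by the empirical standard deviation, which makes
        block LD matrices exact Pearson correlations.
    """

    genotypes: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    scale: str = "maf"
    freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (subjects x SNPs) array")
        for name in ("snp_ids", "chrom", "pos", "a1", "a2"):
            setattr(self, name, np.asarray(getattr(self, name)))
            if getattr(self, name).shape[0] != self.genotypes.shape[1]:
                raise ValueError(f"{name} length does not match SNP count")
        if self.scale not in ("maf", "sd"):
            raise ValueError("scale must be 'maf' or 'sd'")
        self.freq = self.genotypes.mean(axis=0) / 2.0
        if np.any(self.freq <= 0.0) or np.any(self.freq >= 1.0):
            raise InputDataError("monomorphic SNPs must be removed before panel construction")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self, start: int = 0, stop: int | None = None) -> np.ndarray:
        """Standardized genotype columns for SNPs in ``[start, stop)``."""
        stop = self.n_snps if stop is None else stop
        w = self.genotypes[:, start:stop].astype(np.float64)
        p = self.freq[start:stop]
        centered = w - 2.0 * p
        if self.scale == "maf":
            denom = np.sqrt(2.0 * p * (1.0 - p))
        else:
            denom = w.std(axis=0, ddof=0)
            if np.any(denom == 0.0):
                raise InputDataError("zero-variance SNP column under sd scaling")
        return centered / denom

    def subset(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            genotypes=self.genotypes[:, index],
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            a1=self.a1[index],
            a2=self.a2[index],
            scale=self.scale,
        )

    def ambiguous_mask(self) -> np.ndarray:
        """Strand-ambiguous (A/T or C/G) SNPs."""
        out = np.zeros(self.n_snps, dtype=bool)
        for i in range(self.n_snps):
            pair = {str(self.a1[i]).upper(), str(self.a2[i]).upper()}
            out[i] = pair in AMBIGUOUS_PAIRS
        return out


def read_plink(
    prefix: str | Path,
    missing_max: float = 0.01,
    maf_min: float = 0.001,
    scale: str = "maf",
) -> GenotypePanel:
    """Load a PLINK 1 bed/bim/fam triple and apply standard QC.

    SNPs with a genotype missing rate above ``missing_max`` or a minor allele
    frequency below ``maf_min`` are removed; the small number of remaining
    missing genotypes is imputed with the per-SNP mode.  The counted allele is
    reoriented to the minor allele where needed.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    n_subjects = sum(1 for line in open(prefix.with_suffix(".fam")) if line.strip())
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed does not start with the PLINK bed magic bytes")
    p = len(bim)
    bytes_per_snp = (n_subjects + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != p * bytes_per_snp:
        raise FormatError(f"{prefix}.bed length inconsistent with bim/fam dimensions")
    geno = _DECODE[body.reshape(p, bytes_per_snp)].reshape(p, -1)[:, :n_subjects]

    missing = geno < 0
    miss_rate = missing.mean(axis=1)
    keep = miss_rate <= missing_max
    # allele frequency of the counted (A1) allele from observed genotypes
    with np.errstate(invalid="ignore"):
        f = np.where(missing, 0, geno).sum(axis=1) / (2.0 * (~missing).sum(axis=1))
    maf = np.minimum(f, 1.0 - f)
    keep &= maf >= max(maf_min, 1e-12)
    n_dropped = int(p - keep.sum())
    if n_dropped:
        logger.info("read_plink: dropped %d of %d SNPs in QC", n_dropped, p)
    if not keep.any():
        raise InputDataError("all SNPs removed by QC filters")

    geno = geno[keep]
    missing = missing[keep]
    # mode imputation over {0, 1, 2}
    for j in np.nonzero(missing.any(axis=1))[0]:
        obs = geno[j][~missing[j]]
        counts = np.bincount(obs, minlength=3)
        geno[j][missing[j]] = np.argmax(counts)
    # orient counted allele to the minor allele
    f = geno.sum(axis=1) / (2.0 * n_subjects)
    a1 = bim["a1"].to_numpy()[keep].copy()
    a2 = bim["a2"].to_numpy()[keep].copy()
    flip = f > 0.5
    if flip.any():
        geno[flip] = 2 - geno[flip]
        a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    return GenotypePanel(
        genotypes=np.ascontiguousarray(geno.T),
        snp_ids=bim["snp"].to_numpy()[keep],
        chrom=bim["chrom"].to_numpy()[keep],
        pos=bim["pos"].to_numpy()[keep],
        a1=a1,
        a2=a2,
        scale=scale,
    )


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1 bed/bim/fam triple (SNP-major bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = panel.genotypes.shape
    bim = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "snp": panel.snp_ids,
            "cm": 0,
            "pos": panel.pos,
            "a1": panel.a1,
            "a2": panel.a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            fh.write(f"F{i} I{i} 0 0 0 -9\n")
    dosage_to_code = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
    codes = dosage_to_code[panel.genotypes.T]  # (p, n)
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.full((p, pad), 0b11, dtype=np.uint8)])
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(p, -1, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


@dataclass
class LDBlockSet:
    """Contiguous LD blocks over a panel plus the regularization parameter s.

    ``blocks`` is an ordered list of half-open index ranges covering all SNPs.
    The regularized LD operator used by the solver is ``(1-s) R_l + s I`` per
    block, positive definite for any s in (0, 1].
    """

    panel: GenotypePanel
    blocks: list[tuple[int, int]]
    s: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.s <= 1.0:
            raise ValueError("s must be in (0, 1]")
        prev = 0
        for a, b in self.blocks:
            if a != prev or b <= a:
                raise ValueError("blocks must be disjoint, ordered, and cover all SNPs")
            prev = b
        if prev != self.panel.n_snps:
            raise ValueError("blocks must cover all SNPs")

    @property
    def n_snps(self) -> int:
        return self.panel.n_snps

    @property
    def snp_ids(self) -> np.ndarray:
        return self.panel.snp_ids

    @cached_property
    def ld(self) -> list[np.ndarray]:
        return block_ld(self.panel, self.blocks)

    def matvec(self, beta: np.ndarray) -> np.ndarray:
        """Block-diagonal application of the unregularized LD matrix."""
        beta = np.atleast_2d(np.asarray(beta, dtype=np.float64).T).T
        out = np.empty_like(beta)
        for (a, b), R in zip(self.blocks, self.ld):
            out[a:b] = R @ beta[a:b]
        return out

    def subset(self, keep: np.ndarray) -> "LDBlockSet":
        """Restrict to a boolean mask of SNPs, preserving block boundaries."""
        keep = np.asarray(keep, dtype=bool)
        new_panel = self.panel.subset(np.nonzero(keep)[0])
        new_blocks: list[tuple[int, int]] = []
        offset = 0
        for a, b in self.blocks:
            m = int(keep[a:b].sum())
            if m:
                new_blocks.append((offset, offset + m))
                offset += m
        return LDBlockSet(panel=new_panel, blocks=new_blocks, s=self.s)


def read_block_intervals(path: str | Path) -> pd.DataFrame:
    """Read a 3-column BED-like TSV of LD block intervals (0-based half-open)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError("block interval file needs chrom, start, end columns")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def partition_blocks(
    panel: GenotypePanel,
    intervals: pd.DataFrame | str | Path | None = None,
    window: int = 500,
    s: float = 0.5,
    strict: bool = False,
) -> LDBlockSet:
    """Partition the panel's SNPs into contiguous LD blocks.

    With ``intervals`` (chrom/start/end, 0-based half-open) each SNP is
    assigned by position; a SNP outside all intervals of its chromosome is
    assigned to the nearest interval with a warning unless ``strict``.  Without
    intervals a fixed window of ``window`` SNPs per block (within chromosome)
    is used, so no external block file is required.
    """
    chrom = panel.chrom.astype(str)
    pos = panel.pos.astype(np.int64)
    # require sorted positions within chromosome runs
    boundaries = np.nonzero(chrom[1:] != chrom[:-1])[0] + 1
    runs = np.split(np.arange(panel.n_snps), boundaries)
    for run in runs:
        if np.any(np.diff(pos[run]) < 0):
            raise InputDataError("SNPs must be position-sorted within chromosomes")

    blocks: list[tuple[int, int]] = []
    if intervals is None:
        for run in runs:
            for a in range(0, len(run), window):
                blocks.append((int(run[0] + a), int(run[0] + min(a + window, len(run)))))
    else:
        if not isinstance(intervals, pd.DataFrame):
            intervals = read_block_intervals(intervals)
        for run in runs:
            c = chrom[run[0]]
            iv = intervals[intervals["chrom"].astype(str) == c].sort_values("start")
            if iv.empty:
                raise InputDataError(f"no block intervals for chromosome {c}")
            starts = iv["start"].to_numpy()
            ends = iv["end"].to_numpy()
            idx = np.searchsorted(starts, pos[run], side="right") - 1
            outside = (idx < 0) | (pos[run] >= ends[np.clip(idx, 0, len(ends) - 1)])
            if outside.any():
                if strict:
                    raise InputDataError("SNP position outside all block intervals")
                logger.warning(
                    "partition_blocks: %d SNPs outside intervals assigned to nearest block",
                    int(outside.sum()),
                )
                # nearest interval by distance to its boundaries
                for i in np.nonzero(outside)[0]:
                    d = np.minimum(np.abs(starts - pos[run][i]), np.abs(ends - 1 - pos[run][i]))
                    idx[i] = int(np.argmin(d))
            # consecutive runs of identical interval index -> contiguous blocks
            change = np.nonzero(np.diff(idx))[0] + 1
            pieces = np.split(run, change)
            for piece in pieces:
                blocks.append((int(piece[0]), int(piece[-1] + 1)))
    return LDBlockSet(panel=panel, blocks=blocks, s=s)


def block_ld(panel: GenotypePanel, blocks: list[tuple[int, int]]) -> list[np.ndarray]:
    """Per-block LD matrices ``R_l = X_l' X_l / n_r`` on standardized genotypes."""
    out = []
    n = panel.n_subjects
    for a, b in blocks:
        X = panel.standardized(a, b)
        R = X.T @ X / n
        out.append(np.ascontiguousarray((R + R.T) / 2.0))
    return out
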
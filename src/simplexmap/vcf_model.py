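"""Reading VarScan-dialect VCFs into depth matrices, and the two hard filters.

The observable the whole pipeline works from is the per-genotype read-depth
triple written by VarScan: DP (quality read depth), RD (reference-supporting
depth) and AD (variant-supporting depth; scalar, not the array-valued
dialect). Genotype calls (GT) are ignored — allele dosage in a hexaploid is
inferred downstream from read counts, not from the caller's diploid GT.

Two hard filters are applied before any dosage work:
(i) per-cell depth of coverage >= min_depth (default 10) — failing cells are
    masked as missing;
(ii) per-locus proportion of missing data < max_missing (default 0.25) —
    loci at or above the bound are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DepthMatrix", "FilterCriteria", "read_vcf", "apply_depth_filter",
           "apply_missing_filter"]


@dataclass
class DepthMatrix:
    """Loci x individuals read-depth arrays with a missing mask.

    RD + AD <= DP is *not* enforced: VarScan's counts can disagree.
    ``loci`` columns: key, scaffold, pos, ref, alt.
    """

    loci: pd.DataFrame
    samples: list[str]
    dp: np.ndarray
    rd: np.ndarray
    ad: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        n = (len(self.loci), len(self.samples))
        for name in ("dp", "rd", "ad", "missing"):
            arr = getattr(self, name)
            if arr.shape != n:
                raise ValueError(f"{name} has shape {arr.shape}, expected {n}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dp.shape

    def subset_loci(self, idx: np.ndarray) -> "DepthMatrix":
        return DepthMatrix(
            loci=self.loci.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            dp=self.dp[idx], rd=self.rd[idx], ad=self.ad[idx],
            missing=self.missing[idx],
        )


@dataclass(frozen=True)
class FilterCriteria:
    """min_depth: per-cell DP floor (cells below are masked, inclusive keep at
    the floor); max_missing: per-locus missing-proportion bound (strict '<'
    keeps)."""

    min_depth: int = 10
    max_missing: float = 0.25

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0.0 < self.max_missing <= 1.0):
            raise ValueError("max_missing must be in (0, 1]")


def _format_field(variant, name: str, n_samples: int) -> np.ndarray | None:
    arr = variant.format(name)
    if arr is None:
        return None
    arr = np.asarray(arr).reshape(n_samples, -1)[:, 0]
    return arr


def read_vcf(path: str | Path) -> DepthMatrix:
    """Parse a VCF with DP/RD/AD genotype fields into a :class:`DepthMatrix`.

    Only biallelic SNP records are kept; multi-allelic records and indels are
    skipped with a logged warning. A cell is missing when any of its three
    depth fields is absent.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on malformed files
        raise ValueError(f"could not parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    fmt_ids = {h["ID"] for h in vcf.header_iter()
               if h.type == "FORMAT" and "ID" in h.info()}
    for req in ("DP", "RD", "AD"):
        if req not in fmt_ids:
            raise ValueError(f"VCF {path} lacks required FORMAT field {req}")

    loci_rows, dp_rows, rd_rows, ad_rows, miss_rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            logger.warning("skipping non-biallelic-SNP record %s:%s", v.CHROM, v.POS)
            continue
        dp = _format_field(v, "DP", n)
        rd = _format_field(v, "RD", n)
        ad = _format_field(v, "AD", n)
        miss = np.zeros(n, dtype=bool)
        cols = []
        for arr in (dp, rd, ad):
            if arr is None:
                miss[:] = True
                cols.append(np.zeros(n, dtype=np.int32))
            else:
                bad = (arr < 0) | (arr == np.iinfo(np.int32).min)
                miss |= bad
                cols.append(np.where(bad, 0, arr).astype(np.int32))
        key = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        loci_rows.append((key, v.CHROM, v.POS, v.REF, v.ALT[0]))
        dp_rows.append(cols[0])
        rd_rows.append(cols[1])
        ad_rows.append(cols[2])
        miss_rows.append(miss)
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP records in %s", n_skipped, path)

    loci = pd.DataFrame(loci_rows, columns=["key", "scaffold", "pos", "ref", "alt"])
    if loci["key"].duplicated().any():
        raise ValueError("duplicate locus keys in VCF")
    stack = (lambda rows, dt: np.asarray(rows, dtype=dt) if rows
             else np.zeros((0, n), dtype=dt))
    return DepthMatrix(
        loci=loci, samples=samples,
        dp=stack(dp_rows, np.int32), rd=stack(rd_rows, np.int32),
        ad=stack(ad_rows, np.int32), missing=stack(miss_rows, bool),
    )


def apply_depth_filter(matrix: DepthMatrix, criteria: FilterCriteria | None = None) -> DepthMatrix:
    """Mask every cell with DP below the floor. No loci are dropped here."""
    criteria = criteria or FilterCriteria()
    new_missing = matrix.missing | (matrix.dp < criteria.min_depth)
    return DepthMatrix(loci=matrix.loci, samples=matrix.samples,
                       dp=matrix.dp, rd=matrix.rd, ad=matrix.ad,
                       missing=new_missing)


def apply_missing_filter(
    matrix: DepthMatrix, criteria: FilterCriteria | None = None
) -> tuple[DepthMatrix, np.ndarray]:
    """Drop loci whose missing proportion is >= max_missing.

    Returns the filtered matrix and the integer index of kept loci (into the
    input's locus order, which is preserved).
    """
    criteria = criteria or FilterCriteria()
    frac = matrix.missing.mean(axis=1) if matrix.shape[1] else np.zeros(len(matrix.loci))
    kept = np.flatnonzero(frac < criteria.max_missing)
    return matrix.subset_loci(kept), kept
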
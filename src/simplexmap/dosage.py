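"""Allele-dosage work: AAF profiles, double-simplex selection, dichotomized
genotype calls and the 1:3 segregation test.

In an autohexaploid mapped against a haploid reference, a segregating SNP in
the selfed parent can carry 1..6 ALT alleles; the expected ALT-read fraction
(AAF = ALT / (REF + ALT) reads) of a locus is dosage/6, so the population
AAF histogram shows peaks at 1/6, 2/6, ... 6/6. Only *double-simplex* loci
(parent simplex for ALT or for REF) segregate in a tractable disomic-like
way in the S1, so selection keeps pooled AAF in [0.0833, 0.2500) (simplex
ALT, class ``ds-REF``: homozygous-REF individuals are the recessive class)
or [0.7500, 0.9167) (simplex REF, class ``ds-ALT``).

Per-individual read counts are too shallow to distinguish dosage 1 from 2,
so calls are dichotomized: for a ds-REF marker an individual with AAF = 0 is
"homozygous", anything with an ALT read is "not homozygous" (and mirrored
for ds-ALT), giving an expected 1:3 ratio tested by chi-square at alpha=0.01
(markers with p >= alpha are kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vcf_model import DepthMatrix

CALL_HOMO = 0
CALL_NOT_HOMO = 1
CALL_MISSING = -1

DS_REF = "ds-REF"   # AAAAAa x AAAAAa: simplex for ALT, recessive class = hom REF
DS_ALT = "ds-ALT"   # Aaaaaa x Aaaaaa: simplex for REF, recessive class = hom ALT

__all__ = [
    "AafProfile", "SelectionThresholds", "compute_aaf", "select_double_simplex",
    "dichotomize", "chi_square_1_3", "segregation_table",
    "CALL_HOMO", "CALL_NOT_HOMO", "CALL_MISSING", "DS_REF", "DS_ALT",
]


@dataclass
class AafProfile:
    """Pooled and per-individual ALT allele frequencies.

    pooled: (n_loci,) population-pooled AAF (NaN where no informative reads);
    per_individual: (n_loci, n_ind) AAF per cell (NaN for missing / zero
    reads); ref_total / alt_total: pooled read counts per locus.
    """

    pooled: np.ndarray
    per_individual: np.ndarray
    ref_total: np.ndarray
    alt_total: np.ndarray


@dataclass(frozen=True)
class SelectionThresholds:
    """Right-open pooled-AAF selection windows for the two double-simplex
    classes."""

    ds_ref_low: float = 0.0833
    ds_ref_high: float = 0.2500
    ds_alt_low: float = 0.7500
    ds_alt_high: float = 0.9167

    def __post_init__(self) -> None:
        w = (self.ds_ref_low, self.ds_ref_high, self.ds_alt_low, self.ds_alt_high)
        if not (0.0 <= w[0] < w[1] <= w[2] < w[3] <= 1.0):
            raise ValueError(f"selection windows must be disjoint within [0,1]: {w}")


def compute_aaf(matrix: DepthMatrix, denominator: str = "rd_ad") -> AafProfile:
    """Pooled and per-individual AAF from a (filtered) depth matrix.

    ``denominator`` selects ALT/(REF+ALT) reads (``"rd_ad"``, the default)
    or ALT/DP (``"dp"``).
    """
    if denominator not in ("rd_ad", "dp"):
        raise ValueError("denominator must be 'rd_ad' or 'dp'")
    valid = ~matrix.missing
    ad = np.where(valid, matrix.ad, 0).astype(np.float64)
    denom_cell = np.where(
        valid, matrix.rd + matrix.ad if denominator == "rd_ad" else matrix.dp, 0
    ).astype(np.float64)
    alt_total = ad.sum(axis=1)
    ref_total = np.where(valid, matrix.rd, 0).sum(axis=1).astype(np.float64)
    denom_total = denom_cell.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(denom_total > 0, alt_total / denom_total, np.nan)
        per_ind = np.where(denom_cell > 0, ad / denom_cell, np.nan)
    return AafProfile(pooled=pooled, per_individual=per_ind,
                      ref_total=ref_total, alt_total=alt_total)


def select_double_simplex(
    profile: AafProfile, thresholds: SelectionThresholds | None = None
) -> pd.DataFrame:
    """Label loci whose pooled AAF falls in a double-simplex window.

    Returns a frame with columns ``index`` (row in the profile), ``pooled_aaf``
    and ``marker_class`` (ds-REF / ds-ALT); everything outside the windows —
    including monomorphic-ALT loci at pooled AAF exactly 1 — is discarded.
    """
    t = thresholds or SelectionThresholds()
    aaf = profile.pooled
    with np.errstate(invalid="ignore"):
        is_ref = (aaf >= t.ds_ref_low) & (aaf < t.ds_ref_high)
        is_alt = (aaf >= t.ds_alt_low) & (aaf < t.ds_alt_high)
    idx = np.flatnonzero(is_ref | is_alt)
    labels = np.where(is_ref[idx], DS_REF, DS_ALT)
    return pd.DataFrame({"index": idx, "pooled_aaf": aaf[idx], "marker_class": labels})


def dichotomize(
    matrix: DepthMatrix,
    locus_index: np.ndarray,
    marker_class: np.ndarray,
    alt_read_tolerance: int = 0,
    denominator: str = "rd_ad",
) -> np.ndarray:
    """Dominant-style per-individual calls for selected double-simplex loci.

    ds-REF: individual AAF == 0 -> homozygous (0), > 0 -> not-homozygous (1);
    ds-ALT mirrored (AAF == 1 -> homozygous). Cells that are masked or have no
    informative reads are missing (-1). ``alt_read_tolerance`` treats up to
    that many minor-allele reads as zero (default 0 keeps the exact rule).

    Returns an int8 (n_selected, n_individuals) call matrix.
    """
    locus_index = np.asarray(locus_index)
    minor_ref = matrix.ad[locus_index]     # reads of the rare allele, ds-REF view
    minor_alt = matrix.rd[locus_index]
    denom = (matrix.rd + matrix.ad if denominator == "rd_ad" else matrix.dp)[locus_index]
    missing = matrix.missing[locus_index] | (denom <= 0)
    is_ref = np.asarray(marker_class) == DS_REF
    minor = np.where(is_ref[:, None], minor_ref, minor_alt)
    calls = np.where(minor <= alt_read_tolerance, CALL_HOMO, CALL_NOT_HOMO).astype(np.int8)
    calls[missing] = CALL_MISSING
    return calls


def chi_square_1_3(calls_row: np.ndarray, alpha: float = 0.01):
    """Test one marker's homozygous : not-homozygous counts against 1:3.

    Returns ``(n_homo, n_not_homo, chi2, p, keep)``; ``keep`` is True when
    p >= alpha. Raises on an all-missing marker.
    """
    n_homo = int(np.sum(calls_row == CALL_HOMO))
    n_not = int(np.sum(calls_row == CALL_NOT_HOMO))
    n = n_homo + n_not
    if n == 0:
        raise ValueError("degenerate marker: no non-missing calls")
    chi2, p = _chi2_1_3(np.array([n_homo]), np.array([n_not]))
    return n_homo, n_not, float(chi2[0]), float(p[0]), bool(p[0] >= alpha)


def _chi2_1_3(n_homo: np.ndarray, n_not: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = n_homo + n_not
    exp_h = n / 4.0
    exp_n = 3.0 * n / 4.0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n_homo - exp_h) ** 2 / exp_h + (n_not - exp_n) ** 2 / exp_n
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def segregation_table(
    calls: np.ndarray,
    selection: pd.DataFrame,
    loci: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Vectorized 1:3 test over all selected markers.

    Returns one row per selected marker: key, scaffold, pos, marker_class,
    pooled_aaf, n_homo, n_not_homo, chi2, p, kept. Markers with zero
    non-missing calls are reported with ``kept=False`` and reason 'all_missing'.
    """
    n_homo = (calls == CALL_HOMO).sum(axis=1)
    n_not = (calls == CALL_NOT_HOMO).sum(axis=1)
    n = n_homo + n_not
    chi2, p = _chi2_1_3(n_homo.astype(float), n_not.astype(float))
    kept = (n > 0) & (p >= alpha)
    sel_loci = loci.iloc[selection["index"].to_numpy()].reset_index(drop=True)
    return pd.DataFrame({
        "key": sel_loci["key"],
        "scaffold": sel_loci["scaffold"],
        "pos": sel_loci["pos"],
        "marker_class": selection["marker_class"].to_numpy(),
        "pooled_aaf": selection["pooled_aaf"].to_numpy(),
        "n_homo": n_homo,
        "n_not_homo": n_not,
        "chi2": np.where(n > 0, chi2, np.nan),
        "p": np.where(n > 0, p, np.nan),
        "kept": kept,
        "reason": np.where(n == 0, "all_missing", np.where(kept, "", "distorted")),
    })
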
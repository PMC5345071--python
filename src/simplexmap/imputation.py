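"""Map-order-based genotyping-error correction and missing-call imputation.

Sequencing-based genotype calls carry singleton errors that masquerade as
double crossovers; each 1% of marker error inflates a linkage map by roughly
2 cM, so cleaning is done *after* a first map exists and the cleaned calls
are mapped again.

The rule set here is deliberately conservative and auditable:

* correction never flips a call — a call that disagrees with both of its
  flanking co-segregation bins for the same individual (an apparent double
  recombinant), with at most ``max_error`` disagreements inside the local
  window, is set to missing;
* imputation fills a missing cell only when its nearest non-missing
  neighbours within ``window`` bins on each side agree;
* markers whose missing fraction exceeds ``max_missing_frac`` are ineligible
  and pass through untouched;
* co-segregation bins, not raw markers, are the positional unit (markers in
  a bin vote together), and every change is logged with provenance so the
  original matrix is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosage import CALL_MISSING
from .linkage import GeneticMap, GroupingParams, build_map

__all__ = ["ImputationParams", "CorrectionLog", "correct_errors",
           "impute_missing", "rerun_map"]


@dataclass(frozen=True)
class ImputationParams:
    """window: half-width in bins used for flank search and the error
    window; max_error: max disagreements tolerated inside the window for a
    singleton to be masked; max_missing_frac: eligibility ceiling on a
    marker's missing fraction (ineligible markers pass through)."""

    window: int = 2
    max_error: int = 1
    max_missing_frac: float = 0.33

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_error < 0:
            raise ValueError("max_error must be >= 0")


@dataclass
class CorrectionLog:
    """Per-cell provenance of every masked or imputed call."""

    entries: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    # (marker_row, individual, before, after, reason)

    @property
    def n_corrected(self) -> int:
        return sum(1 for e in self.entries if e[4] == "masked_singleton")

    @property
    def n_imputed(self) -> int:
        return sum(1 for e in self.entries if e[4] == "imputed_consensus")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["marker", "individual", "before", "after", "reason"])

    def undo(self, calls: np.ndarray) -> np.ndarray:
        """Recover the pre-correction matrix from the log."""
        out = calls.copy()
        for m, j, before, _after, _reason in reversed(self.entries):
            out[m, j] = before
        return out


def _bin_consensus(calls: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Majority call of a bin per individual (bins are identical pre-noise;
    majority makes the vote robust once errors have been injected)."""
    sub = calls[rows]
    n1 = (sub == 1).sum(axis=0)
    n0 = (sub == 0).sum(axis=0)
    cons = np.full(calls.shape[1], CALL_MISSING, dtype=np.int8)
    cons[n1 > n0] = 1
    cons[n0 > n1] = 0
    return cons


def correct_errors(
    calls: np.ndarray,
    genetic_map: GeneticMap,
    params: ImputationParams | None = None,
) -> tuple[np.ndarray, CorrectionLog]:
    """Mask apparent singleton double-recombinants along each ordered LG.

    For each individual, a bin call that disagrees with both flanking bins'
    (agreeing) calls, and is the sole disagreement within ``window`` bins to
    each side (``<= max_error``), is set to missing in every marker of the
    bin. Chain-end bins are left untouched (one-sided evidence only).
    """
    params = params or ImputationParams()
    out = calls.copy()
    log = CorrectionLog()
    n_ind = calls.shape[1]
    eligible = _eligible_markers(calls, params)
    for lg in genetic_map.lgs:
        n_bins = lg.n_bins
        if n_bins < 3:
            continue
        cons = np.stack([_bin_consensus(calls, rows) for rows in lg.marker_rows])
        for k in range(1, n_bins - 1):
            prev_c, cur_c, next_c = cons[k - 1], cons[k], cons[k + 1]
            flank_ok = (prev_c >= 0) & (next_c >= 0) & (prev_c == next_c)
            disagree = (cur_c >= 0) & flank_ok & (cur_c != prev_c)
            if not disagree.any():
                continue
            lo, hi = max(0, k - params.window), min(n_bins, k + params.window + 1)
            win = cons[lo:hi]
            ref = prev_c  # local consensus within the window
            n_dis = ((win >= 0) & (win != ref[None, :]) & (ref[None, :] >= 0)).sum(axis=0)
            to_mask = disagree & (n_dis <= params.max_error)
            for j in np.flatnonzero(to_mask):
                for m in lg.marker_rows[k]:
                    if not eligible[m] or out[m, j] == CALL_MISSING:
                        continue
                    log.entries.append((int(m), int(j), int(out[m, j]),
                                        CALL_MISSING, "masked_singleton"))
                    out[m, j] = CALL_MISSING
    return out, log


def _eligible_markers(calls: np.ndarray, params: ImputationParams) -> np.ndarray:
    miss_frac = (calls == CALL_MISSING).mean(axis=1)
    return miss_frac <= params.max_missing_frac


def impute_missing(
    calls: np.ndarray,
    genetic_map: GeneticMap,
    params: ImputationParams | None = None,
) -> tuple[np.ndarray, CorrectionLog]:
    """Fill missing cells whose nearest flanking bin calls agree.

    The search extends at most ``window`` bins to each side; a cell flanked
    by disagreeing calls (a crossover interval) stays missing, as do cells
    at group ends with only one-sided evidence.
    """
    params = params or ImputationParams()
    out = calls.copy()
    log = CorrectionLog()
    eligible = _eligible_markers(calls, params)
    for lg in genetic_map.lgs:
        n_bins = lg.n_bins
        if n_bins < 2:
            continue
        cons = np.stack([_bin_consensus(out, rows) for rows in lg.marker_rows])
        for k in range(n_bins):
            left = _nearest(cons, k, -1, params.window)
            right = _nearest(cons, k, +1, params.window)
            fill = (left >= 0) & (right >= 0) & (left == right)
            if not fill.any():
                continue
            for j in np.flatnonzero(fill):
                for m in lg.marker_rows[k]:
                    if not eligible[m] or out[m, j] != CALL_MISSING:
                        continue
                    log.entries.append((int(m), int(j), CALL_MISSING,
                                        int(left[j]), "imputed_consensus"))
                    out[m, j] = left[j]
    return out, log


def _nearest(cons: np.ndarray, k: int, step: int, window: int) -> np.ndarray:
    """Nearest non-missing bin consensus from bin k in one direction."""
    n_bins, n_ind = cons.shape
    found = np.full(n_ind, CALL_MISSING, dtype=np.int8)
    pos = k + step
    for _ in range(window):
        if pos < 0 or pos >= n_bins:
            break
        take = (found < 0) & (cons[pos] >= 0)
        found[take] = cons[pos][take]
        pos += step
    return found


def rerun_map(
    calls: np.ndarray,
    markers: pd.DataFrame,
    params: GroupingParams | None = None,
    map_function: str = "kosambi",
) -> GeneticMap:
    """Second grouping/ordering pass on the corrected+imputed call matrix
    (same parameters as the first pass unless overridden)."""
    return build_map(calls, markers, params=params, map_function=map_function)
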
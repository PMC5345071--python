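"""Two-point linkage, grouping, ordering and map distances for dichotomized
double-simplex markers in a selfed (S1) autohexaploid.

A double-simplex marker pair residing on one homolog segregates, after
dichotomization into homozygous (recessive, expected 1/4) versus
not-homozygous (dominant, 3/4) classes, exactly like a pair of dominant
markers in a diploid F2 under bivalent pairing. The two-point model is
therefore the dominant-x-dominant F2 likelihood:

    coupling  gametes: AB, ab at (1-r)/2;  Ab, aB at r/2
    repulsion gametes: Ab, aB at (1-r)/2;  AB, ab at r/2

and with q = (1-r)/2 (coupling) or q = r/2 (repulsion), the joint class
probabilities for two independent gametes are

    P(homo, homo) = q^2,   P(homo, not) = P(not, homo) = 1/4 - q^2,
    P(not, not)  = 1/2 + q^2.

The log-likelihood is concave in u = q^2, so the ML recombination fraction
has a closed form (root of a quadratic), clamped per phase; the LOD is the
log10 likelihood ratio against independence (r = 0.5, u = 1/16).

Pairs whose rare alleles sit on *different* homologs of one chromosome fit
the repulsion model only weakly (the best-fit association for unlinked-in-
coupling homologs corresponds to r ~ 0.4 and LOD well below typical
grouping thresholds), so single-linkage grouping at a stringent LOD splits
a hexaploid chromosome into one linkage group per homolog — six per
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dosage import CALL_HOMO, CALL_NOT_HOMO

LN10 = np.log(10.0)
_U_INDEP = 1.0 / 16.0  # u at r = 0.5

__all__ = [
    "TwoPointEstimate", "GroupingParams", "TwoPointTable", "LinkageGroup",
    "GeneticMap", "two_point", "two_point_table", "group_markers",
    "bin_cosegregating", "order_markers", "assign_cm", "map_distance",
    "build_map",
]


@dataclass(frozen=True)
class TwoPointEstimate:
    """Two-point result for one marker pair (1 = not-homozygous class)."""

    phase: str                  # "coupling" | "repulsion"
    r: float                    # ML recombination fraction in [0, 0.5]
    lod: float                  # log10 LR vs r = 0.5
    n11: int                    # both not-homozygous
    n10: int
    n01: int
    n00: int                    # both homozygous
    informative: bool = True

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class GroupingParams:
    lod_threshold: float = 7.0
    max_rf: float = 0.5
    min_group_size: int = 20       # markers, for the reported-group filter
    min_shared: int = 20           # shared non-missing individuals per pair

    def __post_init__(self) -> None:
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be > 0")


def _loglik_u(u: np.ndarray, n_hh: np.ndarray, n_c: np.ndarray, n_nn: np.ndarray) -> np.ndarray:
    """Dominant-F2 log-likelihood at u = q^2 (0 * log 0 := 0)."""
    u = np.asarray(u, dtype=np.float64)
    p_hh, p_c, p_nn = u, 0.25 - u, 0.5 + u
    out = np.zeros(np.broadcast(u, n_hh).shape, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        for n, p in ((n_hh, p_hh), (n_c, p_c), (n_nn, p_nn)):
            term = n * np.log(np.maximum(p, 0.0))
            out = out + np.where(np.broadcast_to(n, out.shape) > 0, term, 0.0)
    return out


def _mle_u(n_hh: np.ndarray, n_c: np.ndarray, n_nn: np.ndarray) -> np.ndarray:
    """Unconstrained maximizer of the concave log-likelihood on [0, 1/4].

    Stationary point solves  -N u^2 + b u + n_hh/8 = 0  with
    b = (n_nn - n_hh)/4 - n_c/2; concavity makes clamping to any
    sub-interval exact.
    """
    n_hh = np.asarray(n_hh, float)
    n_c = np.asarray(n_c, float)
    n_nn = np.asarray(n_nn, float)
    N = n_hh + n_c + n_nn
    a = -N
    b = (n_nn - n_hh) / 4.0 - n_c / 2.0
    c = n_hh / 8.0
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
        # a < 0: the larger root of the downward parabola derivative numerator
        u1 = (-b + disc) / (2.0 * a)
        u2 = (-b - disc) / (2.0 * a)
    cand = np.stack([np.clip(u1, 0.0, 0.25), np.clip(u2, 0.0, 0.25),
                     np.full_like(u1, 0.0), np.full_like(u1, 0.25)])
    cand = np.nan_to_num(cand, nan=_U_INDEP)
    ll = _loglik_u(cand, n_hh, n_c, n_nn)
    return np.take_along_axis(cand, np.argmax(ll, axis=0)[None], axis=0)[0]


def _phase_fits(n_hh, n_c, n_nn):
    """Per-phase clamped MLEs and log-likelihoods.

    coupling: u in [1/16, 1/4] (r = 1 - 2 sqrt(u));
    repulsion: u in [0, 1/16]  (r = 2 sqrt(u)).
    """
    u_hat = _mle_u(n_hh, n_c, n_nn)
    u_cpl = np.clip(u_hat, _U_INDEP, 0.25)
    u_rep = np.clip(u_hat, 0.0, _U_INDEP)
    ll_cpl = _loglik_u(u_cpl, n_hh, n_c, n_nn)
    ll_rep = _loglik_u(u_rep, n_hh, n_c, n_nn)
    r_cpl = 1.0 - 2.0 * np.sqrt(u_cpl)
    r_rep = 2.0 * np.sqrt(u_rep)
    return (u_cpl, r_cpl, ll_cpl), (u_rep, r_rep, ll_rep)


def two_point(calls_i: np.ndarray, calls_j: np.ndarray, min_shared: int = 20) -> TwoPointEstimate:
    """ML two-point estimate for one pair of dichotomized call vectors.

    Calls are int arrays with 0 = homozygous, 1 = not-homozygous, -1 missing.
    Pairs with fewer than ``min_shared`` shared non-missing individuals, or a
    degenerate margin (one marker all a single class among shared
    individuals), are flagged uninformative with r = 0.5, LOD = 0.
    """
    ci = np.asarray(calls_i)
    cj = np.asarray(calls_j)
    shared = (ci >= 0) & (cj >= 0)
    hi, ni = ci[shared] == CALL_HOMO, ci[shared] == CALL_NOT_HOMO
    hj, nj = cj[shared] == CALL_HOMO, cj[shared] == CALL_NOT_HOMO
    n00 = int(np.sum(hi & hj)); n01 = int(np.sum(hi & nj))
    n10 = int(np.sum(ni & hj)); n11 = int(np.sum(ni & nj))
    n = n00 + n01 + n10 + n11
    degenerate = (n00 + n01 == 0) or (n10 + n11 == 0) or (n00 + n10 == 0) or (n01 + n11 == 0)
    if n < min_shared or degenerate:
        return TwoPointEstimate("coupling", 0.5, 0.0, n11, n10, n01, n00,
                                informative=False)
    n_hh, n_c, n_nn = float(n00), float(n01 + n10), float(n11)
    (u_c, r_c, ll_c), (u_r, r_r, ll_r) = _phase_fits(n_hh, n_c, n_nn)
    ll0 = float(_loglik_u(np.float64(_U_INDEP), n_hh, n_c, n_nn))
    if ll_c >= ll_r:
        phase, r, ll = "coupling", float(r_c), float(ll_c)
    else:
        phase, r, ll = "repulsion", float(r_r), float(ll_r)
    lod = max((ll - ll0) / LN10, 0.0)
    return TwoPointEstimate(phase, r, lod, n11, n10, n01, n00)


@dataclass
class TwoPointTable:
    """All-pairs two-point results as dense square arrays (symmetric)."""

    r: np.ndarray           # ML recombination fraction at the ML phase
    lod: np.ndarray
    coupling: np.ndarray    # bool: ML phase is coupling
    n_shared: np.ndarray
    informative: np.ndarray

    def to_frame(self, keys) -> pd.DataFrame:
        iu = np.triu_indices(self.r.shape[0], k=1)
        keys = np.asarray(keys)
        return pd.DataFrame({
            "marker_i": keys[iu[0]], "marker_j": keys[iu[1]],
            "phase": np.where(self.coupling[iu], "coupling", "repulsion"),
            "r": self.r[iu], "LOD": self.lod[iu], "n": self.n_shared[iu],
        })


def two_point_table(calls: np.ndarray, min_shared: int = 20) -> TwoPointTable:
    """Vectorized two-point estimation over all marker pairs.

    Joint-class counts come from three matrix products on the 0/1 indicator
    matrices, so ~3,000 markers x 142 individuals runs in seconds.
    """
    H = (calls == CALL_HOMO).astype(np.float64)
    N = (calls == CALL_NOT_HOMO).astype(np.float64)
    n_hh = H @ H.T
    n_nn = N @ N.T
    hn = H @ N.T
    n_c = hn + hn.T
    n_sh = n_hh + n_nn + n_c
    (u_c, r_c, ll_c), (u_r, r_r, ll_r) = _phase_fits(n_hh, n_c, n_nn)
    ll0 = _loglik_u(np.float64(_U_INDEP), n_hh, n_c, n_nn)
    use_cpl = ll_c >= ll_r
    ll = np.where(use_cpl, ll_c, ll_r)
    r = np.where(use_cpl, r_c, r_r)
    lod = np.maximum((ll - ll0) / LN10, 0.0)
    marg_h_i = n_hh + hn       # marker i homozygous among shared individuals
    marg_n_i = n_nn + hn.T
    informative = (n_sh >= min_shared) & (marg_h_i > 0) & (marg_n_i > 0) \
        & (marg_h_i.T > 0) & (marg_n_i.T > 0)
    r = np.where(informative, r, 0.5)
    lod = np.where(informative, lod, 0.0)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return TwoPointTable(r=r, lod=lod, coupling=use_cpl,
                         n_shared=n_sh.astype(np.int64), informative=informative)


def group_markers(
    table: TwoPointTable,
    params: GroupingParams | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Single-linkage partition at ``LOD >= threshold`` and ``r <= max_rf``.

    ``weights`` gives the marker multiplicity of each node (e.g. bin sizes);
    group size is the weighted sum. Returns ``(labels, large, small)`` where
    labels is the component id per node and large/small split the components
    at ``min_group_size`` markers (small groups are reported, never dropped).
    Both lists are ordered by descending group size (ties: first node index).
    """
    params = params or GroupingParams()
    n = table.lod.shape[0]
    w = np.ones(n, dtype=np.int64) if weights is None else np.asarray(weights)
    adj = table.informative & (table.lod >= params.lod_threshold) & (table.r <= params.max_rf)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps = [np.flatnonzero(labels == k) for k in range(n_comp)]
    comps.sort(key=lambda idx: (-int(w[idx].sum()), int(idx[0])))
    large = [c for c in comps if w[c].sum() >= params.min_group_size]
    small = [c for c in comps if w[c].sum() < params.min_group_size]
    return labels, large, small


def bin_cosegregating(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group markers with byte-identical call vectors (missing pattern
    included) into co-segregation bins.

    Returns ``(bin_id per marker, representative row index per bin)``; bins
    are numbered in order of their first member.
    """
    _, first, inverse = np.unique(calls, axis=0, return_index=True, return_inverse=True)
    # renumber so bin ids follow first-occurrence order of the input
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[inverse], first[order]


def _objective(order: list[int], r: np.ndarray) -> float:
    o = np.asarray(order)
    return float(r[o[:-1], o[1:]].sum())


def order_markers(
    group: np.ndarray,
    table: TwoPointTable,
    keys=None,
    ripple_window: int = 4,
    max_passes: int = 20,
) -> np.ndarray:
    """Order the bins of one linkage group.

    Rapid-chain-delineation-style greedy: seed with the highest-LOD pair,
    repeatedly append the unplaced bin with the strongest LOD to either chain
    end, then polish by exhaustive permutation of every sliding window of
    ``ripple_window`` bins, minimizing the sum of adjacent recombination
    fractions. Ties break by higher LOD, then lower r, then marker key.
    Returns group-node indices in map order (orientation is arbitrary; a
    reversed chain scores identically).
    """
    from itertools import permutations

    group = np.asarray(group)
    m = len(group)
    if m == 1:
        return group.copy()
    if keys is None:
        keys = np.arange(table.r.shape[0]).astype(str)
    keys = np.asarray(keys)
    lod = table.lod[np.ix_(group, group)].copy()
    r = table.r[np.ix_(group, group)].copy()
    info = table.informative[np.ix_(group, group)]
    if m > 2 and not _connected(info & (lod > 0)):
        pass  # grouping guarantees connectivity at its threshold; tolerate here
    r = np.where(info, r, 0.5)
    np.fill_diagonal(lod, -np.inf)

    # seed pair: max LOD, tie -> lower r, then lexicographic keys
    iu = np.triu_indices(m, k=1)
    seed_rank = sorted(
        zip(iu[0], iu[1]),
        key=lambda ij: (-lod[ij], r[ij], str(keys[group[ij[0]]]), str(keys[group[ij[1]]])),
    )
    i0, j0 = seed_rank[0]
    chain = [int(i0), int(j0)]
    unplaced = set(range(m)) - set(chain)
    while unplaced:
        best = None
        for k in sorted(unplaced):
            for end, pos in ((chain[0], "head"), (chain[-1], "tail")):
                score = (-lod[k, end], r[k, end], str(keys[group[k]]), pos)
                if best is None or score < best[0]:
                    best = (score, k, pos)
        _, k, pos = best
        chain.insert(0, k) if pos == "head" else chain.append(k)
        unplaced.discard(k)

    # window ripple: local exhaustive permutation, objective = sum adjacent r
    w = min(ripple_window, m)
    perms = list(permutations(range(w)))
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for start in range(0, m - w + 1):
            base = _objective(chain, r)
            best_perm, best_val = None, base
            window = chain[start:start + w]
            for p in perms[1:]:
                trial = chain[:start] + [window[i] for i in p] + chain[start + w:]
                val = _objective(trial, r)
                if val < best_val - 1e-12:
                    best_val, best_perm = val, p
            if best_perm is not None:
                chain[start:start + w] = [window[i] for i in best_perm]
                improved = True
    return group[np.asarray(chain)]


def _connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def map_distance(r: np.ndarray | float, function: str = "kosambi",
                 r_cap: float = 0.4999) -> np.ndarray | float:
    """Recombination fraction -> cM. Kosambi: d = 25 ln((1+2r)/(1-2r));
    Haldane: d = -50 ln(1 - 2r). r is capped below 0.5 before transforming."""
    r = np.minimum(np.asarray(r, dtype=np.float64), r_cap)
    r = np.maximum(r, 0.0)
    if function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    elif function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        raise ValueError(f"unknown map function: {function}")
    return d if d.ndim else float(d)


def assign_cm(ordered: np.ndarray, table: TwoPointTable,
              map_function: str = "kosambi") -> np.ndarray:
    """Cumulative cM positions along an ordered chain of bins (starts at 0)."""
    ordered = np.asarray(ordered)
    if len(ordered) == 1:
        return np.zeros(1)
    r_adj = table.r[ordered[:-1], ordered[1:]]
    d = map_distance(r_adj, map_function)
    return np.concatenate([[0.0], np.cumsum(d)])


# ---------------------------------------------------------------------------
# assembled genetic map


@dataclass
class LinkageGroup:
    """One ordered linkage group. Arrays are bin-level and aligned."""

    lg_id: int
    bin_ids: np.ndarray          # ordered co-segregation bin ids
    bin_cm: np.ndarray           # cumulative cM per bin
    marker_rows: list[np.ndarray]  # per bin: row indices into the call matrix
    is_small: bool = False

    @property
    def n_markers(self) -> int:
        return int(sum(len(rows) for rows in self.marker_rows))

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    @property
    def length_cm(self) -> float:
        return float(self.bin_cm[-1]) if len(self.bin_cm) else 0.0


@dataclass
class GeneticMap:
    """Ordered linkage groups over a dichotomized call matrix."""

    lgs: list[LinkageGroup]
    bin_id: np.ndarray           # co-segregation bin per marker row
    params: GroupingParams
    map_function: str = "kosambi"

    @property
    def n_groups(self) -> int:
        return len(self.lgs)

    def large_groups(self) -> list[LinkageGroup]:
        return [lg for lg in self.lgs if not lg.is_small]

    @property
    def total_length_cm(self) -> float:
        return float(sum(lg.length_cm for lg in self.lgs if not lg.is_small))

    def to_table(self, markers: pd.DataFrame) -> pd.DataFrame:
        """Marker-level map table. ``markers`` supplies key/scaffold/pos rows
        aligned with the call matrix used to build the map."""
        rows = []
        for lg in self.lgs:
            for order_idx, (b, cm, mrows) in enumerate(
                    zip(lg.bin_ids, lg.bin_cm, lg.marker_rows)):
                for mi in sorted(mrows, key=lambda i: str(markers["key"].iloc[i])):
                    rows.append((lg.lg_id, order_idx, int(b), float(cm),
                                 markers["key"].iloc[mi],
                                 markers["scaffold"].iloc[mi],
                                 markers["pos"].iloc[mi], lg.is_small))
        return pd.DataFrame(rows, columns=["lg", "order_index", "bin", "cm",
                                           "key", "scaffold", "pos", "small_group"])


def build_map(
    calls: np.ndarray,
    markers: pd.DataFrame,
    params: GroupingParams | None = None,
    map_function: str = "kosambi",
) -> GeneticMap:
    """Full map construction: bin -> two-point -> group -> order -> cM.

    ``markers`` must align row-for-row with ``calls`` and carry a ``key``
    column used in ordering tie-breaks.
    """
    params = params or GroupingParams()
    bin_per_marker, rep_rows = bin_cosegregating(calls)
    rep_calls = calls[rep_rows]
    n_bins = len(rep_rows)
    bin_sizes = np.bincount(bin_per_marker, minlength=n_bins)
    table = two_point_table(rep_calls, min_shared=params.min_shared)
    _, large, small = group_markers(table, params, weights=bin_sizes)
    bin_keys = markers["key"].to_numpy()[rep_rows]

    marker_rows_by_bin = [np.flatnonzero(bin_per_marker == b) for b in range(n_bins)]
    lgs: list[LinkageGroup] = []
    for is_small, comps in ((False, large), (True, small)):
        for comp in comps:
            ordered = (order_markers(comp, table, keys=bin_keys)
                       if len(comp) > 1 else comp)
            cm = assign_cm(ordered, table, map_function)
            lgs.append(LinkageGroup(
                lg_id=-1, bin_ids=ordered, bin_cm=cm,
                marker_rows=[marker_rows_by_bin[b] for b in ordered],
                is_small=is_small,
            ))
    # provisional numbering: large groups first, by descending marker count
    lgs.sort(key=lambda lg: (lg.is_small, -lg.n_markers, int(lg.bin_ids[0])))
    for i, lg in enumerate(lgs):
        lg.lg_id = i + 1
    return GeneticMap(lgs=lgs, bin_id=bin_per_marker, params=params,
                      map_function=map_function)
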
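"""Two-point estimation, grouping, binning, ordering and map distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import simplexmap as sm
from simplexmap.linkage import GroupingParams, two_point_table, group_markers

from conftest import calls_from_depths


# ---------------------------------------------------------------------------
# independent oracle: joint class probabilities + brute-force grid search

def class_probs(r, phase):
    """Dominant x dominant F2 joint probabilities, written from the gamete
    model directly (independent of the package's parameterization)."""
    if phase == "coupling":
        g = {"AB": (1 - r) / 2, "ab": (1 - r) / 2, "Ab": r / 2, "aB": r / 2}
    else:
        g = {"AB": r / 2, "ab": r / 2, "Ab": (1 - r) / 2, "aB": (1 - r) / 2}
    p = np.zeros(4)  # [nn, nh, hn, hh] with h = double recessive at that locus
    for g1, p1 in g.items():
        for g2, p2 in g.items():
            homo1 = g1[0] == "a" and g2[0] == "a"
            homo2 = g1[1] == "b" and g2[1] == "b"
            p[(2 if homo1 else 0) + (1 if homo2 else 0)] += p1 * p2
    return {"nn": p[0], "nh": p[1], "hn": p[2], "hh": p[3]}


_GRID_CACHE = {}


def _phase_grid(phase, step):
    if (phase, step) not in _GRID_CACHE:
        rs = np.arange(0.0, 0.5 + step / 2, step)
        ps = np.empty((len(rs), 4))
        for i, r in enumerate(rs):
            d = class_probs(r, phase)
            ps[i] = [d["nn"], d["nh"], d["hn"], d["hh"]]
        with np.errstate(divide="ignore"):
            _GRID_CACHE[(phase, step)] = (rs, np.log(ps))
    return _GRID_CACHE[(phase, step)]


def grid_search(n11, n10, n01, n00, step=1e-4):
    best = (-np.inf, 0.5, "coupling")
    counts = np.array([n11, n10, n01, n00], dtype=float)
    for phase in ("coupling", "repulsion"):
        rs, logps = _phase_grid(phase, step)
        with np.errstate(invalid="ignore"):
            ll = np.where(counts > 0, counts * logps, 0.0).sum(axis=1)
        k = int(np.argmax(ll))
        if ll[k] > best[0]:
            best = (float(ll[k]), float(rs[k]), phase)
    return best


def sample_counts(rng, r, phase, n):
    d = class_probs(r, phase)
    draw = rng.multinomial(n, [d["nn"], d["nh"], d["hn"], d["hh"]])
    return int(draw[0]), int(draw[1]), int(draw[2]), int(draw[3])


def calls_from_counts(n11, n10, n01, n00):
    ci = np.array([1] * n11 + [1] * n10 + [0] * n01 + [0] * n00, dtype=np.int8)
    cj = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00, dtype=np.int8)
    return ci, cj


class TestTwoPoint:
    def test_ml_matches_grid_search_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            r = rng.uniform(0.0, 0.5)
            phase = rng.choice(["coupling", "repulsion"])
            n = int(rng.integers(30, 250))
            n11, n10, n01, n00 = sample_counts(rng, r, phase, n)
            est = sm.two_point(*calls_from_counts(n11, n10, n01, n00))
            if not est.informative:
                continue
            _, r_grid, _ = grid_search(n11, n10, n01, n00)
            assert abs(est.r - r_grid) <= 5e-4

    def test_perfect_cosegregation(self):
        ci = np.array([1] * 100 + [0] * 42, dtype=np.int8)
        est = sm.two_point(ci, ci.copy())
        assert est.phase == "coupling" and est.r == 0.0
        # closed-form LOD for identical vectors
        expected = 100 * np.log10((3 / 4) / (9 / 16)) + 42 * np.log10((1 / 4) / (1 / 16))
        assert est.lod == pytest.approx(expected, rel=1e-9)

    def test_exact_independence_proportions_give_r_half(self):
        # counts exactly at the r=0.5 class probabilities (9:3:3:1)/16
        est = sm.two_point(*calls_from_counts(90, 30, 30, 10))
        assert est.r == pytest.approx(0.5)
        assert est.lod == pytest.approx(0.0, abs=1e-9)

    def test_lod_nonnegative_property(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = rng.multinomial(140, [0.25, 0.25, 0.25, 0.25])
            est = sm.two_point(*calls_from_counts(*counts))
            assert est.lod >= 0.0

    def test_phase_flip_on_inverted_calls(self):
        rng = np.random.default_rng(8)
        n11, n10, n01, n00 = sample_counts(rng, 0.05, "coupling", 142)
        ci, cj = calls_from_counts(n11, n10, n01, n00)
        est = sm.two_point(ci, cj)
        est_inv = sm.two_point(ci, (1 - cj).astype(np.int8))
        assert est.phase == "coupling"
        assert est_inv.phase == "repulsion"

    def test_min_shared_floor_flags_uninformative(self):
        ci = np.array([1, 0, 1, 0, -1, -1], dtype=np.int8)
        est = sm.two_point(ci, ci, min_shared=20)
        assert not est.informative and est.lod == 0.0

    def test_degenerate_margin_flagged(self):
        ci = np.ones(50, dtype=np.int8)  # marker all one class
        cj = np.array([0, 1] * 25, dtype=np.int8)
        assert not sm.two_point(ci, cj, min_shared=20).informative

    def test_mean_r_recovery_in_coupling(self):
        rng = np.random.default_rng(99)
        ests = []
        for _ in range(500):
            counts = sample_counts(rng, 0.1, "coupling", 142)
            est = sm.two_point(*calls_from_counts(*counts))
            ests.append(est.r)
        assert np.mean(ests) == pytest.approx(0.1, abs=0.02)

    def test_unlinked_markers_rarely_reach_lod3(self):
        rng = np.random.default_rng(100)
        lods = []
        for _ in range(500):
            counts = sample_counts(rng, 0.5, "coupling", 142)
            lods.append(sm.two_point(*calls_from_counts(*counts)).lod)
        assert np.mean(np.array(lods) >= 3.0) <= 0.01

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(st.integers(0, 120), st.integers(0, 60),
                     st.integers(0, 60), st.integers(0, 60)))
    def test_vectorized_table_matches_single_pair(self, counts):
        n11, n10, n01, n00 = counts
        ci, cj = calls_from_counts(n11, n10, n01, n00)
        if len(ci) == 0:
            return
        table = two_point_table(np.vstack([ci, cj]), min_shared=1)
        est = sm.two_point(ci, cj, min_shared=1)
        if est.informative:
            assert table.r[0, 1] == pytest.approx(est.r, abs=1e-9)
            assert table.lod[0, 1] == pytest.approx(est.lod, abs=1e-7)
        else:
            assert not table.informative[0, 1]


class TestGroupingAndBins:
    def test_infinite_threshold_gives_singletons(self, small_map):
        _, calls, markers = small_map
        bins, reps = sm.bin_cosegregating(calls)
        table = two_point_table(calls[reps])
        _, large, small = group_markers(table, GroupingParams(lod_threshold=1e9))
        assert len(large) + len(small) == len(reps)

    def test_group_count_monotone_in_lod(self, small_map):
        _, calls, markers = small_map
        bins, reps = sm.bin_cosegregating(calls)
        sizes = np.bincount(bins, minlength=len(reps))
        table = two_point_table(calls[reps])
        counts = []
        for lod in range(3, 11):
            _, large, small = group_markers(
                table, GroupingParams(lod_threshold=float(lod)), weights=sizes)
            counts.append(len(large) + len(small))
        assert counts == sorted(counts)

    def test_partition_matches_true_homolog_lineages(self, small_founder, small_map):
        # 3 chromosomes x 6 homologs: grouping at LOD 7 must recover the 18
        # true (chromosome, homolog) lineages exactly
        gm, calls, markers = small_map
        truth_lineage = {}
        for row in small_founder.loci.itertuples():
            truth_lineage[row.key] = (row.chrom, next(iter(row.carriers)))
        table = gm.to_table(markers)
        assert gm.n_groups == 18
        for lg_id, grp in table.groupby("lg"):
            lineages = {truth_lineage[k] for k in grp["key"]}
            assert len(lineages) == 1

    def test_bins_require_identical_vectors_including_missing(self):
        calls = np.array([[1, 0, 1, -1],
                          [1, 0, 1, -1],
                          [1, 0, 1, 1],
                          [1, 0, 0, -1]], dtype=np.int8)
        bins, reps = sm.bin_cosegregating(calls)
        assert bins[0] == bins[1]
        assert len({bins[0], bins[2], bins[3]}) == 3

    def test_cosegregating_sim_loci_share_bins(self):
        founder = sm.simulate_founder(n_chrom=1, loci_per_homolog=3,
                                      chrom_length_cm=1e-9, seed=31)
        truth = sm.simulate_s1_population(founder, n_individuals=100, seed=32)
        dep = sm.simulate_read_depths(truth.attrs["dosage"],
                                      sm.ReadDepthModel(depth_mean=200), seed=33)
        from conftest import depth_matrix_from_sim
        dm = depth_matrix_from_sim(founder, dep, 100)
        calls, markers = calls_from_depths(dm)
        carrier = {row.key: next(iter(row.carriers))
                   for row in founder.loci.itertuples()}
        bins, _ = sm.bin_cosegregating(calls)
        by_homolog = {}
        for i, k in enumerate(markers["key"]):
            by_homolog.setdefault(carrier[k], set()).add(bins[i])
        assert all(len(b) == 1 for b in by_homolog.values())


class TestOrdering:
    def test_three_bin_additivity(self):
        # disagreements: 1-2 in 5 individuals, 2-3 in 5 others, 1-3 in all 10
        base = np.array([1] * 75 + [0] * 25, dtype=np.int8)
        m1 = base.copy()
        m2 = base.copy(); m2[:5] = 1 - m2[:5]
        m3 = m2.copy(); m3[5:10] = 1 - m3[5:10]
        calls = np.vstack([m1, m3, m2])  # middle marker listed last
        table = two_point_table(calls, min_shared=10)
        order = sm.order_markers(np.arange(3), table)
        assert order.tolist() in ([0, 2, 1], [1, 2, 0])

    def test_reversal_scores_identically(self, small_map):
        gm, calls, markers = small_map
        lg = gm.large_groups()[0]
        bins, reps = sm.bin_cosegregating(calls)
        table = two_point_table(calls[reps])
        o = lg.bin_ids
        fwd = table.r[o[:-1], o[1:]].sum()
        rev = table.r[o[::-1][:-1], o[::-1][1:]].sum()
        assert fwd == pytest.approx(rev)

    def test_order_recovery_against_truth(self, small_founder, small_map):
        from scipy.stats import spearmanr
        gm, calls, markers = small_map
        truth_cm = dict(zip(small_founder.loci["key"], small_founder.loci["cm"]))
        table = gm.to_table(markers)
        rhos = []
        for lg_id, grp in table.groupby("lg"):
            if grp["bin"].nunique() < 10:
                continue
            rho = spearmanr(grp["cm"], grp["key"].map(truth_cm)).statistic
            rhos.append(abs(rho))
        assert len(rhos) > 0
        assert np.min(rhos) >= 0.95


class TestMapDistance:
    def test_kosambi_values(self):
        assert sm.map_distance(0.0) == 0.0
        # closed form: 25 ln(1.2 / 0.8)
        assert sm.map_distance(0.1) == pytest.approx(25 * np.log(1.2 / 0.8))
        assert sm.map_distance(0.1) == pytest.approx(10.137, abs=1e-3)

    def test_haldane_alternative(self):
        assert sm.map_distance(0.1, "haldane") == pytest.approx(-50 * np.log(0.8))

    def test_r_capped_below_half(self):
        assert np.isfinite(sm.map_distance(0.5))

    def test_unknown_function_rejected(self):
        with pytest.raises(ValueError):
            sm.map_distance(0.1, "morgan")

    def test_group_length_is_sum_of_adjacent_distances(self, small_map):
        gm, calls, markers = small_map
        bins, reps = sm.bin_cosegregating(calls)
        table = two_point_table(calls[reps])
        lg = gm.large_groups()[0]
        d = sm.map_distance(table.r[lg.bin_ids[:-1], lg.bin_ids[1:]])
        assert lg.length_cm == pytest.approx(np.sum(d))
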
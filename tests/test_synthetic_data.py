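"""Simulator checks: meiosis genetics, depth model, and VCF round trip."""

import itertools

import numpy as np
import pandas as pd
import pytest

import simplexmap as sm
from simplexmap.synthetic_data import PLOIDY, SimDepths

from conftest import N_IND, depth_matrix_from_sim


class TestFounder:
    def test_simplex_mix_gives_single_carrier_everywhere(self, small_founder):
        assert all(len(c) == 1 for c in small_founder.loci["carriers"])
        # simplex carriers spread over all 6 homologs of every chromosome
        for c in range(small_founder.n_chrom):
            sub = small_founder.loci[small_founder.loci["chrom"] == c]
            assert {next(iter(s)) for s in sub["carriers"]} == set(range(PLOIDY))

    def test_hexaploid_chromosome_count(self):
        founder = sm.simulate_founder(n_chrom=15, loci_per_homolog=2, seed=5)
        lineages = {(c, h) for c in range(founder.n_chrom) for h in range(PLOIDY)}
        assert len(lineages) == 90  # 2n = 6x = 90

    def test_determinism(self):
        a = sm.simulate_founder(n_chrom=2, loci_per_homolog=5, seed=42)
        b = sm.simulate_founder(n_chrom=2, loci_per_homolog=5, seed=42)
        pd.testing.assert_frame_equal(a.loci, b.loci)
        pd.testing.assert_frame_equal(a.scaffolds, b.scaffolds)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sm.simulate_founder(n_chrom=0)
        with pytest.raises(ValueError):
            sm.simulate_founder(loci_per_homolog=0)
        with pytest.raises(ValueError):
            sm.simulate_founder(chrom_length_cm=-1.0)
        with pytest.raises(ValueError):
            sm.simulate_founder(dosage_class_mix=np.array([0.5, 0.5, 0, 0, 0, 0.5]))

    def test_scaffolds_partition_each_chromosome(self, small_founder):
        for c, grp in small_founder.scaffolds.groupby("chrom"):
            segs = grp.sort_values("start")
            assert segs["start"].iloc[0] == 0
            assert segs["end"].iloc[-1] == small_founder.chrom_length_bp
            assert (segs["end"].to_numpy()[:-1] == segs["start"].to_numpy()[1:]).all()
            assert (segs["length"] > 0).all()

    def test_genetic_positions_strictly_increasing(self, small_founder):
        for c, grp in small_founder.loci.groupby("chrom"):
            assert np.all(np.diff(grp["cm"].to_numpy()) > 0)


class TestMeiosis:
    def test_homolog_marginal_transmission_is_half(self, small_founder):
        # over many gametes each homolog appears at a locus position with p=1/2
        alt, hom = sm.simulate_gametes(small_founder, chrom=0, n_gametes=10_000,
                                       rng=7)
        at_first_locus = hom[:, :, 0]  # (gametes, 3 strands)
        freqs = np.bincount(at_first_locus.ravel(), minlength=PLOIDY) / 10_000
        assert np.allclose(freqs, 0.5, atol=0.02)

    def test_cross_homolog_cotransmission_matches_enumeration(self, small_founder):
        # oracle: enumerate the 15 perfect pairings of 6 homologs; with no
        # recombination a gamete carries both of two marked homologs only
        # when they sit in different bivalents (each then transmitted w.p. 1/2)
        homs = list(range(PLOIDY))
        pairings = []

        def enumerate_pairings(rest):
            if not rest:
                return [[]]
            a = rest[0]
            out = []
            for b in rest[1:]:
                remaining = [x for x in rest if x not in (a, b)]
                for tail in enumerate_pairings(remaining):
                    out.append([(a, b)] + tail)
            return out

        pairings = enumerate_pairings(homs)
        assert len(pairings) == 15
        marked = (0, 3)
        p_both = 0.0
        for pairing in pairings:
            together = any(set(pair) == set(marked) for pair in pairing)
            p_both += 0.0 if together else 0.25
        p_both /= len(pairings)
        assert p_both == pytest.approx(1 / 5)

        # empirical check at short distance: the first loci carried by
        # homologs 0 and 3 of chromosome 0 sit ~2.5 cM apart in this founder
        loci0 = small_founder.loci[small_founder.loci["chrom"] == 0]
        carrier = np.array([next(iter(c)) for c in loci0["carriers"]])
        i0 = int(np.flatnonzero(carrier == marked[0])[0])
        i3 = int(np.flatnonzero(carrier == marked[1])[0])
        alt, _ = sm.simulate_gametes(small_founder, 0, 20_000, rng=8)
        both = ((alt[:, i0] > 0) & (alt[:, i3] > 0)).mean()
        assert both == pytest.approx(p_both, abs=0.02)

    def test_simplex_s1_segregates_1_2_1(self, small_truth):
        d = small_truth.attrs["dosage"]
        assert set(np.unique(d)) <= {0, 1, 2}
        frac0 = (d == 0).mean()
        # pooled over 360 loci x 142 individuals the binomial CI is tight
        assert frac0 == pytest.approx(0.25, abs=0.01)

    def test_zero_distance_coupled_loci_cosegregate(self):
        founder = sm.simulate_founder(n_chrom=1, loci_per_homolog=2,
                                      chrom_length_cm=1e-9, seed=9)
        carrier = np.array([next(iter(c)) for c in founder.loci["carriers"]])
        truth = sm.simulate_s1_population(founder, n_individuals=500, seed=10)
        d = truth.attrs["dosage"]
        same = np.flatnonzero(carrier == carrier[0])
        assert np.array_equal(d[same[0]], d[same[1]])


class TestReadDepths:
    def test_pure_dosage_extremes(self):
        d = np.array([[0] * 50, [6] * 50])
        dep = sm.simulate_read_depths(d, sm.ReadDepthModel(error_rate=0.0), seed=1)
        assert (dep.ad[0] == 0).all()
        assert (dep.rd[1] == 0).all()

    @pytest.mark.parametrize("dosage", range(1, 7))
    def test_pooled_alt_fraction_concentrates_at_d_over_6(self, dosage):
        d = np.full((40, 200), dosage)
        dep = sm.simulate_read_depths(d, sm.ReadDepthModel(depth_mean=120), seed=dosage)
        aaf = dep.ad.sum() / (dep.rd.sum() + dep.ad.sum())
        assert aaf == pytest.approx(dosage / 6, abs=0.005)

    def test_error_rate_validation(self):
        with pytest.raises(ValueError):
            sm.ReadDepthModel(error_rate=0.5)
        with pytest.raises(ValueError):
            sm.ReadDepthModel(error_rate=-0.01)

    def test_missing_rate_applies(self):
        d = np.full((50, 100), 1)
        dep = sm.simulate_read_depths(d, sm.ReadDepthModel(missing_rate=0.2), seed=3)
        assert dep.missing.mean() == pytest.approx(0.2, abs=0.03)

    def test_dosage_range_enforced(self):
        with pytest.raises(ValueError):
            sm.simulate_read_depths(np.array([[7]]), sm.ReadDepthModel(), seed=0)


class TestVcfRoundTrip:
    def test_write_read_recovers_depths(self, small_founder, small_depths, tmp_path):
        path = sm.write_vcf(small_depths, small_founder.loci,
                            small_founder.scaffolds, tmp_path / "pop.vcf")
        dm = sm.read_vcf(path)
        assert dm.shape == small_depths.dp.shape
        # align by locus key: the writer sorts by scaffold/position
        key_to_row = {k: i for i, k in enumerate(small_founder.loci["key"])}
        src = np.array([key_to_row[k] for k in dm.loci["key"]])
        assert np.array_equal(dm.dp, small_depths.dp[src])
        assert np.array_equal(dm.rd, small_depths.rd[src])
        assert np.array_equal(dm.ad, small_depths.ad[src])
        assert np.array_equal(dm.missing, small_depths.missing[src])
        assert (dm.loci["pos"] >= 1).all()

    def test_missing_cells_round_trip(self, small_founder, tmp_path):
        rng = np.random.default_rng(4)
        n = small_founder.n_loci
        dep = sm.simulate_read_depths(
            rng.integers(0, 3, size=(n, 10)),
            sm.ReadDepthModel(missing_rate=0.3), seed=5)
        path = sm.write_vcf(dep, small_founder.loci, small_founder.scaffolds,
                            tmp_path / "m.vcf")
        dm = sm.read_vcf(path)
        assert dm.missing.sum() == dep.missing.sum()

    def test_unwritable_path_names_file(self, small_founder, small_depths):
        with pytest.raises(OSError, match="no/such/dir"):
            sm.write_vcf(small_depths, small_founder.loci,
                         small_founder.scaffolds, "/no/such/dir/x.vcf")


def test_inject_call_errors_leaves_missing_untouched():
    rng = np.random.default_rng(0)
    calls = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(100, 50))
    out = sm.inject_call_errors(calls, 0.1, seed=1)
    assert np.array_equal(out == -1, calls == -1)
    changed = (out != calls).mean()
    assert 0.03 < changed < 0.12  # ~10% of the ~2/3 non-missing cells
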
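import numpy as np
import pandas as pd
import pytest

from simplexmap.vcf_model import DepthMatrix
import simplexmap as sm

N_IND = 142


def depth_matrix_from_sim(founder, depths, n_ind):
    """Bypass the VCF round trip: wrap simulated depths directly."""
    loci = founder.loci[["key", "scaffold", "pos"]].copy()
    loci["ref"] = "A"
    loci["alt"] = "G"
    return DepthMatrix(
        loci=loci.reset_index(drop=True),
        samples=[f"S1_{i + 1:03d}" for i in range(n_ind)],
        dp=depths.dp, rd=depths.rd, ad=depths.ad, missing=depths.missing,
    )


def calls_from_depths(dm, alpha=0.01):
    """Standard filter -> select -> dichotomize -> 1:3 chain."""
    dm = sm.apply_depth_filter(dm)
    dm, _ = sm.apply_missing_filter(dm)
    prof = sm.compute_aaf(dm)
    sel = sm.select_double_simplex(prof)
    calls = sm.dichotomize(dm, sel["index"].to_numpy(), sel["marker_class"].to_numpy())
    seg = sm.segregation_table(calls, sel, dm.loci, alpha=alpha)
    keep = seg["kept"].to_numpy()
    return calls[keep], seg[seg["kept"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_founder():
    # 3 chromosomes x 6 homologs x 20 simplex loci, 100 cM each:
    # dense enough for near-error-free ordering, small enough to stay fast
    return sm.simulate_founder(n_chrom=3, loci_per_homolog=20, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_founder):
    return sm.simulate_s1_population(small_founder, n_individuals=N_IND, seed=102)


@pytest.fixture(scope="session")
def small_depths(small_truth):
    return sm.simulate_read_depths(small_truth.attrs["dosage"],
                                   sm.ReadDepthModel(), seed=103)


@pytest.fixture(scope="session")
def small_dm(small_founder, small_depths):
    return depth_matrix_from_sim(small_founder, small_depths, N_IND)


@pytest.fixture(scope="session")
def small_calls(small_dm):
    return calls_from_depths(small_dm)


@pytest.fixture(scope="session")
def small_map(small_calls):
    calls, markers = small_calls
    gm = sm.build_map(calls, markers)
    return gm, calls, markers


@pytest.fixture(scope="session")
def dense_founder():
    # 2 chromosomes, 60 loci per homolog over 60 cM: ~1 cM (r ~ 0.01)
    # between adjacent markers of a homolog — the dense-map regime the
    # correction/imputation guarantees assume
    return sm.simulate_founder(n_chrom=2, loci_per_homolog=60,
                               chrom_length_cm=60.0, seed=201)


@pytest.fixture(scope="session")
def dense_truth(dense_founder):
    return sm.simulate_s1_population(dense_founder, n_individuals=N_IND, seed=202)


@pytest.fixture(scope="session")
def dense_map(dense_founder, dense_truth):
    dep = sm.simulate_read_depths(dense_truth.attrs["dosage"],
                                  sm.ReadDepthModel(), seed=203)
    dm = depth_matrix_from_sim(dense_founder, dep, N_IND)
    calls, markers = calls_from_depths(dm)
    gm = sm.build_map(calls, markers)
    return gm, calls, markers


def tiny_depth_matrix(dp, rd, ad, missing=None):
    """Hand-built DepthMatrix for boundary tests; arrays are (loci, ind)."""
    dp = np.atleast_2d(np.asarray(dp, dtype=np.int32))
    rd = np.atleast_2d(np.asarray(rd, dtype=np.int32))
    ad = np.atleast_2d(np.asarray(ad, dtype=np.int32))
    if missing is None:
        missing = np.zeros_like(dp, dtype=bool)
    else:
        missing = np.atleast_2d(np.asarray(missing, dtype=bool))
    n_loci, n_ind = dp.shape
    loci = pd.DataFrame({
        "key": [f"m{i}" for i in range(n_loci)],
        "scaffold": [f"sc{i}" for i in range(n_loci)],
        "pos": np.arange(1, n_loci + 1),
        "ref": "A", "alt": "G",
    })
    return DepthMatrix(loci=loci, samples=[f"I{j}" for j in range(n_ind)],
                       dp=dp, rd=rd, ad=ad, missing=missing)
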
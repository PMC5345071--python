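"""Reference study configurations: canned simulation-plus-analysis runs.

These bundle the package's standard verification scenarios — the
15-chromosome hexaploid S1 design (142 individuals, 30 evenly spaced
simplex loci per homolog, 100 cM chromosomes, deep error-free ddRAD
depths) and a smaller error-injection scenario — so tests, example scripts
and the reproduction script all execute the identical conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .vcf_model import DepthMatrix, apply_depth_filter, apply_missing_filter
from .dosage import compute_aaf, select_double_simplex, dichotomize, segregation_table
from .linkage import GroupingParams, build_map
from .imputation import correct_errors, impute_missing, rerun_map
from .hg_assign import build_incidence, cluster_hgs, number_groups

__all__ = ["hexaploid_s1_study", "StudyResult", "error_injection_study"]


@dataclass
class StudyResult:
    founder: "sd.FounderGenome"
    truth: pd.DataFrame
    calls: np.ndarray
    markers: pd.DataFrame
    genetic_map: object
    map_table: pd.DataFrame
    partition: object | None = None


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def hexaploid_s1_study(
    seed: int,
    n_chrom: int = 15,
    loci_per_homolog: int = 30,
    n_individuals: int = 142,
    depth_mean: float = 80.0,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    lod: float = 7.0,
    via_vcf: bool = True,
    tmp_dir=None,
    with_hg: bool = True,
) -> StudyResult:
    """Simulate the standard hexaploid S1 design and map it end to end.

    With ``via_vcf`` the depth layer makes a full round trip through the
    VarScan-dialect VCF writer and reader (requires ``tmp_dir``); otherwise
    the depth arrays are wrapped directly.
    """
    s_founder, s_pop, s_depth = _child_seeds(seed, 3)
    founder = sd.simulate_founder(n_chrom=n_chrom, loci_per_homolog=loci_per_homolog,
                                  seed=s_founder)
    truth = sd.simulate_s1_population(founder, n_individuals=n_individuals,
                                      seed=s_pop)
    model = sd.ReadDepthModel(depth_mean=depth_mean, error_rate=error_rate,
                              missing_rate=missing_rate)
    depths = sd.simulate_read_depths(truth.attrs["dosage"], model, seed=s_depth)

    if via_vcf:
        from pathlib import Path
        from .vcf_model import read_vcf
        if tmp_dir is None:
            raise ValueError("via_vcf requires tmp_dir")
        path = sd.write_vcf(depths, founder.loci, founder.scaffolds,
                            Path(tmp_dir) / "population.vcf")
        dm = read_vcf(path)
    else:
        loci = founder.loci[["key", "scaffold", "pos"]].copy()
        loci["ref"] = "A"
        loci["alt"] = "G"
        dm = DepthMatrix(loci=loci.reset_index(drop=True),
                         samples=[f"S1_{i + 1:03d}" for i in range(n_individuals)],
                         dp=depths.dp, rd=depths.rd, ad=depths.ad,
                         missing=depths.missing)

    dm = apply_depth_filter(dm)
    dm, _ = apply_missing_filter(dm)
    profile = compute_aaf(dm)
    selection = select_double_simplex(profile)
    calls = dichotomize(dm, selection["index"].to_numpy(),
                        selection["marker_class"].to_numpy())
    seg = segregation_table(calls, selection, dm.loci)
    keep = seg["kept"].to_numpy()
    calls = calls[keep]
    markers = seg[seg["kept"]].reset_index(drop=True)

    gm = build_map(calls, markers, params=GroupingParams(lod_threshold=lod))
    tab = gm.to_table(markers)
    partition = None
    if with_hg:
        incidence = build_incidence(tab[~tab["small_group"]])
        partition = cluster_hgs(incidence)
        partition = number_groups(partition, tab[~tab["small_group"]])
    return StudyResult(founder=founder, truth=truth, calls=calls,
                       markers=markers, genetic_map=gm, map_table=tab,
                       partition=partition)


def error_injection_study(seed: int, error_rate: float = 0.01,
                          n_chrom: int = 5) -> dict:
    """Scaled-down map-inflation scenario: build a clean map, inject call
    errors, map again, correct + impute, and map a third time.

    Returns pass-1 (with errors) and pass-2 (cleaned) total lengths plus the
    clean-data baseline.
    """
    s_study, s_inject = _child_seeds(seed, 2)
    clean = hexaploid_s1_study(s_study, n_chrom=n_chrom, via_vcf=False,
                               with_hg=False)
    noisy = sd.inject_call_errors(clean.calls, error_rate, seed=s_inject)
    gm1 = build_map(noisy, clean.markers,
                    params=GroupingParams(lod_threshold=7.0))
    corrected, _ = correct_errors(noisy, gm1)
    imputed, _ = impute_missing(corrected, gm1)
    gm2 = rerun_map(imputed, clean.markers,
                    params=GroupingParams(lod_threshold=7.0))
    return {
        "clean_length_cm": clean.genetic_map.total_length_cm,
        "pass1_length_cm": gm1.total_length_cm,
        "pass2_length_cm": gm2.total_length_cm,
        "n_markers": int(clean.calls.shape[0]),
    }
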
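"""End-to-end orchestration: VCF -> filters -> dosage -> map -> impute ->
remap -> homologous groups, with summary tables and a reproducibility
manifest.

Every stage writes plain tab-separated outputs with header comments naming
units (1-based bp, cM, right-open AAF windows), and the manifest records the
marker attrition at each step so every reported number is traceable to a
stage file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .vcf_model import DepthMatrix, FilterCriteria, read_vcf, apply_depth_filter, \
    apply_missing_filter
from .dosage import (SelectionThresholds, compute_aaf, select_double_simplex,
                     dichotomize, segregation_table)
from .linkage import GroupingParams, GeneticMap, build_map, two_point_table, \
    bin_cosegregating, group_markers
from .imputation import ImputationParams, correct_errors, impute_missing, rerun_map
from .hg_assign import build_incidence, cluster_hgs, number_groups, hg_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report_tables",
           "lod_sweep"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published protocol values
    (depth >= 10, missing < 0.25, AAF windows 0.0833-0.2500 / 0.7500-0.9167,
    segregation P >= 0.01, grouping LOD 7 with >= 20 SNPs reported,
    imputation missing ceiling 33%)."""

    vcf: str | None = None
    scaffold_table: str | None = None
    out_dir: str = "simplexmap_out"
    seed: int = 0
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    alpha: float = 0.01
    grouping: GroupingParams = field(default_factory=GroupingParams)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    map_function: str = "kosambi"
    aaf_denominator: str = "rd_ad"
    min_shared_scaffolds: int = 2
    hg_ploidy: int = 6
    skip_imputation: bool = False

    def set(self, key: str, value: str) -> None:
        """Dotted ``--set key=value`` override, e.g. ``grouping.lod_threshold=5``."""
        parts = key.split(".")
        chain = [self]
        for p in parts[:-1]:
            chain.append(getattr(chain[-1], p))
        obj = chain[-1]
        current = getattr(obj, parts[-1])
        cast = type(current) if current is not None else str
        if cast is bool:
            value = value.lower() in ("1", "true", "yes")
        else:
            value = cast(value)
        # frozen stage configs are rebuilt via dataclasses.replace
        if dataclasses.is_dataclass(obj) and type(obj).__dataclass_params__.frozen:
            rebuilt = dataclasses.replace(obj, **{parts[-1]: value})
            setattr(chain[-2], parts[-2], rebuilt)
        else:
            setattr(obj, parts[-1], value)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    manifest: dict
    map_table: pd.DataFrame | None = None
    hg: pd.DataFrame | None = None
    genetic_map: GeneticMap | None = None
    calls: np.ndarray | None = None
    markers: pd.DataFrame | None = None


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured VCF; returns the result bundle and
    writes all stage outputs plus ``manifest.yaml`` under ``out_dir``.

    Aborts with a stage-named RuntimeError if a stage empties the marker set
    (partial outputs are retained on disk).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "simplexmap", "version": __version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    if config.vcf is None:
        raise ValueError("config.vcf is required (run the simulator first)")
    manifest["inputs"]["vcf"] = {"path": str(config.vcf), "sha256": _checksum(config.vcf)}
    if config.scaffold_table:
        manifest["inputs"]["scaffold_table"] = {
            "path": str(config.scaffold_table), "sha256": _checksum(config.scaffold_table)}

    stage = "read_vcf"
    try:
        dm = read_vcf(config.vcf)
        manifest["stages"]["read_vcf"] = {"n_loci": dm.shape[0], "n_individuals": dm.shape[1]}

        stage = "filter"
        dm = apply_depth_filter(dm, config.filter)
        dm, kept = apply_missing_filter(dm, config.filter)
        manifest["stages"]["filter"] = {"n_loci_kept": int(len(kept))}
        _write_tsv(dm.loci[["key", "scaffold", "pos"]], out / "kept_loci.tsv",
                   "candidate SNP loci after depth>= and missing< filters; pos is 1-based bp")
        if dm.shape[0] == 0:
            raise RuntimeError("no loci survive the depth/missing filters")

        stage = "select"
        profile = compute_aaf(dm, denominator=config.aaf_denominator)
        selection = select_double_simplex(profile, config.thresholds)
        manifest["stages"]["select"] = {
            "n_candidates": int(len(selection)),
            "n_ds_ref": int((selection["marker_class"] == "ds-REF").sum()),
            "n_ds_alt": int((selection["marker_class"] == "ds-ALT").sum()),
        }
        if len(selection) == 0:
            raise RuntimeError("no double-simplex candidates in the AAF windows")

        stage = "segregation"
        calls = dichotomize(dm, selection["index"].to_numpy(),
                            selection["marker_class"].to_numpy(),
                            denominator=config.aaf_denominator)
        seg = segregation_table(calls, selection, dm.loci, alpha=config.alpha)
        _write_tsv(seg, out / "selected_markers.tsv",
                   "double-simplex candidates with 1:3 chi-square results; "
                   "right-open AAF windows; kept = p >= alpha")
        keep_mask = seg["kept"].to_numpy()
        calls = calls[keep_mask]
        markers = seg.loc[keep_mask, ["key", "scaffold", "pos", "marker_class"]] \
            .reset_index(drop=True)
        manifest["stages"]["segregation"] = {"n_kept": int(keep_mask.sum())}
        if keep_mask.sum() == 0:
            raise RuntimeError("no markers pass the 1:3 segregation test")

        stage = "map_pass1"
        gm1 = build_map(calls, markers, params=config.grouping,
                        map_function=config.map_function)
        tab1 = gm1.to_table(markers)
        _write_tsv(tab1, out / "map_pass1.tsv", "first-pass map; cm cumulative per LG")
        manifest["stages"]["map_pass1"] = _map_stats(gm1)

        if config.skip_imputation:
            gm2, calls2 = gm1, calls
            manifest["stages"]["impute"] = {"skipped": True}
        else:
            stage = "impute"
            corrected, log_c = correct_errors(calls, gm1, config.imputation)
            calls2, log_i = impute_missing(corrected, gm1, config.imputation)
            _write_tsv(pd.concat([log_c.to_frame(), log_i.to_frame()]),
                       out / "correction_log.tsv",
                       "per-cell provenance: before/after are calls "
                       "(0 homozygous, 1 not-homozygous, -1 missing)")
            manifest["stages"]["impute"] = {
                "n_corrected": log_c.n_corrected, "n_imputed": log_i.n_imputed}

            stage = "map_pass2"
            gm2 = rerun_map(calls2, markers, params=config.grouping,
                            map_function=config.map_function)
            manifest["stages"]["map_pass2"] = _map_stats(gm2)

        tab2 = gm2.to_table(markers)
        _write_tsv(tab2, out / "map_final.tsv",
                   "final map: one row per mapped SNP (LG, order, bin, cM, scaffold, 1-based bp)")

        stage = "hg"
        incidence = build_incidence(tab2[~tab2["small_group"]])
        partition = cluster_hgs(incidence, config.min_shared_scaffolds, config.hg_ploidy)
        partition = number_groups(partition, tab2[~tab2["small_group"]])
        hg_tab = hg_table(partition, tab2)
        _write_tsv(hg_tab, out / "hg_table.tsv",
                   "homologous groups numbered by descending map length (cM)")
        manifest["stages"]["hg"] = {
            "n_hgs": partition.n_hgs,
            "n_chimeric_scaffolds": len(partition.chimeric_scaffolds),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    report_tables(out, profile, calls2, hg_tab, config)
    return PipelineResult(manifest=manifest, map_table=tab2, hg=hg_tab,
                          genetic_map=gm2, calls=calls2, markers=markers)


def _map_stats(gm: GeneticMap) -> dict:
    large = gm.large_groups()
    return {
        "n_groups_total": gm.n_groups,
        "n_groups_large": len(large),
        "n_markers_mapped": int(sum(lg.n_markers for lg in large)),
        "n_bins": int(sum(lg.n_bins for lg in large)),
        "total_length_cm": round(gm.total_length_cm, 1),
    }


def lod_sweep(calls: np.ndarray, params: GroupingParams,
              lod_range=range(3, 11)) -> pd.DataFrame:
    """Groups with >= min_group_size markers at each LOD threshold 3..10."""
    bin_per_marker, rep_rows = bin_cosegregating(calls)
    sizes = np.bincount(bin_per_marker, minlength=len(rep_rows))
    table = two_point_table(calls[rep_rows], min_shared=params.min_shared)
    rows = []
    for lod in lod_range:
        p = GroupingParams(lod_threshold=float(lod), max_rf=params.max_rf,
                           min_group_size=params.min_group_size,
                           min_shared=params.min_shared)
        _, large, small = group_markers(table, p, weights=sizes)
        rows.append((lod, len(large), len(large) + len(small)))
    return pd.DataFrame(rows, columns=["LOD", "n_groups_min_size", "n_groups_total"])


def report_tables(out_dir, profile, calls, hg_tab, config,
                  aaf_bin_width: float = 0.005) -> None:
    """Summary artifacts: AAF histogram bins, LOD-sweep table, HG x LG grid."""
    out = Path(out_dir)
    edges = np.arange(0.0, 1.0 + aaf_bin_width, aaf_bin_width)
    pooled = profile.pooled[~np.isnan(profile.pooled)]
    hist, _ = np.histogram(pooled, bins=edges)
    _write_tsv(pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                             "count": hist}),
               out / "aaf_histogram.tsv",
               f"pooled ALT-allele-frequency histogram, bin width {aaf_bin_width}")
    sweep = lod_sweep(calls, config.grouping)
    _write_tsv(sweep, out / "lod_sweep.tsv",
               f"groups with >= {config.grouping.min_group_size} markers per LOD threshold")
    grid = hg_tab.pivot_table(index="HG", columns="LG", values="n_loci",
                              fill_value=0, aggfunc="sum")
    grid["total"] = grid.sum(axis=1)
    grid.loc["total"] = grid.sum(axis=0)
    grid.reset_index().to_csv(out / "hg_lg_grid.tsv", sep="\t", index=False)
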
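"""Homologous-group identification by anchoring linkage groups to scaffolds.

Double-simplex markers cannot anchor the six homolog maps of one chromosome
to each other genetically, so homologous groups (HGs) are recovered
physically: every mapped SNP has a position on a scaffold of a diploid
relative's assembly, LGs sharing scaffolds are joined in a graph, and the
connected components are the HGs — expected to number the basic chromosome
count, each holding ~6 LGs (one per homolog). Scaffolds anchoring more LGs
than the ploidy allows are flagged as likely chimeric assemblies and
excluded from edge weighting; an edge needs at least ``min_shared_scaffolds``
supporting scaffolds so a single misassembled scaffold cannot bridge two
HGs. HGs and LGs are finally numbered by descending map length.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

PLOIDY = 6

__all__ = ["LgScaffoldIncidence", "HgPartition", "build_incidence",
           "cluster_hgs", "number_groups", "hg_table"]


@dataclass
class LgScaffoldIncidence:
    """counts: (LG x scaffold) mapped-SNP counts; assigned: per-scaffold set
    of LGs with >= min_snps SNPs there."""

    counts: pd.DataFrame            # index: lg id, columns: scaffold id
    min_snps: int

    @property
    def assigned(self) -> dict[str, set[int]]:
        out = {}
        for sc in self.counts.columns:
            col = self.counts[sc]
            out[sc] = set(col.index[col >= self.min_snps])
        return out


@dataclass
class HgPartition:
    """lg_to_hg: raw component id per LG; chimeric: scaffolds anchoring more
    LGs than the ploidy; labels filled by :func:`number_groups`."""

    lg_to_hg: dict[int, int]
    chimeric_scaffolds: list[str]
    hg_labels: dict[int, str] | None = None      # component -> "HG01"
    lg_labels: dict[int, str] | None = None      # lg -> "LG1" (within its HG)
    hg_order: list[int] | None = None

    @property
    def n_hgs(self) -> int:
        return len(set(self.lg_to_hg.values()))

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for lg, hg in self.lg_to_hg.items():
            out.setdefault(hg, []).append(lg)
        return out


def build_incidence(map_table: pd.DataFrame, min_snps: int = 1,
                    known_scaffolds=None) -> LgScaffoldIncidence:
    """Tally mapped SNPs per (LG, scaffold) from a marker-level map table.

    ``map_table`` needs columns ``lg`` and ``scaffold``. SNPs on scaffolds
    absent from ``known_scaffolds`` (if given) are excluded with a warning.
    """
    import logging

    tab = map_table
    if known_scaffolds is not None:
        known = set(known_scaffolds)
        bad = ~tab["scaffold"].isin(known)
        if bad.any():
            logging.getLogger(__name__).warning(
                "excluding %d SNPs on unknown scaffolds", int(bad.sum()))
            tab = tab[~bad]
    if len(tab) == 0:
        return LgScaffoldIncidence(counts=pd.DataFrame(), min_snps=min_snps)
    counts = tab.pivot_table(index="lg", columns="scaffold", values="key",
                             aggfunc="count", fill_value=0)
    return LgScaffoldIncidence(counts=counts, min_snps=min_snps)


def cluster_hgs(
    incidence: LgScaffoldIncidence,
    min_shared_scaffolds: int = 2,
    ploidy: int = PLOIDY,
) -> HgPartition:
    """Connected components of the LG graph weighted by shared scaffolds.

    Edge weight between two LGs = number of (non-chimeric) scaffolds assigned
    to both; edges lighter than ``min_shared_scaffolds`` are removed.
    Scaffolds assigned to more than ``ploidy`` LGs are flagged chimeric and
    contribute no edges.
    """
    counts = incidence.counts
    g = nx.Graph()
    g.add_nodes_from(counts.index if len(counts) else [])
    chimeric: list[str] = []
    if len(counts):
        assigned = incidence.assigned
        weights: dict[tuple[int, int], int] = {}
        for sc, lgs in assigned.items():
            if len(lgs) > ploidy:
                chimeric.append(sc)
                continue
            lgs_sorted = sorted(lgs)
            for i, a in enumerate(lgs_sorted):
                for b in lgs_sorted[i + 1:]:
                    weights[(a, b)] = weights.get((a, b), 0) + 1
        for (a, b), w in weights.items():
            if w >= min_shared_scaffolds:
                g.add_edge(a, b, weight=w)
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    lg_to_hg = {lg: i for i, comp in enumerate(comps) for lg in sorted(comp)}
    return HgPartition(lg_to_hg=lg_to_hg, chimeric_scaffolds=sorted(chimeric))


def number_groups(partition: HgPartition, map_table: pd.DataFrame) -> HgPartition:
    """Number HGs and, within each HG, LGs by descending map length.

    Ties break by marker count, then by raw label. ``map_table`` needs
    columns ``lg``, ``cm`` and ``key``; an LG's length is its max cM.
    Returns the partition with ``hg_labels`` (HG01, ...) and ``lg_labels``
    (LG1, ... within each HG) filled in.
    """
    lg_len = map_table.groupby("lg")["cm"].max()
    lg_n = map_table.groupby("lg")["key"].count()
    members = partition.members()
    hg_stats = []
    for hg, lgs in members.items():
        tot_cm = float(sum(lg_len.get(lg, 0.0) for lg in lgs))
        tot_n = int(sum(lg_n.get(lg, 0) for lg in lgs))
        hg_stats.append((hg, tot_cm, tot_n))
    hg_stats.sort(key=lambda t: (-t[1], -t[2], t[0]))
    hg_labels = {hg: f"HG{i + 1:02d}" for i, (hg, _, _) in enumerate(hg_stats)}
    lg_labels: dict[int, str] = {}
    for hg, _, _ in hg_stats:
        lgs = sorted(members[hg],
                     key=lambda lg: (-float(lg_len.get(lg, 0.0)),
                                     -int(lg_n.get(lg, 0)), lg))
        for j, lg in enumerate(lgs):
            lg_labels[lg] = f"LG{j + 1}"
    return HgPartition(
        lg_to_hg=partition.lg_to_hg,
        chimeric_scaffolds=partition.chimeric_scaffolds,
        hg_labels=hg_labels,
        lg_labels=lg_labels,
        hg_order=[hg for hg, _, _ in hg_stats],
    )


def hg_table(partition: HgPartition, map_table: pd.DataFrame) -> pd.DataFrame:
    """Per-LG summary in the numbered layout: HG, LG, n_loci, cM."""
    if partition.hg_labels is None:
        raise ValueError("run number_groups first")
    lg_len = map_table.groupby("lg")["cm"].max()
    lg_n = map_table.groupby("lg")["key"].count()
    rows = []
    for hg in partition.hg_order:
        for lg, lab in sorted(
                ((lg, partition.lg_labels[lg]) for lg, h in partition.lg_to_hg.items() if h == hg),
                key=lambda t: int(t[1][2:])):
            rows.append((partition.hg_labels[hg], lab, int(lg_n.get(lg, 0)),
                         float(lg_len.get(lg, 0.0)), lg))
    return pd.DataFrame(rows, columns=["HG", "LG", "n_loci", "cM", "lg_raw"])
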
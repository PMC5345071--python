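"""Simulation of autohexaploid S1 populations with ddRAD-style read depths.

The simulator builds a heterozygous hexaploid founder (6 homologs per
chromosome) carrying SNPs of configurable allele dosage (1-6 ALT-carrying
homologs), passes it through random-bivalent meiosis with Poisson crossovers,
selfs it once to produce an S1 population, and emits per-locus /
per-individual read depths plus a VarScan-dialect VCF (DP/RD/AD genotype
fields) and a fragmented-scaffold physical table, together with truth files.

Model assumptions
-----------------
* Bivalent-only pairing: at each meiosis the 6 homologs of a chromosome are
  partitioned uniformly at random into 3 disjoint pairs; a gamete receives
  exactly one recombinant strand per bivalent, so each homolog is transmitted
  with marginal probability 1/2.
* Crossovers: count ~ Poisson(length_cM / 100) per transmitted strand,
  positions uniform on the cM axis, no interference, no double reduction.
* Read depths: total depth ~ negative binomial around a configurable mean;
  ALT-supporting reads ~ Binomial(depth, (d/6)(1-eps) + (1-d/6)eps) for true
  ALT dosage d and per-read error rate eps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PLOIDY = 6

__all__ = [
    "FounderGenome",
    "MeiosisModel",
    "ReadDepthModel",
    "SimDepths",
    "simulate_founder",
    "simulate_s1_population",
    "simulate_gametes",
    "simulate_read_depths",
    "inject_call_errors",
    "write_vcf",
    "write_scaffold_table",
    "write_truth",
]


@dataclass(frozen=True)
class MeiosisModel:
    """Random-bivalent hexaploid meiosis.

    ``crossover_rate_per_cM`` converts map length to the Poisson mean of
    crossovers on a transmitted strand (1/100 makes 1 cM = 1% recombination
    at short distances). Double reduction is fixed at zero.
    """

    crossover_rate_per_cM: float = 1.0 / 100.0
    double_reduction: float = 0.0

    def __post_init__(self) -> None:
        if self.double_reduction != 0.0:
            raise ValueError("only double_reduction=0 is modelled")


@dataclass(frozen=True)
class ReadDepthModel:
    """Per-cell sequencing depth model for ddRAD-style genotyping.

    depth_mean : mean total depth per locus x individual cell
    dispersion : negative-binomial size parameter (larger = closer to Poisson)
    error_rate : per-read probability of reading the wrong allele (eps)
    missing_rate : probability a cell is dropped entirely
    """

    depth_mean: float = 80.0
    dispersion: float = 10.0
    error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class FounderGenome:
    """A hexaploid founder: loci table + per-chromosome geometry.

    ``loci`` columns: key, chrom (int), scaffold, pos (1-based bp on the
    scaffold), chrom_bp (0-based bp on the chromosome), cm, dosage,
    carriers (frozenset of homolog indices 0-5).
    ``scaffolds`` columns: scaffold, chrom, start, end, length (0-based
    half-open chromosome coordinates).
    """

    n_chrom: int
    chrom_length_cm: float
    chrom_length_bp: int
    loci: pd.DataFrame
    scaffolds: pd.DataFrame
    seed: int | None = None

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def carriers_matrix(self, chrom: int) -> np.ndarray:
        """(6, n_loci_on_chrom) boolean: homolog h carries ALT at locus j."""
        sub = self.loci[self.loci["chrom"] == chrom]
        mat = np.zeros((PLOIDY, len(sub)), dtype=bool)
        for j, carr in enumerate(sub["carriers"]):
            for h in carr:
                mat[h, j] = True
        return mat


@dataclass
class SimDepths:
    """Raw simulated depth layer (pre-VCF): integer arrays (loci x individuals)."""

    dp: np.ndarray
    rd: np.ndarray
    ad: np.ndarray
    missing: np.ndarray


def _default_mix() -> np.ndarray:
    # all-simplex founder: every locus has exactly one ALT-carrying homolog
    mix = np.zeros(PLOIDY)
    mix[0] = 1.0
    return mix


def simulate_founder(
    n_chrom: int = 15,
    loci_per_homolog: int = 30,
    dosage_class_mix: np.ndarray | None = None,
    chrom_length_cm: float = 100.0,
    chrom_length_bp: int = 2_000_000,
    scaffold_n50_bp: int = 150_000,
    chimeric_fraction: float = 0.0,
    seed: int | None = None,
) -> FounderGenome:
    """Build a heterozygous hexaploid founder and its fragmented reference.

    Loci are evenly spaced in bp along each chromosome (genetic position
    proportional to bp); for simplex loci the ALT-carrying homolog cycles
    0..5 so every homolog receives an evenly spread ladder of markers.
    ``dosage_class_mix`` is a probability vector over founder ALT dosages
    1..6 (default: all mass on dosage 1, i.e. simplex only).
    ``chimeric_fraction`` of scaffolds are made chimeric by fusing a segment
    from a different chromosome onto them.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if loci_per_homolog < 1:
        raise ValueError("need at least one locus per homolog")
    if chrom_length_cm <= 0 or chrom_length_bp <= 0 or scaffold_n50_bp <= 0:
        raise ValueError("lengths must be positive")
    mix = _default_mix() if dosage_class_mix is None else np.asarray(dosage_class_mix, float)
    if mix.shape != (PLOIDY,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("dosage_class_mix must be a probability vector over dosages 1..6")

    rng = np.random.default_rng(seed)
    n_loci_chrom = loci_per_homolog * PLOIDY
    records = []
    scaffold_rows = []
    for c in range(n_chrom):
        # even bp spacing, half-step offset so loci stay inside the chromosome
        bp = ((np.arange(n_loci_chrom) + 0.5) / n_loci_chrom * chrom_length_bp).astype(np.int64)
        cm = bp / chrom_length_bp * chrom_length_cm
        dosages = rng.choice(np.arange(1, PLOIDY + 1), size=n_loci_chrom, p=mix)
        # simplex loci cycle through homologs; higher dosages draw random subsets
        simplex_cycle = 0
        for j in range(n_loci_chrom):
            d = int(dosages[j])
            if d == 1:
                carriers = frozenset({simplex_cycle % PLOIDY})
                simplex_cycle += 1
            elif d == 5:
                non_carrier = simplex_cycle % PLOIDY
                simplex_cycle += 1
                carriers = frozenset(range(PLOIDY)) - {non_carrier}
            else:
                carriers = frozenset(rng.choice(PLOIDY, size=d, replace=False).tolist())
            records.append((c, int(bp[j]), float(cm[j]), d, carriers))
        scaffold_rows.extend(_fragment_chromosome(c, chrom_length_bp, scaffold_n50_bp, rng))

    scaffolds = pd.DataFrame(scaffold_rows, columns=["scaffold", "chrom", "start", "end"])
    scaffolds = _apply_chimerism(scaffolds, chimeric_fraction, rng)
    scaffolds["length"] = scaffolds["end"] - scaffolds["start"]

    loci = pd.DataFrame(records, columns=["chrom", "chrom_bp", "cm", "dosage", "carriers"])
    loci = _place_on_scaffolds(loci, scaffolds)
    loci["key"] = [
        f"{row.scaffold}:{row.pos}" for row in loci.itertuples()
    ]
    loci = loci[["key", "chrom", "scaffold", "pos", "chrom_bp", "cm", "dosage", "carriers"]]
    return FounderGenome(
        n_chrom=n_chrom,
        chrom_length_cm=chrom_length_cm,
        chrom_length_bp=chrom_length_bp,
        loci=loci,
        scaffolds=scaffolds,
        seed=seed,
    )


def _fragment_chromosome(chrom: int, length_bp: int, n50_bp: int, rng: np.random.Generator):
    """Split [0, length_bp) at uniform breakpoints into ~length/n50 scaffolds."""
    k = max(1, round(length_bp / n50_bp))
    if k == 1:
        cuts = np.array([0, length_bp], dtype=np.int64)
    else:
        inner = np.sort(rng.choice(np.arange(1, length_bp), size=k - 1, replace=False))
        cuts = np.concatenate(([0], inner, [length_bp]))
    return [
        (f"sc{chrom:02d}_{i:04d}", chrom, int(cuts[i]), int(cuts[i + 1]))
        for i in range(len(cuts) - 1)
    ]


def _apply_chimerism(scaffolds: pd.DataFrame, fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    """Fuse pairs of segments from different chromosomes under one scaffold id.

    A chimeric scaffold keeps two rows (one per chromosome segment) sharing
    the same id; loci on the second segment get bp offsets past the first.
    """
    if fraction <= 0:
        return scaffolds.reset_index(drop=True)
    chroms = scaffolds["chrom"].unique()
    if len(chroms) < 2:
        return scaffolds.reset_index(drop=True)
    n_chimeric = int(fraction * scaffolds["scaffold"].nunique())
    sc = scaffolds.copy().reset_index(drop=True)
    ids = sc["scaffold"].to_numpy().copy()
    used: set[int] = set()
    made = 0
    order = rng.permutation(len(sc))
    for i in order:
        if made >= n_chimeric:
            break
        if i in used:
            continue
        partners = [j for j in order if j not in used and j != i and sc.at[j, "chrom"] != sc.at[i, "chrom"]]
        if not partners:
            break
        j = partners[0]
        ids[j] = ids[i]  # fuse: segment j now reports scaffold id of i
        used.update((int(i), int(j)))
        made += 1
    sc["scaffold"] = ids
    return sc


def _place_on_scaffolds(loci: pd.DataFrame, scaffolds: pd.DataFrame) -> pd.DataFrame:
    """Assign each locus to its covering scaffold segment; pos is 1-based on
    the scaffold (chimeric second segments are offset past the first)."""
    # per-scaffold cumulative offset of each segment
    offsets = {}
    for sid, grp in scaffolds.groupby("scaffold", sort=False):
        run = 0
        for idx in grp.index:
            offsets[idx] = run
            run += int(scaffolds.at[idx, "end"] - scaffolds.at[idx, "start"])
    out_scaffold = np.empty(len(loci), dtype=object)
    out_pos = np.empty(len(loci), dtype=np.int64)
    for chrom, grp in scaffolds.groupby("chrom", sort=False):
        segs = grp.sort_values("start")
        mask = loci["chrom"] == chrom
        bps = loci.loc[mask, "chrom_bp"].to_numpy()
        seg_idx = np.searchsorted(segs["end"].to_numpy(), bps, side="right")
        for row_pos, (bp, k) in zip(np.flatnonzero(mask.to_numpy()), zip(bps, seg_idx)):
            seg = segs.iloc[int(k)]
            out_scaffold[row_pos] = seg["scaffold"]
            out_pos[row_pos] = bp - int(seg["start"]) + offsets[seg.name] + 1
    loci = loci.copy()
    loci["scaffold"] = out_scaffold
    loci["pos"] = out_pos
    return loci


def _strand(positions_cm: np.ndarray, pair: np.ndarray, length_cm: float,
            model: MeiosisModel, rng: np.random.Generator) -> np.ndarray:
    """Homolog id carried by one transmitted strand at each locus position."""
    n_xo = rng.poisson(length_cm * model.crossover_rate_per_cM)
    start = rng.integers(2)
    if n_xo == 0:
        return np.full(positions_cm.shape, pair[start])
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    seg = np.searchsorted(xo, positions_cm, side="right")
    return pair[(start + seg) % 2]


def simulate_gametes(
    founder: FounderGenome,
    chrom: int,
    n_gametes: int,
    meiosis: MeiosisModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample gametes for one chromosome.

    Returns ``(alt_counts, homologs)``: alt_counts is (n_gametes, n_loci)
    ALT-allele counts (0-3); homologs is (n_gametes, 3, n_loci) giving the
    homolog id each of the 3 transmitted strands carries at every locus.
    """
    meiosis = meiosis or MeiosisModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sub = founder.loci[founder.loci["chrom"] == chrom]
    pos = sub["cm"].to_numpy()
    carriers = founder.carriers_matrix(chrom)  # (6, n_loci)
    n_loci = len(pos)
    alt = np.zeros((n_gametes, n_loci), dtype=np.int8)
    hom = np.zeros((n_gametes, 3, n_loci), dtype=np.int8)
    for g in range(n_gametes):
        perm = rng.permutation(PLOIDY)
        for b in range(3):
            pair = perm[2 * b: 2 * b + 2]
            strand = _strand(pos, pair, founder.chrom_length_cm, meiosis, rng)
            hom[g, b] = strand
            alt[g] += carriers[strand, np.arange(n_loci)]
    return alt, hom


def simulate_s1_population(
    founder: FounderGenome,
    meiosis: MeiosisModel | None = None,
    n_individuals: int = 142,
    seed: int | None = None,
) -> pd.DataFrame:
    """Self the founder once: each S1 individual fuses two independent gametes.

    Returns the truth table: the founder loci table plus a ``dosage_matrix``
    attribute-style column layout is avoided — the (n_loci, n_individuals)
    int8 true-dosage matrix is returned in ``.attrs['dosage']`` of the copy
    of the loci table, and also directly accessible via the returned frame's
    ``attrs``. Use :func:`true_dosage_matrix` for just the matrix.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    meiosis = meiosis or MeiosisModel()
    rng = np.random.default_rng(seed)
    dosage = np.zeros((founder.n_loci, n_individuals), dtype=np.int8)
    loci = founder.loci
    for chrom in range(founder.n_chrom):
        idx = np.flatnonzero((loci["chrom"] == chrom).to_numpy())
        alt1, _ = simulate_gametes(founder, chrom, n_individuals, meiosis, rng)
        alt2, _ = simulate_gametes(founder, chrom, n_individuals, meiosis, rng)
        dosage[idx, :] = (alt1 + alt2).T
    truth = loci.copy()
    truth.attrs["dosage"] = dosage
    truth.attrs["seed"] = seed
    return truth


def true_dosage_matrix(truth: pd.DataFrame) -> np.ndarray:
    return truth.attrs["dosage"]


def simulate_read_depths(
    dosage_matrix: np.ndarray,
    model: ReadDepthModel | None = None,
    seed: int | None = None,
) -> SimDepths:
    """Draw per-cell read depths for a true-dosage matrix.

    Total depth is negative binomial (size=dispersion, mean=depth_mean);
    ALT reads are binomial with success probability
    (d/6)(1-eps) + (1-d/6)eps.  Cells are dropped (missing) independently
    at ``missing_rate``.
    """
    model = model or ReadDepthModel()
    d = np.asarray(dosage_matrix)
    if d.min() < 0 or d.max() > PLOIDY:
        raise ValueError("dosage matrix entries must be in 0..6")
    rng = np.random.default_rng(seed)
    size = model.dispersion
    p_nb = size / (size + model.depth_mean)
    dp = rng.negative_binomial(size, p_nb, size=d.shape).astype(np.int32)
    frac = d / PLOIDY
    p_alt = frac * (1.0 - model.error_rate) + (1.0 - frac) * model.error_rate
    ad = rng.binomial(dp, p_alt).astype(np.int32)
    rd = dp - ad
    missing = rng.random(d.shape) < model.missing_rate
    dp = np.where(missing, 0, dp)
    rd = np.where(missing, 0, rd)
    ad = np.where(missing, 0, ad)
    return SimDepths(dp=dp, rd=rd, ad=ad, missing=missing)


def inject_call_errors(calls: np.ndarray, rate: float, seed: int | None = None) -> np.ndarray:
    """Flip a fraction of non-missing dichotomized calls (0<->1).

    Used to emulate residual genotyping error on the call layer; missing
    cells (-1) are never touched.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = calls.copy()
    flip = (rng.random(calls.shape) < rate) & (calls >= 0)
    out[flip] = 1 - out[flip]
    return out


# ---------------------------------------------------------------------------
# serialization

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=simplexmap-simulator
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Quality Read Depth">
##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Depth of reference-supporting bases">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Depth of variant-supporting bases">
"""


def write_vcf(depths: SimDepths, loci: pd.DataFrame, scaffolds: pd.DataFrame,
              path: str | Path, sample_prefix: str = "S1_") -> Path:
    """Write a VarScan-dialect VCF (DP/RD/AD genotype fields, AD scalar).

    CHROM is the scaffold id, POS the 1-based position on the scaffold.
    Missing cells are written as ``./.:.:.:.``.
    """
    path = Path(path)
    n_loci, n_ind = depths.dp.shape
    if n_loci != len(loci):
        raise ValueError("depth matrix and loci table disagree on locus count")
    samples = [f"{sample_prefix}{i + 1:03d}" for i in range(n_ind)]
    # contig lengths: total per scaffold id (chimeric ids sum their segments)
    contig_len = scaffolds.groupby("scaffold", sort=False)["end"].sum() - \
        scaffolds.groupby("scaffold", sort=False)["start"].sum()
    order = np.lexsort((loci["pos"].to_numpy(), loci["scaffold"].to_numpy()))
    try:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for sid, ln in contig_len.items():
                fh.write(f"##contig=<ID={sid},length={int(ln)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for i in order:
                row = loci.iloc[i]
                cells = []
                for j in range(n_ind):
                    if depths.missing[i, j]:
                        cells.append("./.:.:.:.")
                    else:
                        dp, rd, ad = int(depths.dp[i, j]), int(depths.rd[i, j]), int(depths.ad[i, j])
                        gt = "0/0" if ad == 0 else ("1/1" if rd == 0 else "0/1")
                        cells.append(f"{gt}:{dp}:{rd}:{ad}")
                fh.write(
                    f"{row.scaffold}\t{int(row.pos)}\t{row.key}\tA\tG\t.\tPASS\t.\tGT:DP:RD:AD\t"
                    + "\t".join(cells) + "\n"
                )
    except OSError as exc:
        raise OSError(f"failed to write VCF to {path}: {exc}") from exc
    return path


def write_scaffold_table(scaffolds: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    scaffolds.to_csv(path, sep="\t", index=False,
                     columns=["scaffold", "chrom", "start", "end", "length"])
    return path


def write_truth(truth: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write truth files: loci table (with carrier sets) and the dosage matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    loci_path = out_dir / "truth_loci.tsv"
    tab = truth.copy()
    tab["carriers"] = [",".join(map(str, sorted(c))) for c in tab["carriers"]]
    tab.to_csv(loci_path, sep="\t", index=False)
    dosage = truth.attrs["dosage"]
    mat_path = out_dir / "truth_dosage.tsv"
    pd.DataFrame(dosage, index=truth["key"]).to_csv(mat_path, sep="\t")
    return {"loci": loci_path, "dosage": mat_path}
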
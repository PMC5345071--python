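"""Simulate a hexaploid S1 population and write its VCF + truth files.

Builds a small 3-chromosome autohexaploid founder (6 homologs each, simplex
SNPs laddered along every homolog), selfs it once to get 142 S1 progeny,
draws ddRAD-style read depths, and writes the VarScan-dialect VCF the
mapping pipeline consumes.
"""

from pathlib import Path

import simplexmap as sm

out = Path("scratch/example_sim")
out.mkdir(parents=True, exist_ok=True)

founder = sm.simulate_founder(n_chrom=3, loci_per_homolog=20, seed=1)
truth = sm.simulate_s1_population(founder, n_individuals=142, seed=2)
depths = sm.simulate_read_depths(truth.attrs["dosage"],
                                 sm.ReadDepthModel(depth_mean=80), seed=3)
sm.write_vcf(depths, founder.loci, founder.scaffolds, out / "population.vcf")
sm.write_scaffold_table(founder.scaffolds, out / "scaffolds.tsv")
sm.write_truth(truth, out)

dosage = truth.attrs["dosage"]
print(f"founder: {founder.n_chrom} chromosomes x 6 homologs, "
      f"{founder.n_loci} simplex SNP loci")
print(f"scaffolds: {founder.scaffolds['scaffold'].nunique()} "
      f"(fragmented reference the loci are anchored on)")
print(f"S1 progeny dosage matrix: {dosage.shape[0]} loci x {dosage.shape[1]} individuals")
print(f"dosage-0 fraction at simplex loci: {(dosage == 0).mean():.3f} "
      "(expected 0.25: the homozygous class of a 1:2:1 selfing)")
print(f"wrote {out / 'population.vcf'}")
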
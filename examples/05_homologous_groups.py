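"""Homologous-group assignment by anchoring linkage groups to scaffolds.

Double-simplex markers cannot link the six homolog maps of one chromosome
to each other, so the homologous groups are recovered physically: linkage
groups that share reference scaffolds are clustered into connected
components. On an error-free simulation each chromosome's six homolog LGs
share that chromosome's scaffolds and fall into one HG.
"""

import simplexmap as sm
from simplexmap.studies import hexaploid_s1_study
from simplexmap.hg_assign import hg_table

study = hexaploid_s1_study(seed=42, n_chrom=5, via_vcf=False)
part = study.partition

print(f"{len(study.genetic_map.large_groups())} linkage groups "
      f"-> {part.n_hgs} homologous groups (expected: the chromosome count, 5)")
sizes = sorted((len(v) for v in part.members().values()), reverse=True)
print(f"LGs per HG: {sizes} (expected six, one per homolog)")
print(f"chimeric scaffolds flagged (> 6 LGs): {len(part.chimeric_scaffolds)}")

tab = hg_table(part, study.map_table[~study.map_table['small_group']])
print("\nHG table (numbered by descending map length):")
for hg, grp in tab.groupby("HG", sort=False):
    print(f"  {hg}: {len(grp)} LGs, {grp['n_loci'].sum()} loci, "
          f"{grp['cM'].sum():.1f} cM")
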
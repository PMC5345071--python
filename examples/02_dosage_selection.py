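"""From read depths to double-simplex markers: AAF, windows, 1:3 test.

Reproduces the dosage-classification arithmetic on a mixed-dosage
simulation: pooled ALT allele frequencies (AAF = ALT/(REF+ALT) reads) peak
at k/6 for founder ALT dosage k; only loci in the simplex windows
[0.0833, 0.25) and [0.75, 0.9167) are kept, dichotomized per individual,
and tested against the 1:3 homozygous : not-homozygous S1 ratio.
"""

import numpy as np

import simplexmap as sm
from simplexmap.vcf_model import DepthMatrix

# founder carrying all six dosage classes in equal proportion
mix = np.full(6, 1 / 6)
founder = sm.simulate_founder(n_chrom=2, loci_per_homolog=40,
                              dosage_class_mix=mix, seed=11)
truth = sm.simulate_s1_population(founder, n_individuals=142, seed=12)
depths = sm.simulate_read_depths(truth.attrs["dosage"],
                                 sm.ReadDepthModel(depth_mean=80), seed=13)
loci = founder.loci[["key", "scaffold", "pos"]].assign(ref="A", alt="G")
dm = DepthMatrix(loci=loci.reset_index(drop=True),
                 samples=[f"S1_{i:03d}" for i in range(142)],
                 dp=depths.dp, rd=depths.rd, ad=depths.ad,
                 missing=depths.missing)

dm = sm.apply_depth_filter(dm)
dm, _ = sm.apply_missing_filter(dm)
profile = sm.compute_aaf(dm)

print("pooled AAF by true founder dosage (expected k/6):")
for d in range(1, 7):
    vals = profile.pooled[founder.loci["dosage"].to_numpy() == d]
    print(f"  dosage {d}: median pooled AAF = {np.median(vals):.3f} "
          f"(expected {d / 6:.3f}, n = {len(vals)})")

selection = sm.select_double_simplex(profile)
print(f"\nselected {len(selection)} double-simplex candidates "
      f"({(selection['marker_class'] == 'ds-REF').sum()} ds-REF, "
      f"{(selection['marker_class'] == 'ds-ALT').sum()} ds-ALT) "
      f"of {dm.shape[0]} loci — duplex/triplex regions are discarded")

calls = sm.dichotomize(dm, selection["index"].to_numpy(),
                       selection["marker_class"].to_numpy())
seg = sm.segregation_table(calls, selection, dm.loci)
print(f"1:3 segregation test at alpha=0.01: kept {int(seg['kept'].sum())} "
      f"of {len(seg)} (a ~1% type-I rejection rate is expected on true simplex loci)")
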
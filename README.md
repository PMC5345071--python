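# simplexmap

High-density SNP linkage mapping for **autohexaploid selfed (S1)
populations**, from depth-annotated VCF genotypes to homologous groups —
plus a hexaploid meiosis / read-depth simulator so every stage can be
verified against known truth.

Autohexaploids such as sweetpotato (*Ipomoea batatas*, 2n = 6x = 90) carry
six homologous copies of every chromosome that pair essentially at random,
which defeats ordinary diploid mapping software. `simplexmap` implements a
strategy that makes the problem disomic-like:

1. **Dosage from read depth.** Against a haploid reference, a segregating
   SNP in the parent carries *d* ∈ {1..6} ALT alleles, and the ALT allele
   frequency of pooled reads, AAF = ALT/(REF+ALT), concentrates at *d*/6 —
   six peaks at 0.167, 0.333, 0.500, 0.667, 0.833, 1.000.
2. **Double-simplex selection.** Only loci where the selfed parent is
   simplex (AAF in [0.0833, 0.2500) for simplex-ALT, or [0.7500, 0.9167)
   for simplex-REF) segregate 1:2:1 like a diploid heterozygote. Per
   individual, reads are too shallow to separate dosage 1 from 2, so calls
   are **dichotomized**: homozygous (individual AAF exactly 0, or exactly 1
   for the mirrored class) versus not-homozygous, an expected 1:3 ratio
   tested by χ² at α = 0.01.
3. **Two-point mapping.** A double-simplex pair on one homolog behaves like
   a dominant×dominant diploid F2 pair; with *q* = (1−r)/2 the joint class
   probabilities are (q², ¼−q², ¼−q², ½+q²), the likelihood is concave in
   q², and r̂ has a closed form. Single-linkage grouping at LOD ≥ 7 splits
   each chromosome into its six per-homolog linkage groups (LGs); markers
   are ordered by greedy chain growth with window ripple and placed in cM
   with the Kosambi function d = 25·ln((1+2r)/(1−2r)).
4. **Map-based cleaning.** Singleton double-recombinants are masked, missing
   calls imputed from agreeing flanking co-segregation bins, and the cleaned
   data mapped again — genotyping error otherwise inflates the map by
   roughly 2 cM per 1% error.
5. **Homologous groups (HGs).** Double-simplex markers cannot anchor
   homologs to each other genetically, so LGs sharing ≥ 2 reference
   scaffolds are clustered into connected components; each component is one
   basic chromosome with its ~6 homolog LGs. Scaffolds anchoring more LGs
   than the ploidy are flagged as chimeric.

The intended users are plant-genetics and genome-informatics groups mapping
polysomic polyploids from ddRAD/GBS read counts (VarScan-style `DP`/`RD`/`AD`
genotype fields).

## Worked example

```bash
python examples/03_linkage_map.py
```

simulates a 3-chromosome hexaploid S1 (n = 142, 30 simplex SNPs per
homolog, deep error-free depths) and prints:

```
539 markers passed selection + segregation

LOD sweep (groups with >= 20 markers):
  LOD  3: 6 groups
  LOD  4: 12 groups
  LOD  5: 16 groups
  LOD  6: 17 groups
  LOD  7: 18 groups  <- 6 x 3 chromosomes
  ...
at LOD 7: 18 linkage groups (one per homolog; 3 chromosomes x 6 homologs)
group lengths: 82.1 - 106.3 cM (truth: each homolog spans ~100 cM)

adjacent pair in 1: phase=coupling, r=0.024, LOD=23.9 -> 2.37 cM (Kosambi)
```

At low LOD thresholds homolog groups merge through weak repulsion-phase
associations; at LOD 7 the count locks onto 6 LGs per chromosome — the
behaviour the threshold is chosen for. The other scripts in `examples/`
cover simulation (`01`), dosage classification and the six AAF peaks (`02`),
error correction and map deflation (`04`), and homologous-group assignment
(`05`).

The same flow is available as a CLI:

```bash
simplexmap simulate --n-chrom 3 --n-ind 142 --seed 1 --out-dir sim/
simplexmap run-all --vcf sim/population.vcf --scaffolds sim/scaffolds.tsv \
    --out-dir run/ --lod 7
```

`run-all` writes stage tables (`selected_markers.tsv`, `map_final.tsv`,
`hg_table.tsv`, `aaf_histogram.tsv`, `lod_sweep.tsv`, ...) and a
`manifest.yaml` recording the marker attrition at every stage.

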
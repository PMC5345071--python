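# Methods

This note documents the models, rules and numerical choices behind
`simplexmap`, and what the simulation-based tests do and do not establish.

## Genetic model

The package targets a selfed (S1) population of a single autohexaploid
parent genotyped by sequencing against a haploid reference. Two premises do
all the work:

* **Polysomic bivalent inheritance.** At meiosis the six homologs of a
  chromosome form three bivalents drawn uniformly at random from the 15
  perfect pairings; each gamete receives one recombinant strand per
  bivalent, so every homolog is transmitted with probability 1/2 and
  double reduction is absent.
* **Double-simplex segregation.** A locus whose parent carries the minor
  allele on exactly one homolog segregates 1:2:1 by dosage in the S1
  (0, 1 or 2 copies), exactly like a diploid heterozygote selfed. All
  other dosage classes (duplex, triplex, ...) are excluded rather than
  modelled.

Dichotomizing dosage into *homozygous* (0 minor alleles; expected 1/4)
versus *not homozygous* (expected 3/4) turns each double-simplex marker
into a dominant-type marker, because per-individual read depth cannot
separate dosage 1 from dosage 2 reliably.

## Dosage classification

AAF is computed as ALT/(REF+ALT) read counts — pooled over the population
for marker selection, per cell for dichotomization. The pooled statistic is
used for selection because the population sum has thousands of reads and
resolves the six *d*/6 peaks; per-cell AAF is only trusted for the
zero/nonzero (one/non-one) distinction. An `aaf_denominator="dp"` switch
computes ALT/DP instead; the default follows the REF+ALT definition whose
pooled arithmetic the selection windows were designed around.

Selection windows are right-open: [0.0833, 0.2500) labels simplex-ALT
("ds-REF": the recessive class is homozygous-REF) and [0.7500, 0.9167)
labels simplex-REF ("ds-ALT"). The window edges are the midpoints between
the 0/6, 1/6, 2/6 (resp. 4/6, 5/6, 6/6) peaks. Loci at pooled AAF exactly
1.0 are monomorphic-ALT and non-segregating, and fall outside the windows.

The 1:3 test is a plain one-degree-of-freedom χ² against (n/4, 3n/4) over
non-missing calls, no continuity correction (n ≈ 142 is large); markers
with p ≥ 0.01 are kept. Note that all markers of one homolog co-segregate,
so this test effectively draws once per homolog lineage: occasionally an
entire lineage's markers are rejected together (see *Limitations*).

Sequencing error makes "individual AAF exactly 0" fragile at high depth; an
`alt_read_tolerance` (treat ≤ t minor-allele reads as zero, default t = 0)
is exposed for error-prone data, with the strict rule as default.

## Two-point likelihood

For two dichotomized markers the joint class probabilities under coupling
are P(homo,homo) = q², P(homo,not) = P(not,homo) = 1/4 − q²,
P(not,not) = 1/2 + q² with q = (1−r)/2; repulsion exchanges r and 1−r.
The log-likelihood is concave in u = q², so the stationary point solves a
quadratic and the ML estimate is closed-form, clamped to the phase's u
interval (coupling u ∈ [1/16, 1/4], repulsion u ∈ [0, 1/16]); the reported
phase maximizes the likelihood and LOD is the log10 ratio against u = 1/16
(r = 0.5). A brute-force grid-search oracle in the test suite confirms the
closed form to 5×10⁻⁴ over random tables. Pairwise class counts for all
markers come from three matrix products on the 0/1 indicator matrices, so
~3,000 markers × 142 individuals complete in seconds on one CPU.

Pairs with fewer than 20 shared non-missing individuals (configurable) or a
degenerate margin are flagged uninformative and contribute no edges.

Markers on *different* homologs of one chromosome are genuinely associated
(two marked homologs enter the same gamete with probability 1/5 rather than
1/4), and the repulsion model absorbs this at r ≈ 0.4 — but the expected
LOD is below 1 at n = 142, far under the grouping threshold of 7, which is
why LOD-7 single-linkage grouping resolves one linkage group per homolog
(6 × basic chromosome number in total).

## Grouping, binning, ordering, distances

Grouping is single-linkage transitive closure over edges with LOD ≥
threshold (default 7; sweep 3–10 reported) and r̂ ≤ 0.5. Groups under the
reporting floor (default 20 markers) are kept and listed separately, never
silently dropped. Markers with byte-identical call vectors (missing pattern
included) form co-segregation bins; one representative per bin enters
two-point estimation and ordering.

Ordering is a deterministic greedy chain in the rapid-chain-delineation
style: seed with the highest-LOD pair, append the unplaced bin with the
strongest LOD to either chain end, then polish with an exhaustive
permutation ripple over a sliding window of 4 bins, minimizing the sum of
adjacent r̂. Ties break by higher LOD, then lower r̂, then marker key; a
reversed chain scores identically, so orientation is arbitrary. This is
validated by parameter recovery on simulations (Spearman |ρ| ≥ 0.95 against
the true order in ≥ 90% of groups with ≥ 30 bins) rather than against any
particular external implementation.

Adjacent r̂ (capped at 0.4999) is converted to cM with the Kosambi function
d = 25·ln((1+2r)/(1−2r)) by default; Haldane (−50·ln(1−2r)) is available.
Positions accumulate from 0 per group.

## Error correction and imputation

Correction is a conservative mask-then-impute window rule operating on
ordered co-segregation bins (bin members vote by majority):

* a call disagreeing with both flanking bins' agreeing calls — an apparent
  double recombinant — is set to *missing* when it is within `max_error`
  (default 1) disagreements inside the ±`window` (default 2) bin
  neighbourhood; chain ends are left alone;
* a missing cell is filled only when the nearest non-missing flanks within
  the window agree; crossover intervals stay missing;
* markers above the 33% missing-eligibility ceiling pass through untouched;
* no call is ever flipped directly, and every change carries per-cell
  provenance in a log from which the original matrix is recoverable.

The cleaned matrix is then regrouped and reordered with the same
parameters (second pass). A second correct+impute pass on cleaned data is a
no-op (idempotence).

Because the crossover model has no interference, genuinely tight double
crossovers occur and are indistinguishable from singleton errors: on clean
1 cM-spaced simulated maps about 0.03% of true calls are masked. This
conservative bias (shared by map-based cleaners generally) slightly
shortens even clean maps and is the reason correction can recover a little
more than the injected inflation.

## Homologous-group assignment

Each mapped SNP carries a scaffold of the (fragmented) reference. An LG ×
scaffold incidence is tallied (a scaffold is assigned to an LG with ≥ 1 of
its SNPs there; configurable); LGs are nodes of a graph whose edge weights
count shared scaffolds; edges below 2 shared scaffolds are dropped so that
one chimeric or misassembled scaffold cannot bridge two homologous groups;
connected components are the HGs. Scaffolds assigned to more LGs than the
ploidy (> 6) are flagged chimeric and excluded from edge weighting. HGs and
then LGs within HGs are numbered by descending map length, ties broken by
marker count then label.

## Simulator

The simulator generates what the pipeline consumes and nothing more:

* **Founder**: C chromosomes × 6 homologs; loci evenly spaced in bp with
  genetic position proportional to bp (only relative order matters
  downstream); simplex carriers cycle through the homologs so each homolog
  gets an even ladder; higher dosages draw random carrier subsets from a
  configurable dosage-class mix.
* **Meiosis**: bivalent pairing uniform over the 15 pairings; crossovers per
  transmitted strand ~ Poisson(L/100) with uniform positions, no
  interference, no double reduction. Brute-force enumeration of pairings
  fixes the cross-homolog co-transmission probability at 1/5, which the
  sampler reproduces.
* **Read depths**: per-cell total depth ~ negative binomial (mean 80,
  dispersion 10 by default — RAD-seq-like overdispersion; the exact family
  is irrelevant downstream), ALT reads binomial with success
  (d/6)(1−ε) + (1−d/6)ε, cells dropped at a configurable missing rate.
* **Reference**: chromosomes fragmented at uniform breakpoints into
  ~length/N50 scaffolds; a configurable fraction of chimeric scaffolds
  fuses segments of two chromosomes to exercise the chimera flagging.
* **Output**: VCF 4.2 with VarScan-dialect `GT:DP:RD:AD` genotype fields
  (AD scalar = variant-supporting depth), scaffold table, truth tables,
  and a config snapshot; one seed per operation.

The standard verification study is 15 chromosomes × 6 homologs × 30
simplex loci per homolog, 100 cM / 2 Mb chromosomes, n = 142, depth mean
80, ε = 0, no missing data; the error-correction study uses 5 chromosomes
(and the correction unit tests a denser 1 cM spacing) to keep run times in
minutes. These sizes are the package's own verification choices.

What the simulator does **not** emulate: read-level artifacts (alignment
error, allele-specific bias, paralog collapse), depth correlation between
neighbouring loci or individuals, segregation distortion, multivalent
pairing or double reduction, and real assembly error beyond simple
two-chromosome chimeras. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated genetic model, not robustness to
every pathology of real ddRAD data.

## Known limitations

* All markers of a homolog share one segregation draw, so the 1:3 test can
  reject a clustered run of markers of one lineage; on the standard study
  this occasionally (roughly 3 seeds in 10) leaves 88–89 instead of 90
  groups at the ≥ 20-marker floor.
* Ordering is two-point greedy, not multipoint likelihood; very short or
  sparse groups (< 3 bins) are returned as given.
* Repulsion-phase information is used for phase reporting but is too weak
  in an S1 double-simplex design to join homologs — joining is delegated
  entirely to the physical (scaffold) layer.
* The imputation rule is local; it will not rescue long missing runs nor
  resolve calls in crossover intervals, by design.
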
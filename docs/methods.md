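# Methods

## Study design being modelled

The pipeline targets the standard map-based cloning workflow for a
monogenic recessive mutant in a selfing crop: cross mutant × divergent
line, self the F1, and use the F2 two ways. First, two phenotype-selected
bulks (mutant vs normal) are RNA-sequenced and SNV allele frequencies
compared between pools to localise the causal chromosome region. Second,
the recessive-phenotype F2 individuals — whose genotype at the trait locus
is known exactly — are genotyped at markers inside the region to fine-map
the locus between flanking recombinants, after which genes in the interval
are inspected for a causal variant and its expression measured by qPCR.

## Bulked-segregant scan

For a biallelic SNV the ED statistic over the two pools' (alt, ref)
frequency vectors reduces to √2·|Δf|, so it ranges over [0, √2] with
expectation ≈ 0 at unlinked sites and a maximum near the causal locus,
where recessive selection fixes the mutant allele in the mutant bulk
(f ≈ 1) while the wild bulk remains at ≈ 1/3 (the frequency of the mutant
allele among phenotypically normal F2 genotypes). ED is raised to k = 5;
any odd power preserves ranking (selection before and after the transform
is identical — asserted as a property test) but steepens the contrast
between sampling noise and linkage signal in plots and in the tail of the
distribution.

Processing order and defaults:

1. **Depth filter** — coverage strictly greater than `min_depth = 3` reads
   in *each* pool (a site at 4× in both pools passes, 3× fails). The filter
   is per-pool rather than on the combined depth; both the threshold and
   this convention are configurable.
2. **Frequencies and ED^k** per SNV.
3. **Top-quantile threshold** — the selection is the top `q = 0.01`
   fraction of ED^k genome-wide (not per chromosome), nominal size
   ceil(q·n), with ties at the boundary all included so equal evidence is
   never silently dropped.
4. **Region calling** — per chromosome, selected SNVs closer than
   `max_gap_bp = 2,000,000` chain into clusters; clusters with at least
   `min_snv = 5` members are reported as [min pos, max pos] intervals. The
   defaults are sized so that a single strong linkage block at BSA
   resolution (several Mb) merges into one region. No sliding-window
   smoothing enters the calls; a rolling-mean overlay exists for plotting
   only.

A consequence of these defaults worth knowing: on data with *no* causal
locus, the top 1% of SNVs is still selected by construction, and at typical
simulated densities (60 selected SNVs over 90 Mb, mean spacing 1.5 Mb <
max gap) random chains can merge into sizeable regions. The discriminating
signature of a real locus is therefore concentration, not mere existence,
of regions: in the simulations the causal region captures the majority of
all selected SNVs, while under the null no chromosome or region does. The
test suite asserts exactly this contrast.

## Segregation tests

Pearson χ² = Σ(obs − exp)²/exp without continuity correction, df = classes
− 1, compared to the α = 0.05 critical value (3.84 at df = 1); the Yates
correction is available behind a flag. Ratios are reported as x:1 to three
decimals. The conclusion is "fits" iff χ² < critical value.

## Fine mapping

Within the recessive-homozygote mapping population each individual
contributes two scoreable gametes. Marker codes map to recombinant-gamete
counts A→0, H→1, B→2 (U excluded from N); this gamete-level weighting is
what makes r = recombinants/(2N) reproduce sub-centimorgan distances when
the field reports "recombinants" as individuals. Distances use Kosambi's
function, cM = 25·ln((1+2r)/(1−2r)); its relative deviation from the
linear 100·r is 4r²/3 + O(r⁴), i.e. negligible (< 0.01%) for the r < 0.005
range where fine mapping operates. r ≥ 0.5 is an error (infinite
distance); r > 0.5 from noisy counts is flagged as unlinked.

Side assignment uses recombinant-individual identity: a crossover between
the locus and a marker makes the same individual recombinant at every
marker further out on that side, so same-side markers have nested
recombinant sets while opposite-side markers have disjoint ones. The
implementation sorts informative markers by position and splits them at
the point minimising the number of recombinant individuals shared across
the split; individuals recombinant on both sides (double crossovers, or
genotyping errors masquerading as them) are listed as conflicts rather
than silently resolved. The interval runs between the innermost marker of
each side; zero-recombinant markers co-segregate and are checked to fall
inside it. Degenerate inputs: all markers co-segregating returns status
"unresolved" (not an error); a single informative marker cannot flank the
locus and is fatal. Tables not restricted to recessive homozygotes are
rejected unless forced. Physical span is (end − start + 1)/1000 kb with
1-based inclusive coordinates.

## Candidate annotation

Gene extraction uses an any-overlap rule (one shared base suffices) —
"fully contained" would be the only alternative and is not what interval
browsers report. SNP classification maps the genomic position to the
spliced CDS coordinate, respecting strand (coordinates counted from the 3′
genomic end and alleles complemented on −), derives codon number and
within-codon position, translates reference and alternate codons with the
standard nuclear genetic code, and classifies synonymous / missense /
nonsense; positions in introns or UTRs are non_coding, and a reference
mismatch against the supplied genome is fatal. Exon numbering follows
transcription order. Amino acids are reported as 3-letter codes ("Ter" for
stop). Co-segregation under the recessive model requires phenotype mutant
⇔ genotype homozygous-mutant for every tested individual.

## qPCR

Per replicate ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the mean
ΔCt of the calibrator group within the same tissue; relative expression is
2^−ΔΔCt. A group is summarised as 2^−(mean ΔΔCt), which makes the
calibrator exactly 1 by construction (the arithmetic mean of replicate
folds would exceed 1 under noise, by Jensen's inequality); the sd is taken
over replicate-level folds, and replicate folds — not group means — feed a
two-sided Welch t-test against the calibrator (Student's pooled variant
behind a flag), significant at α = 0.05. Zero-variance degenerate inputs
are guarded (equal means → p = 1). Tissues lacking calibrator replicates
are skipped with a warning.

## Synthetic data generator

`simulate_f2` draws, per gamete and chromosome, a Poisson(L/100) number of
crossovers placed uniformly in genetic coordinates — a no-interference
(Haldane) meiosis — with a fair-coin starting phase; phenotype is mutant
iff both gametes carry the mutant-parent allele at the causal locus. The
cM↔bp map is linear per chromosome (constant recombination rate). Defaults:
3 chromosomes of 100 cM / 30 Mb, causal locus mid-chromosome A01, 600 F2
individuals, bulks of 50, 20× mean depth, 2,000 SNVs per chromosome,
sequencing error 10⁻³ applied symmetrically per read. These mirror a
realistic BSR-Seq design for a single recessive gene: bulks of ~50 are the
common practice and at that size the mutant bulk is fully fixed at the
causal locus, while 20× Poisson depth per pool reproduces the binomial
frequency noise that the ED⁵ transform is meant to suppress.
`simulate_bulks` records the true pool frequencies alongside the sampled
counts. `simulate_marker_genotypes` reads codes directly off the stored
gametes (no genotyping error model). `simulate_qpcr` shifts the mutant
target Ct by −log2(fold) and adds Gaussian noise per Ct.

What the simulator does *not* emulate — and hence what passing tests do not
establish about real data: crossover interference (simulated distances are
Haldane; at the sub-cM scale recovered here the Kosambi–Haldane discrepancy
is far below marker resolution), locally varying recombination rate,
expression-dependent RNA-seq coverage (depth is independent of genotype and
position, whereas BSR-Seq depth tracks transcription), allele-specific
expression bias, genotyping error in marker assays, and segregation
distortion. Determinism: every stage derives its generator from
(stage-tag, seed) so the same seed yields bit-identical outputs regardless
of which stages are run.

## Problem sizes used in validation

The recovery experiments run 100 replicates each: the scan on the default
design above (6,000 SNVs, bulks of 50, depth 20, causal locus placed at
random) and fine mapping on single-chromosome populations of 6,800 F2
(~1,700 mutants, trimmed to the 1,575 used for counting) with markers every
0.2 cM across ±2 cM of the locus. Monte-Carlo checks use 300 qPCR
replicates (fold 4, sd 0.2) and 1,000 null t-tests. These sizes give
binomial standard errors of ≤ 2 percentage points on the recovery rates
while keeping the full validation run to a couple of minutes.

## Known limitations

- The ED formula is the biallelic two-component form; multiallelic records
  are excluded at parse time rather than generalised.
- Region boundaries are the outermost selected SNVs of a cluster, so the
  reported region can only shrink relative to the true linkage block as SNV
  density falls.
- Side assignment assumes one locus on one chromosome; multi-locus traits
  and marker-order errors surface as conflicts, not corrections.
- The qPCR model has no amplification-efficiency correction (2^−ΔΔCt
  assumes ~100% efficiency for target and reference alike).
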
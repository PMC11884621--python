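# Methods

`globintyper` reimplements the bioinformatics core of a targeted long-read
sequencing (T-LRS) assay for the globin gene clusters: multiplex long-range
PCR amplicons are sequenced as high-fidelity CCS reads, genotyped for
thalassemia-relevant structural and small variants, phased within each
amplicon, and analysed at population scale (haplogroups, LD, TFBS screening,
genotype–phenotype association). Everything is verifiable against a bundled
synthetic-data generator that emits machine-readable truth.

## The amplicon model

An amplicon is a primer pair plus a reference interval; its expected product
length is `end − start` (0-based half-open coordinates throughout; VCF
output is 1-based). Because every CCS read is a full-length PCR product, two
observables carry the structural signal:

* **which primer pair** matches the read's termini (read → amplicon
  assignment), and
* **the read length**, whose deviation from the expected product length
  reveals deletions (shorter), duplications (longer) or — when a primer
  site itself is lost — amplicon dropout, the gap-PCR signature of
  whole-cluster deletions.

Primer matching is a windowed Hamming scan (window 50 bp, ≤ 2 mismatches per
primer by default, no indels inside the primer window) over both strands; a
read matching two amplicons equally well is left unassigned with an
ambiguity flag.

## The synthetic mini-reference

Real globin clusters contain paralogous units (HBA2/HBA1, HBG2/HBG1) that
are nearly identical over ~4 kb. The mini-reference reproduces that
geometry with three contigs:

* `alpha` — two 4,000-bp paralogous units separated by a 100-bp spacer,
  differing at exactly `n_diagnostic` (default 40) positions;
* `gamma` — the same structure with 3,400-bp units and a 272-bp spacer;
* `mod` — a plain 3,000-bp modifier-gene-like contig.

The default panel places a 7,122-bp amplicon over the gamma pair and an
8,135-bp amplicon over the alpha pair — the fragment sizes of the real
assay — plus a wider 8,800-bp "spanning" amplicon whose primers survive the
largest catalogued alpha deletion, and a 2,500-bp modifier amplicon.
Diagnostic positions are drawn uniformly per seed; the generator is
deterministic given its seed, and the Hamming distance between units equals
`n_diagnostic` exactly by construction.

The default allele catalog has 23 entries mirroring a routine-PCR-style
panel: 13 SNVs, 4 small indels, and 6 structural alleles (unit deletions of
3.7/4.2 kb, a 3.7-kb duplication, an 8.3-kb whole-cluster deletion that
removes the internal alpha amplicon's primers, an unequal-crossover
rearrangement with a +500-bp net shift, and a 4.9-kb deletion joining the
two gamma units). One SNV pair sits at homologous offsets of the two alpha
units to exercise paralog-specific assignment.

## Read simulation

Per haplotype, catalogued events are applied to the reference
(`apply_events` maintains a reference→mutated coordinate map), products are
amplified in silico (primer search with the same mismatch budget as the
caller; internal deletions shorten the product, primer loss drops it), and
full-length reads are emitted with independent per-base substitutions and
short indels at CCS-like rates (defaults 0.3% substitutions, 0.05% each
indel class; rates are capped at 5%). Half the reads are
reverse-complemented. `depth` is the per-product read count (fixed or
Poisson), so a heterozygous sample sees ~2× `depth` reads per amplicon.

Small events drawn on the same haplotype as an overlapping structural event
are dropped (the truth records only applied events); alpha-cluster
structural alleles are mutually exclusive per haplotype (drawn
categorically). Cis configurations of a small variant inside its own
haplotype's SV interval are therefore not simulated — a deliberate
simplification.

Phenotypes follow an additive model: HbF (g/L) and ferritin (µg/L) are
intercept + Σ(effect × dosage) + Gaussian noise (clipped at 0; defaults
place HbF at 6 ± 2 g/L so clipping is negligible), and transfusion-free
survival is exponential with hazard `h₀·exp(Σ log-HR × dosage)`, censored at
a Uniform(2, 30)-year follow-up age. Founder haplotypes for the gamma
fragment (three clades over 12 non-catalog SNPs, with 1% per-locus mutation
noise) plant a clade structure for haplogroup recovery; the most frequent
founder carries a +4 g/L HbF effect and a protective transfusion hazard.

What the generator does **not** model: homopolymer-biased CCS errors,
chimeric reads (available as an option but off by default), depth variation
between amplicons of one sample, barcode demultiplexing, and cis SNV+SV
haplotypes. Passing tests therefore demonstrate the pipeline's logic under
idealized error structure, not its robustness to instrument-specific
artefacts.

## Structural-variant calling

Per sample × amplicon, read lengths are split into a REF-like bin
(|observed − expected| ≤ tolerance, default 100 bp) and shifted clusters
(1-D gap clustering at the tolerance). Each cluster with ≥ 3 supporting
reads becomes a call with `length_shift` = median observed − expected
(negative for deletions, positive for duplications); it is matched to the
catalog when the shift agrees within the tolerance and the sign matches,
else classed `novel`. Genotype comes from the cluster's read fraction —
`hom` at ≥ 0.9, `het` inside [0.25, 0.75] — so compound heterozygotes (two
shifted clusters, no REF-like reads) genotype correctly. An amplicon with
no reads in an otherwise covered sample is a dropout call, interpreted
jointly with catalogued spanning deletions. The het/hom windows are the
package's own documented choice; nothing in the assay fixes them.

### Split-read breakpoints

Deletion breakpoints are refined per supporting read by two-anchor split
alignment: a 400-bp prefix anchor and suffix anchor are placed by infix
alignment, giving two mapping offsets whose difference is the deletion
size. This is deliberate: a single global unit-cost alignment *scatters*
the gap when the deletion joins two paralogous units (the read's flank
matches the homologous unit at only a few diagnostic mismatches), whereas
the offset difference is invariant to that ambiguity. The switch point
from prefix to suffix mapping is chosen to minimize total mismatches; the
leftmost optimal switch is the left-normalized breakpoint, and the span of
optimal switch points is the junction microhomology. Reads with indel
errors fall back to a banded offset DP (±5 offset band, distance-transform
per step) that absorbs CCS-rate indels. Per-read breakpoints are
aggregated by majority over up to 6 reads (≥ 3 required).

## Small-variant calling

Reads are globally aligned to their amplicon reference with a banded
edit-distance aligner (edlib). Gap placement from the aligner is not
trusted: differences are extracted as variant records and left-normalized
(leftmost equivalent placement, minimal representation), and clusters of
gaps separated by ≤ 10 aligned bases are collapsed to a single indel when
an equal-cost contiguous representation exists — unit-cost aligners
otherwise split indels beside repeats into placements that never match a
catalogued allele. Alignment identity < 70% excludes a read from the
pileup.

Reads in a shifted (SV) cluster are aligned against an *SV-adjusted*
reference (the catalogued event, or the refined breakpoint for novel
deletions, applied to the reference) and their observations lifted back to
amplicon coordinates. The lifted coverage spans the deleted interval, so a
deletion-carrying haplotype counts as reference-allele coverage there and
an SNV in trans still genotypes as heterozygous; a duplication's second
copy is dropped during lifting so the region is counted once.

Genotyping is per column by allele fraction: alt alleles need fraction
≥ 0.2 and ≥ 5 supporting reads; het inside [0.25, 0.75], hom at ≥ 0.9,
anything else `AMBIGUOUS`. Columns below **20 reads emit only non-PASS
`LOW_DEPTH` records — the assay's hard depth rule**; the suite asserts no
PASS call ever violates it. When the same catalogued allele is reported by
two amplicons with conflicting zygosity, the deeper-covered amplicon wins
and the annotation is flagged: when a whole-cluster deletion removes one
haplotype's product from an internal amplicon, only the spanning amplicon
still sees both haplotypes.

## Phasing

Full-length amplicon reads make diploid phasing a 2-clustering problem
under the minimum-error-correction (MEC) objective, not fragment assembly.
Instances with ≤ 12 reads are solved exactly by bipartition enumeration;
larger ones by consensus-pair seeding from the distinct read rows (up to 30
seeds) with iterative reassignment. Ties break toward the
lexicographically smaller consensus pair, and cluster 1 is the
lexicographically smaller consensus, making output invariant to read input
order. Where MEC leaves the two consensus haplotypes equal at a het site,
the weaker-supported cluster is flipped so haplotypes always differ at het
sites. A cluster below 3 reads flags the sample unphased for that
amplicon; a sample with no het site yields two identical flagged
haplotypes. Phasing across amplicons is not attempted — the products are
independent molecules.

Paralog assignment labels each variant by the annotated unit interval
containing it ("intergenic" outside both); a variant independently called
at the homologous offset of both units is reported in both genes. Gene
conversion is a maximal run of ≥ 3 (configurable) consecutive diagnostic
positions carrying the donor paralog's allele on one haplotype; tract
bounds are the outermost switched sites, resolvable only to the flanking
inter-diagnostic intervals.

## Population analytics

The haplotype matrix has one row per phased haplotype (two per sample;
unphased samples excluded and counted) and one 0/1 column per segregating
locus. Rows are de-duplicated with multiplicity and the unique rows
clustered by complete-linkage agglomeration on 1 − Pearson correlation
(the scheme heatmap tooling applies to such matrices; Hamming distance is
available as an option). Pairs with undefined correlation (constant rows)
are set to the maximum distance 2.0 and logged. The group count defaults
to the largest relative merge-height gap over k = 2..8 and can be fixed
explicitly; groups map back to all rows and are labelled `Hap_s1`,
`Hap_s2`, … by descending size.

LD is computed directly from phased haplotype counts: D = p_AB − p_A·p_B,
r² = D²/(p_A(1−p_A)p_B(1−p_B)), D′ = D/D_max, after excluding loci with
MAF < 0.01; blocks are maximal runs of consecutive loci with all pairwise
r² ≥ 0.8. The TFBS screen tests each SNV on both strands against IUPAC
consensi of five erythroid regulators (GATA1 `WGATAR`, KLF1 CACCC-box
`CCMCRCCCN`, NF-Y `CCAAT`, TAL1 E-box `CANNTG`, BCL11A `TGACCA`, the
commonly used literature forms) — a site matching with the reference but
not the alternate base is `destroyed`, the converse `created`. Consensus
matching, not PWM scoring, is intentional; PWM support is a possible
extension.

## Association

Per-variant association is a linear model `phenotype ~ dosage + age + sex`
(identity link; covariates configurable) with Wald tests and
Benjamini–Hochberg step-up FDR across all tested variants; monomorphic,
rare (MAF < 0.01), under-powered (n < 10) and singular designs are skipped
with recorded reasons. Group contrasts: two-sided Student t between
groups, a one-sample t-test for very rare carriers against a reference
mean, and one-way ANOVA with Dunnett-adjusted comparisons against a
control group. Transfusion-free survival (age at first transfusion,
right-censored at last follow-up for never-transfused patients) is
compared across haplogroups by Kaplan–Meier estimation with the log-rank
test; each patient is assigned the lowest-numbered (largest) haplogroup
among their two haplotypes. The burden score counts catalogued beneficial
alleles per sample, with the phenotype trend fit by OLS on the score.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) regenerates everything
from scratch: a 200-sample cohort at 40× per amplicon and ~0.6% error for
detection sensitivity/specificity; a 100-sample cohort for 23-allele
catalog concordance; an error-free 40-read sample for split-read sizing of
the 4.9-kb gamma deletion; and a 1,020-sample gamma-fragment cohort at 30×
per sample for the 2,040-row haplotype matrix. These sizes were chosen as
the smallest at which the corresponding claims are meaningful at cohort
scale while remaining desk-scale reproducible on one CPU. All randomness
flows from the `--seed` argument through `numpy.random.default_rng`; reruns
are byte-identical.

## Known limitations

* Genotype windows (het [0.25, 0.75], hom ≥ 0.9) are heuristics tuned for
  amplicon data with balanced allele sampling; heavily skewed PCR would
  need likelihood-based genotyping.
* Mosaic fractions, somatic calling and quality recalibration are out of
  scope; SVs smaller than the length tolerance are left to the
  small-variant caller.
* Breakpoints of duplications are inferred only coarsely (largest
  insertion run of a single read) for reference adjustment; only deletion
  breakpoints are refined and reported.
* The crossover allele class is matched by net length shift; its internal
  structure is taken from the catalog, not re-derived from reads.
* Pathogenicity tiering of novel variants is not attempted — annotation is
  catalog lookup.
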
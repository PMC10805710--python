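# Methods

This note documents the models, algorithms and parameter choices behind
`haplarith`: what is computed, under which assumptions, and where the
design was genuinely open.

## Inputs and coordinate system

All per-SNP data live on a `SnpMap`: biallelic SNPs sorted by
(chromosome, bp), chromosomes in karyotype order. The default synthetic
karyotype is equine-like — 31 autosomes with lengths falling linearly from
190 Mbp to 30 Mbp plus a 130 Mbp X — and is fully config-overridable;
nothing downstream depends on these lengths beyond crossover counts and
plot geometry. Sample measurements (genotype call AA/AB/BB/NC, BAF, LogR)
are read from tab-separated GenomeStudio-style exports; numeric fields are
written with 6 decimals, which bounds round-trip error. An optional
`GC Score` column is thresholded at 0.75 (configurable), mirroring the
common genotype-quality filter applied upstream; rows below it keep their
numeric channels but lose the discrete call.

## Phasing

Two deterministic Mendelian routes assign each parent's AB alleles to
homologue 1 vs homologue 2:

* **Grandparents.** At a parent-AB SNP the assignment "grandsire
  transmitted A" is possible iff the grandsire can carry A and the
  granddam can carry B (NC is permissive). Exactly one possible assignment
  resolves the SNP with H1 := the grandsire-derived allele; zero marks a
  Mendelian-impossible trio (counted, unresolved); two is ambiguous.
* **Sibling embryo.** Where the parent is AB, the other parent homozygous
  and the sibling called, the sibling allele not attributable to the other
  parent is the transmitted one and defines H1. Homologue labels are
  therefore relative to the sibling's *recombinant* transmitted strand:
  block switches in other embryos appear wherever either strand
  recombined. This is fine for PGT — only consistent labels matter — but
  it means breakpoint counts are embryo+sibling crossovers, not embryo
  crossovers alone.

On the X chromosome a male sibling is hemizygous; the array renders its
single maternal allele as a homozygous diploid call, which under the
diploid rule looks Mendelian-inconsistent whenever it differs from the
homozygous father. Sibling-based maternal phasing therefore treats
X-chromosome sibling hom calls as directly naming the transmitted allele.
Without this the maternal X track loses the SNPs of one subtrack and male
X classification degenerates.

No population/statistical phasing is attempted; unresolved SNPs are simply
non-informative.

## Haplarithm construction

At informative SNPs (target parent AB and phased, other parent homozygous,
embryo BAF present — the embryo's *discrete* call is ignored, NC included),
the folded BAF `f = |BAF − b₀|` is assigned to subtrack P1 if the target
parent's H1 allele differs from the other parent's allele, else P2. For a
homologue-copy configuration (m₁, m₂, p₁, p₂) with total n, the expected
levels are m₁/n and m₂/n (maternal subtracks), p₁/n and p₂/n (paternal),
with LogR = log₂(n/2).

Subtracks are segmented **jointly** per chromosome (shared breakpoints):
a segment's cost is the sum of each subtrack's within-segment squared
error, minimised with a penalised exact search (PELT, L2 cost). Both
copy-number changes and homologue switches move the two levels together,
and shared breakpoints simplify the joint classification downstream.

**Penalty.** `penalty = max(6 · σ̂² · log n, 0.05)` per changepoint, with
σ̂ estimated from median absolute successive differences *within* each
subtrack (cross-subtrack differences reflect the level offset, not noise).
The floor keeps the penalty positive so noise-free data yields the minimal
exact segmentation. The hard minimum segment length in the search is 1
point — the penalty, not a size constraint, prevents over-segmentation;
with a size floor of several SNPs, two crossovers falling within a few
informative SNPs provably contaminate segment means even on noise-free
data. `min_seg_snps = 10` is retained as a *support* threshold: a
chromosome with fewer informative SNPs gets one low-support segment.

**Blocks.** Segment levels map to an inherited label: both subtracks ≤ tol
(default 0.1) → `none` (lost parental chromosome); one ≈ 0 and the other
≥ 0.2 → `H1`/`H2` (the 0.2 presence floor admits the legitimate non-0.5
levels 1, ⅔, ⅓ arising under monosomy of the other parent or trisomy);
comparable non-zero levels → `both` (heterodisomy); anything else
`undetermined`. Adjacent same-label segments merge; recombination
breakpoints are H1↔H2 transitions, placed midway between the flanking
informative SNPs.

## Copy-number, mosaicism, ploidy, sex

Per chromosome, the union of LogR-track and subtrack breakpoints (clustered
within 2 Mbp) defines classification intervals. Each interval's five
observables — mean LogR, maternal P1/P2, paternal P1/P2 (a subtrack needs
≥ 3 SNPs in the interval, else it is unavailable, as on the male X where
the hemizygous father has no heterozygous SNPs) — are matched to the
nearest configuration by root weighted mean squared deviation (all weights
1 by default). Acceptance tolerance 0.1; ties break towards the smallest
copy-number change from disomy, then maternal before paternal (arbitrary,
documented). Configurations are enumerated to total copy number 4.

If no pure configuration fits, a two-component mixture of disomic and
aberrant cells is fitted: LogR mixes through mean copy number
`n(ρ) = 2ρ + n_a(1−ρ)` and subtracks through copy-weighted pooled allele
fractions. The disomic fraction ρ is found by grid search (201 points;
equivalent to continuous optimisation at the reported precision). A
mosaic is called when the mixture fits within tolerance, improves on the
best pure fit ≥ 2-fold, and the aberrant fraction lies in [0.2, 0.8] —
the source analyses describe mosaicism only qualitatively ("deviating from
expected values"), so these thresholds are this package's documented
defaults, not a claim about any other implementation.

Intervals then merge by state; slivers shorter than 5 Mbp are absorbed
into their larger neighbour (minimum reportable segment). The chromosome
state is the state covering the largest total span (< 50 % → `segmental`);
an interval whose LogR matches a non-disomic level but whose subtracks
confirm nothing is reported as `undefined_parental_origin` rather than
given an arbitrary parent.

**Heterodisomy and ploidy.** A chromosome is heterodisomic when intervals
with both homologues of one parent (m₁,m₂ ≥ 1 or p₁,p₂ ≥ 1) cover ≥ 20 %
of its length; judging by span suppresses boundary-interval misfits. The
genome label follows the modal (maternal, paternal) pattern over autosomes
(≥ 80 % required; < 90 % of chromosomes callable → `undetermined`;
otherwise `complex`): (1,1) biparental diploid, (2,1) digynic triploid —
*meiotic* if ≥ 25 % of trisomic chromosomes are heterodisomic (two
distinct transmitted genomes), else *mitotic* (one duplicated genotype) —
(1,2) diandric mirror, (1,0)/(0,1) gynogenetic/androgenetic haploidy,
(2,0)/(0,2) genome-wide uniparental disomy.

**Sex** is the X copy-number pattern: one maternal X → male, biparental
XX → female, anything else undetermined (triploid embryos are thus
deliberately unsexed). The male X is reported with the same state
vocabulary as autosomes, i.e. `paternal_loss` for (1,0).

**Event origin across samples.** For multiple samples of one embryo, an
identical event (chromosome, state) in all samples is meiotic; one in a
strict subset of blastomeres is mitotic; one present in a trophectoderm
biopsy but absent from its whole blastocyst is low-grade mosaicism. A
single sample leaves origins undetermined.

## PGT-M locus calls

The haplotype block overlapping a locus gives the inherited homologue per
parent. Inconclusive reasons, in precedence order: parental copy number 0
at the locus → `no_heterozygosity`; a recombination breakpoint inside the
locus interval → `recombination_at_locus`; a breakpoint-bounded flank with
zero informative SNPs between the breakpoint and the locus →
`no_informative_snps` (a detected switch is only localised to the gap
between its flanking informative SNPs, and an empty flank means that gap
may contain the locus); no supporting informative SNPs in the containing
block → `no_informative_snps`; a `both`/`none` block (duplicated or lost
homologues — no single haplotype to read) → `no_heterozygosity`. Flanking metrics report the distance in bp and the
informative-SNP count from each locus edge to the nearest breakpoint or
chromosome end. The five default loci carry the classic equine PGT-M gene
names (*B3GALNT2*, *PLOD1*, *MUTYH*, *STX17*, *GBE1*) but **synthetic**
placeholder coordinates on the synthetic karyotype; real analyses must
supply assembly coordinates via the locus table.

## The simulator and what it does (not) show

Founder haplotypes draw each allele independently from per-SNP population
B frequencies (uniform on [0.05, 0.95] by default), giving ~36 %
heterozygosity and ~20k informative SNPs per parent on a 70k array —
matching the scale reported for sibling-phased arrays. Meiosis uses
Poisson crossovers at 1 per 100 Mbp, uniform positions, no interference,
no obligate crossover; nondisjunction transmits both homologues (MI, each
independently recombined — genome-wide heterodisomy) or a duplicated
recombined strand (MII — isodisomy); nullisomic gametes model meiotic
losses. Embryos are collections of cells: meiotic events enter through
the gametes and are shared by construction; mitotic plans apply
whole/segmental gains/losses or genome duplication to cell subsets.

Measurement: each allele of each copy in each sampled cell survives WGA
with probability 1 − ADO independently; pooled surviving counts give the
ideal BAF (k/n levels exactly) and the thresholded genotype composition
(< 0.15 → AA, > 0.85 → BB, else AB); the *true* mean copy number of the
sampled cells gives the ideal LogR, floored at −5 for zero copies (log₂ 0
is undefined; the constant is documented, arbitrary, and far below any
real level). Gaussian dispersion (BAF truncated to [0, 1]), random
genotype miscalls and missing calls are layered on top. Defaults:
ADO 0.2/cell, miscall 0.005, missing 0.05, BAF sd 0.05, LogR sd 0.15;
biopsies pool 10 of 20 cells; bulk parental DNA uses a near-noiseless
profile without ADO. Pooling dilutes ADO with cell count, which is why
simulated single blastomeres show the high Mendelian-inconsistency rates
characteristic of single-cell WGA while multi-cell samples do not.

Male embryos carry one maternal X and no Y probes exist; a male founder's
X is stored with its single haplotype duplicated so it renders as
homozygous diploid calls, as a clustered array export would show.

Not emulated: GC-content-dependent amplification bias and wave artifacts,
correlated (segmental) ADO, cross-contamination, population linkage
disequilibrium (founder alleles are independent across SNPs), genotyping
intensity clusters (BAF/LogR are generated, not derived from raw
intensities), and real assembly coordinates. Passing recovery tests on
these simulations therefore demonstrates the *inference logic* under a
realistic noise magnitude, not robustness to every artifact of real
arrays.

## Problem sizes used in tests and the acceptance script

Unit tests run on 4–16k-SNP maps; the end-to-end recovery panel uses the
full 70k-SNP array with 20 embryos spanning euploidy, meiotic
monosomies/trisomies (MI and MII), mitotic mosaics (aberrant cell
fractions 0.4–0.5 in the biopsy) and digynic triploidy of both origins;
phasing-recovery runs use a 400k-SNP map so that > 10⁵ SNPs resolve.
These sizes are the package's chosen study conditions; the simulator and
analysis scale linearly in SNP count.

## Known limitations

* Copy numbers above 4 are not modelled (signatures converge and array
  saturation makes them unreliable); such regions collapse to the nearest
  enumerated state.
* Mosaic fractions outside [0.2, 0.8] are by design not called mosaic; a
  low-grade mosaic in a biopsy is only recoverable through the
  multi-sample origin comparison.
* Sibling-anchored phase makes homologue labels sibling-relative;
  grandparent-anchored labels are grandsire-relative. The two conventions
  cannot be mixed within one parent.
* With one unphased parent (grandparent mode without a sibling), that
  parent's haplarithm track is empty: its homologue-level calls and
  locus haplotypes are undetermined, and copy-number calls rest on LogR
  plus the phased parent's subtracks.
* The mixture model assumes exactly two cell populations (disomic +
  one aberration); biopsies mixing three or more karyotypes classify as
  `complex`/`undetermined` at the affected intervals.
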
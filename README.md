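# haplarith

Genome-wide haplotyping and copy-number profiling — *haplarithmisis* — for
SNP-array preimplantation genetic testing (PGT), with a bundled synthetic
embryo simulator.

## The problem

In vitro-produced embryos (the package defaults model the equine case: 31
autosomes + X, a ~70k SNP genotyping array) are screened before transfer
for two things at once:

* **PGT-A** — whole-chromosome and segmental aneuploidies, genome-wide
  ploidy errors (digynic/diandric triploidy, haploidy, genome-wide
  uniparental disomy), their parental origin and their meiotic vs mitotic
  mechanism;
* **PGT-M** — which parental haplotype the embryo inherited at genes of
  interest (disease or trait loci), inferred from flanking informative
  markers rather than direct genotyping, which is unreliable after
  whole-genome amplification of a few cells.

Both come from one analysis. Parental genotypes are phased with pedigree
samples (paternal grandparents or a sibling embryo). At *informative* SNPs
— one parent heterozygous AB, the other homozygous — the embryo's B-allele
frequency (BAF) is folded towards the homozygous parent's allele,
`f = |BAF − b₀|` with `b₀ ∈ {0, 1}`, and split into two subtracks **P1**
and **P2** by which parental homologue carries the discriminating allele.
For a configuration with `m₁`/`m₂` copies of the maternal homologues and
`p₁`/`p₂` of the paternal ones (total `n`):

```
LogR           = log₂(n / 2)
maternal P1,P2 = m₁/n , m₂/n
paternal P1,P2 = p₁/n , p₂/n
```

so biparental disomy sits at LogR 0 with subtrack levels {0.5, 0} (a 0.5
parental-BAF distance), monosomy at LogR −1 with levels {0, 1}, trisomy at
LogR log₂(3/2) ≈ 0.58 with levels {0, ⅓, ⅔, 1}, tetrasomy at LogR 1 with
levels {0, ¼, ½, ¾, 1}. Segments are classified to the nearest
configuration; mixtures of disomic and aberrant cells (mosaicism) are
fitted as a two-component model; heterodisomic spans (both homologues of
one parent present) distinguish meiosis-I-type extra genomes from
duplicated single genotypes.

Because the corresponding real per-sample arrays are not publicly
deposited, the package ships a first-class simulator: pedigree founders
with known phase, Poisson-crossover meiosis with MI/MII nondisjunction,
multi-cell embryos with shared meiotic and cell-private mitotic events,
and an array measurement model with per-allele amplification dropout
(ADO), genotype miscalls, missing calls and BAF/LogR dispersion. Every
test compares analysis output against exact simulation truth.

## Worked example

```bash
haplarith simulate --seed 5 --n-snps 70000 --out demo/
haplarith run --config demo/run_config.yaml
```

`simulate` writes GenomeStudio-style sample tables for the pedigree
(mother, father, grandparents, a sibling blastocyst) and a 20-embryo panel
plus `truth.json`; `run` executes phasing → haplarithm → copy-number →
reporting and prints, e.g.:

```
analyzed 20 samples (20 ok); summary at demo/analysis/summary.tsv
```

`summary.tsv` holds one row per embryo sample (abridged columns):

```
sample_id        status  call_rate  mendelian_inconsistency_rate  n_informative_snps  ploidy                    sex     aberrations
euploid_f1       ok      0.949757   0.004122                      28499               biparental_diploid        female
mat_monosomy_31  ok      0.950671   0.005763                      28499               biparental_diploid        female  31:maternal_loss
digynic_meiotic_1 ok     0.950586   0.004224                      28499               digynic_triploid_meiotic  undetermined  1:maternal_gain;2:maternal_gain;...
```

`call_rate` is the fraction of array SNPs with a genotype call;
`n_informative_snps` counts the phased informative positions feeding the
haplarithm (tens of thousands on a 70k array with sibling phasing); the
`aberrations` column lists non-disomic chromosomes as `chrom:state` — a
maternal monosomy of chromosome 31 reads `31:maternal_loss`, a digynic
triploid shows the genome-wide `maternal_gain` pattern, and a normal male
X is reported in the same vocabulary as `X:paternal_loss` (one maternal
X, no paternal copy). Per-gene PGT-M columns give the inherited
maternal/paternal haplotype (`H1`/`H2`, relative to the sibling-anchored
phase) or `inconclusive` with a reason (lost homologue, no informative
SNPs, or a recombination site inside the locus). `haplarith plot` renders
the five-panel haplarithm figure (LogR, maternal BAF subtracks, maternal
blocks, paternal BAF subtracks, paternal blocks) and a circos-style
per-sample aberration summary.

As a library:

```python
from haplarith import analyze_sample, phase_parents
from haplarith.scenarios import simulate_suite

family, embryos = simulate_suite(seed=5, n_snps=70_000)
phased = phase_parents(family.samples["mother"], family.samples["father"],
                       sibling=family.samples["sibling"], snp_map=family.snp_map)
result = analyze_sample(embryos[0].sample, family.samples["mother"],
                        family.samples["father"], phased, family.snp_map)
print(result.ploidy.label, result.sex)   # e.g. "biparental_diploid female"
```

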
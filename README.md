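# spetpanel

Design and validation toolkit for **single primer enrichment technology
(SPET)** genotyping panels, aimed at plant and tree geneticists running
targeted SNP assays on species with a reference genome.

SPET enriches ~40-bp probe-adjacent regions around pre-selected *target*
SNPs, sequencing both the target and any *accessory* polymorphisms in
the enrichment footprint. `spetpanel` covers both ends of such a project:

* **Design** — select a budgeted set of target SNPs from a whole-genome
  variant call set under the standard assay constraints: minimum
  inter-target spacing per genomic context (5 kb within CDS, 10 kb
  intergenic), clean probe windows on both borders, flanking SNPs inside
  the enrichment footprint, alt-allele frequency in [0.10, 0.90] and no
  heterozygosity excess (a paralog-collapse proxy). Selection maximises
  the target count under the spacing constraints with an exact dynamic
  program, then ranks by informativeness when the budget binds.
* **Validation** — once the assay returns genotypes: GATK-style hard
  filtering (`QD < 2.0 || MQ < 40.0 || MQRankSum < -12.5`, mean depth,
  call rate, non-ref), target/accessory classification, folded-MAF
  spectrum comparison against the design call set (ascertainment-bias
  check via Pearson's *r* over shared sites), per-sample heterozygosity,
  marker spacing, windowed LD pruning (r² > 0.3) and LD decay,
  pseudo-testcross (CP) marker classification (lm×ll / nn×np / hk×hk),
  segregation-distortion chi-square tests, identical-locus collapsing,
  and **Mendelian-inconsistency genotyping-error estimation** in F1
  progenies.
* **Simulation** — a fully seeded generator for every input format
  (FASTA + GFF3 reference, founder VCF under Hardy–Weinberg with
  inbreeding, F1 progenies with Haldane recombination, injected error
  and missingness with truth masks), so the entire pipeline is testable
  offline with known ground truth.

## The error-rate estimator

At a marker where both parents are called, an offspring call is
*Mendelian-inconsistent* when no pair of parental gametes can produce
it. Writing the per-call error rate as ε and the per-cross-class
probability that an error is flagged as *d(class)* (the **detectable
fraction**), the expected raw inconsistency rate is

```
E[raw] = ε · Σ_class w_class · d(class)
```

with *w* the checked-call share of each class. The detectable fractions
are enumerated exactly under an explicit error model — for a uniform
genotype swap: monomorphic hom×hom *d* = 1, lm×ll and nn×np *d* = 0.5,
aa×bb *d* = 1, hk×hk *d* = 0 (every offspring genotype is producible, so
errors there are invisible). The estimator inverts the relation:

```
ε̂ = raw rate / (Σ_class w_class · d(class))
```

Raw and adjusted rates, the singleton share among inconsistent sites,
and per-class call counts are always reported together.

## Worked example

Simulate a biparental cross genotyped at 2,000 markers with 90
offspring, a 1.8% injected per-call error rate, then estimate the error
rate back from Mendelian inconsistencies and LD-prune the marker set:

```
$ spetpanel --seed 7 --out-dir demo simulate --preset cross \
      --n-sites 2000 --n-samples 6 --n-offspring 90 --error-rate 0.018
wrote reference.fasta, genes.gff3, cross.vcf, truth.json

$ spetpanel --out-dir demo progeny-qc --vcf demo/cross.vcf --p1 S001 --p2 S002
checked 179978 calls: raw 1.11%  adjusted 1.80% (uniform-swap)

$ spetpanel --out-dir demo ld-prune --vcf demo/cross.vcf
sites in: 2000  kept after pruning: 481
```

The raw inconsistency rate (1.11%) underestimates the injected 1.8%
because roughly a sixth of the markers are hk×hk (both parents
heterozygous), where errors can never be detected, and half of the
errors at single-parent-heterozygous markers land on a producible
genotype; the detectability correction recovers the injected rate. The
LD pruning reflects the strong linkage among F1 markers on the two
simulated chromosomes.

The design phase runs the same way from a simulated (or real) call set:

```
$ spetpanel --seed 7 --out-dir panel simulate --preset panel --n-sites 3000 --n-samples 60
$ spetpanel --out-dir panel design --vcf panel/founders.vcf \
      --fasta panel/reference.fasta --gff panel/genes.gff3 \
      --budget 400 --config design.yaml
candidates: 3000  eligible: 644  selected: 236
```

Every run writes a JSON manifest (version, resolved config, input
digests, seed, outputs) for reproducibility. Positions are 1-based in
VCF/TSV output and 0-based half-open in BED.

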
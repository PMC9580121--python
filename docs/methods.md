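# Methods

## Scope and data model

`spetpanel` operates downstream of read alignment and variant calling:
its inputs are a multi-sample VCF of simple biallelic SNPs (multiallelic
and indel records are skipped and counted), a reference FASTA and a GFF3
gene annotation for the design phase, and a post-assay genotype VCF for
the validation phase. Genotypes are coded 0/1/2 dosages with an explicit
missing code; internal coordinates are 0-based half-open, VCF-facing
positions 1-based, BED output 0-based half-open. Phase (`|`-separated
genotypes) is preserved on read and required only by the gamete
simulator.

## Panel design

A candidate target must satisfy, in first-fail order:

1. **maf_range** — alt-allele frequency within [0.10, 0.90] (inclusive,
   as printed on the unfolded scale; equivalent to folded MAF ≥ 0.10);
2. **het_excess** — observed heterozygosity ≤ 0.60 by default, a proxy
   for collapsed paralogs;
3. **probe_window** — `probe_len` (default 40) bases immediately 5' and
   3' of the site fully inside the chromosome and free of ambiguous
   bases;
4. **flanking_snps** — at least `min_flanking_snps` (default 2) other
   called SNPs within the enrichment footprint (`footprint_len`,
   default 150 bp), so the assay can discover accessory variants. The
   alternative reading — limiting polymorphisms *inside* the probe
   windows to protect hybridisation — is exposed as
   `max_probe_window_snps` and off by default.

**Spacing/selection.** Selected targets must be ≥ 5 kb apart when in
CDS/genic context and ≥ 10 kb when intergenic; for a mixed adjacent pair
the larger of the two class gaps applies (conservative: both
constraints hold). Because the pairwise gap depends on both members, a
left-to-right greedy scan is not count-optimal — an intergenic site can
block two closer genic sites that are mutually compatible — so
selection uses an exact dynamic program over position-sorted
candidates (suffix maxima per context class, O(n log n)), which
provably attains the maximum target count under the spacing
constraint; checking adjacent selected pairs suffices because gaps per
class are monotone. Among optimal solutions the reconstruction prefers
earliest positions, and position ties break by (ref, alt), making the
panel byte-reproducible. When the achievable maximum exceeds the
budget, candidates are re-selected greedily in global rank order
(|alt freq − 0.5| ascending, genic before intergenic, then position)
under the same spacing test until the budget binds; the ranking is a
package choice and configurable.

Probe sequences are emitted for both borders: the left probe is the
`probe_len` bases 5' of the target on the + strand; the right probe is
the reverse complement of the 3' bases, so both read toward the target.
Thermodynamic probe scoring is out of scope (vendor territory).

Post-assay, called sites are classified **target** (exact designed
position), **accessory** (within `footprint_len` of a target) or
**unassigned**.

## Site QC

Hard filtering follows the conventional GATK-style cascade with
*strict* comparisons exactly as the filter expression is written — a
site with QD = 2.0, MQ = 40.0 or MQRankSum = −12.5 passes. A site
lacking an annotation (e.g. MQRankSum is undefined at sites without het
calls) passes that rule, matching the expression engine's semantics;
`fail_if_absent` inverts this. Mean depth is the across-sample mean of
per-sample DP (a per-sample variant was considered and not needed at
this scope). "max-missing 0.90" is interpreted as ≥ 90% call rate
(missingness ≤ 0.10). Removal counts use first-match attribution in
cascade order, so they sum to the number of removed sites. The
clean-set filter keeps folded MAF strictly greater than 0.05 and is
idempotent.

## Spectra, spacing, LD

MAF spectra are folded (0–0.5), half-open bins except the last,
monomorphic sites in the first bin. The ascertainment-bias comparison
pairs folded MAFs by (chrom, pos, ref, alt) across two call sets and
reports Pearson's *r* (per-site mode, the default) or correlates the
two binned spectra (`binned` mode); both modes exist because "spectrum
correlation" is ambiguous in common usage, and the shared-site count is
always reported alongside.

LD is composite r²: squared Pearson correlation of dosages over
pairwise-complete samples, phase-free, invariant to allele relabelling;
constant vectors give an undefined (missing) value. Pruning slides a
window of `window_size` surviving sites advanced by `window_step`,
drops the lower-MAF member of any pair with r² above the threshold
(ties drop the later position) and repeats passes until stable, so the
kept set contains no offending pair within any window of consecutive
kept sites and re-pruning is a no-op. The threshold statistic is r²
(the conventional pruning scale) with an `use_r` flag for |r|
semantics. LD decay bins all within-chromosome pairs by physical
distance up to `max_decay_dist` and reports per-bin mean r² with pair
counts.

## Cross QC and error estimation

Parental genotype pairs map to CP classes: het×hom → lm×ll (seed
parent informative), hom×het → nn×np, het×het → hk×hk, identical
hom×hom → monomorphic, opposite hom×hom → aa×bb. Offspring calls are
checked against the gamete-producible genotype set (unphased);
anything missing is unchecked.

The error estimator treats every checkable (site, offspring) call —
segregating *and* monomorphic — as one Bernoulli trial. The **raw
rate** is inconsistent/checked. The **detectable fraction** of a class
is the exactly enumerated probability that a call hit by the error
process becomes inconsistent, with true offspring genotypes at
Mendelian expected frequencies. Two error models are built in:

* *uniform swap* (default): an erroneous call becomes one of the two
  other genotypes equiprobably — d = 1 for monomorphic and aa×bb, 0.5
  for lm×ll and nn×np, 0 for hk×hk;
* *allelic dropout*: a het is read as either hom equiprobably; a hit on
  a true homozygote changes nothing and therefore never flags —
  d = 0.25 for lm×ll/nn×np, 0 elsewhere.

The **adjusted rate** divides the raw rate by the checked-call-weighted
mean detectable fraction and is an unbiased estimator of the error
process's hit rate under either model (undefined when the weighted
fraction is 0, e.g. an all-hk×hk cross). Singletons (inconsistent at
exactly one offspring) are counted but not excluded — an assay-scale
rate estimate should include them. aa×bb markers are included in error
estimation but excluded from the CP mapping export, which covers lm×ll
and nn×np only (JoinMap-style plain text). Both raw and adjusted rates
are always reported, since published "error rates" rarely state whether
they were detectability-corrected.

Segregation distortion tests the 1:1 split of the two producible
classes of lm×ll / nn×np markers (chi-square GOF, df = 1, flag at
p ≤ 0.05). Identical loci (pairwise genotype identity over
pairwise-complete samples strictly above 0.95, single linkage) collapse
to the least-missing member, ties to the lowest position.

## Simulator

The generator emulates the data shapes of a targeted-genotyping study
at desk scale; defaults chosen once and kept: 2 chromosomes × 500 kb,
2,000 sites, 128 samples, alt frequencies Beta(1.5, 1.5) clipped to
[0.01, 0.99] (folded-MAF mean ≈ 0.3, a common-variant diversity panel),
missingness 10⁻⁴ (the near-zero missing-data regime of a deep targeted
assay), 100 cM per chromosome, inbreeding F = 0. Founder genotypes use
inbreeding-adjusted Hardy–Weinberg (p² + Fpq, 2pq(1−F), q² + Fpq).
Gametes follow a Haldane crossover process — Poisson crossover count on
the chromosome's cM length, uniform positions, no interference — chosen
over Kosambi as the simpler null; a Kosambi→Haldane conversion utility
is provided but the simulator itself is Haldane. Error injection hits
each call independently at the configured rate under the named model,
then masks missingness independently, recording hit/changed/masked
truth masks. All randomness flows from one explicit seed through
spawned child generators; no global RNG state.

What the simulator does **not** model: linkage disequilibrium between
founder sites (sites are drawn independently, so population LD
structure, selection and demography are absent), read-level error
processes (depth-dependent miscalls, allele-specific bias, reference
bias), index hopping or sample contamination, and structural variation.
Passing recovery tests therefore demonstrates the estimator's
correctness under its stated model, not robustness to every real-assay
artefact; in particular the uniform-swap model treats all genotype
transitions as equally likely, which real callers do not.

The validation experiment for the error estimator uses 8 chromosomes ×
3 Mb, 20,000 markers, 150 offspring and an injected rate of 1.8% —
about 3 × 10⁶ checked calls, sized so the Monte-Carlo standard error of
the adjusted estimate (< 0.01 percentage points) is far below the
±0.2-point acceptance band while completing in seconds. Errors are
injected into offspring calls only: the quantity under study is the
assay's per-call error rate as seen through progeny inconsistencies,
and clean parents keep CP-class assignment exact; parent miscalls
would misattribute classes (e.g. hk×hk read as lm×ll) and are a
separate failure mode outside this estimator's model.

## Numerical and degenerate-input choices

All-missing sites raise in single-site statistics and yield NaN in
vectorised tables; r² with fewer than two shared calls or a constant
vector is NaN and never flags a pruning pair; spectrum correlation
requires ≥ 3 shared sites; distortion tests require a non-zero count
and reject classes other than lm×ll/nn×np. Chi-square p-values from
discrete counts live on a lattice, so calibration checks compare
against the exact enumerated null distribution rather than a
continuous uniform. Panel TSVs store floats at 17 significant digits so
read(write(panel)) is exact.

## Known limitations

* The identical-locus collapse is O(n²) in marker count — adequate for
  mapping-scale marker sets, not for whole-genome call sets.
* The CP export covers single-parent-informative markers only; hk×hk
  phasing for mapping is out of scope.
* Gene models in the simulated annotation are simple three-exon genes;
  alternative isoforms and overlapping genes are not generated, though
  the annotation index handles overlaps with UTR > exon > intron
  precedence (configurable, since separate UTR accounting is a
  reporting convention rather than a biological necessity).
* Chromosome names are opaque labels sorted lexicographically; no
  linkage-group renaming or liftover is attempted.
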
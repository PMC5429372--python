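# hwescan

Genome-wide Hardy–Weinberg equilibrium (HWE) quality control for
sequencing-based genotype data: exact autosomal and X-chromosomal tests
with mid *p*-values, variant filtering, annotation-stratified
disequilibrium summaries, horizontal-band detection, and a synthetic
genome generator that emulates the genotyping-error mechanisms known to
produce disequilibrium.

## The problem

Under random mating, a bi-allelic marker with allele frequencies *p* and
*q* shows genotypes AA, AB and BB at frequencies *p*², 2*pq* and *q*².
Departures from these proportions in a population sample — Hardy–Weinberg
disequilibrium (HWD) — are routinely used to flag genotyping problems.
In next-generation sequence data, two artifact classes dominate:

- **null alleles** (un-assayed third alleles) misclassify carriers as
  homozygotes, producing a *deficiency* of heterozygotes (inbreeding
  coefficient *f* > 0), reduced read depth and extra missing calls;
- **collapsed segmental duplications** merge two paralogous polymorphisms
  into one call, producing an *excess* of heterozygotes (*f* < 0) and
  roughly doubled read depth — in the extreme, paralogs fixed for
  different alleles yield 100% heterozygosity.

`hwescan` is for people doing variant-level QC who want to *diagnose*
disequilibrium rather than silently discard significant markers: it
stratifies HWD rates by chromosome, missingness, read-depth decile and
segmental-duplication / tandem-repeat annotation, and detects "horizontal
bands" of variants that share one genotypic composition because two
haplotypes explain every individual.

## The tests

For an autosomal marker, conditional on the observed minor-allele count
*n*<sub>A</sub>, the heterozygote count *N*<sub>AB</sub> is
parameter-free under HWE (the Levene–Haldane distribution):

```
P(N_AB = n_AB | N_A = n_A) = n_A! n_B! n! 2^{n_AB} / (n_AA! n_AB! n_BB! (2n)!)
```

The two-sided exact *p*-value sums the probabilities of all outcomes no
more probable than the observed one.  Because the support is discrete,
this test is conservative; `hwescan` therefore reports the **mid
*p*-value** — half the probability of the observed outcome plus the
probabilities of all strictly less probable outcomes — which has
expectation exactly 0.5 under the null and rejection rates close to the
nominal level.

For X-chromosomal markers, hemizygous males are not discarded: an omnibus
exact test evaluates HWE in females *jointly* with equality of male and
female allele frequencies, through the joint null distribution of (number
of A males, number of heterozygous females) given the allele count:

```
P(M_A, F_AB | n, n_A, n_m) = n_A! n_B! n_m! n_f! 2^{f_AB} / (m_A! m_B! f_AA! f_AB! f_BB! n_t!)
```

with *n*<sub>t</sub> = 2*n*<sub>f</sub> + *n*<sub>m</sub> total alleles.
With no males it reduces exactly to the autosomal test.  Variants in the
pseudo-autosomal regions PAR1/PAR2 (diploid in both sexes) are tested
autosomally.  The heterozygote balance is summarized by the inbreeding
coefficient *f* = 1 − H<sub>obs</sub>/H<sub>exp</sub>.

## Worked example

Library level — the heterozygote-deficient composition (AA=97, AB=4,
BB=3) seen in a 104-individual sample:

```python
>>> from hwescan import GenotypeCounts, hwe_core
>>> counts = GenotypeCounts(n_aa=3, n_ab=4, n_bb=97)   # minor-allele oriented
>>> res = hwe_core.test_autosomal(counts)
>>> res.p_std, res.p_mid, res.f
(0.00035750061850419883, 0.00018010926742249194, 0.5797979797979798)
```

The standard exact *p* is 3.6e-4, the mid *p* 1.8e-4 — significant at the
HapMap exclusion level α = 0.001 — and *f* = 0.58 indicates a strong
heterozygote deficiency at minor allele frequency 0.048.

Command line — simulate a genome (104 individuals: 56 males, 48 females;
85% monomorphic baseline; null-allele, collapsed-duplication,
fixed-divergent and two-haplotype-band blocks) and scan it:

```sh
$ hwescan simulate --out sim --seed 1 --scale 0.1
wrote 5136 variants for 104 samples
$ hwescan scan --vcf sim/data.vcf --sex sim/sex.tsv \
    --segdup sim/segdup.bed --repeats sim/repeats.bed --out scan
retained 5127/5136 variants; results in scan
```

`scan/chromosome_summary.tsv` then contains (excerpt):

```
    scope  n_variants  pct_monomorphic  pct_significant  pct_het_excess  median_f  median_dp
     chr2        1221        86.486486         5.454545        0.000000 -0.019608    17824.0
     chr3        1230        85.528455        16.853933      100.000000 -0.024631    17905.5
autosomes        4627        85.022693        11.832612       48.780488 -0.014778    17920.0
```

chr2 carries the planted null-allele block (all its significant variants
have *f* > 0, heterozygote deficiency), chr3 the collapsed-duplication
block (100% of significant variants are heterozygote excess).
`pct_significant` is computed among polymorphic variants only and
`fold_enrichment` divides it by the chance expectation 100·α.
`hwescan bands` and `hwescan plot manhattan|track|qq|missingness|depth|strata`
work from the same outputs; every figure also emits its underlying frame
as TSV.

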
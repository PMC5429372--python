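# Methods

## Exact tests

**Autosomal.** Conditional on the minor-allele count, the heterozygote
count of a bi-allelic marker under HWE follows the parameter-free
Levene–Haldane distribution.  All probabilities are evaluated in
log-factorial space (`scipy.special.gammaln`) and exponentiated at the
end, so sample sizes in the thousands neither overflow nor lose
precision; per-(n, n_A) tables are memoised, which makes a genome scan
over a fixed cohort cost one table per distinct allele count.

**Two-sidedness and ties.** The test is two-sided by probability
ordering: the standard p-value sums all outcomes whose probability does
not exceed the observed outcome's.  Outcomes whose probabilities differ
by less than a relative 1e-12 are treated as tied; ties enter the
standard p at full weight and the mid p at half weight, with the observed
outcome a member of its own tie set.  This is the unique convention under
which the mid p-value has expectation exactly 0.5 under the null — a
property the tests verify by full enumeration to 1e-10.

**X chromosome.** The omnibus test uses the joint conditional
distribution of (A-carrying males, heterozygous females) given the allele
count, simultaneously testing female HWE and male/female allele-frequency
equality.  With no males the distribution reduces algebraically to the
autosomal one, which is asserted for every female configuration up to
n_f = 30.  Variants inside the hg19 pseudo-autosomal regions
(X:60,001–2,699,520 and X:154,931,044–155,260,560, stored 0-based
half-open and overridable in `ScanConfig`) are diploid in both sexes and
tested autosomally.

**Minor-allele convention.** The "A" allele is the minor allele; at exact
ties the ALT allele is designated minor.  Both exact tests are symmetric
in the alleles, so the choice cannot affect p-values (asserted).

**Inbreeding coefficient.** f = 1 − H_obs/H_exp with
H_exp = 2·p̂·(1−p̂) at the sample allele frequency.  The plain ratio
estimator is used, without a 2n/(2n−1) small-sample correction — a
documented convention; f only ranks and colors variants here, it enters
no test statistic.  f < 0 means heterozygote excess.  For X variants f is
computed from the females only (hemizygotes carry no heterozygosity) and
is undefined when the females are monomorphic.

**Monomorphic variants** are never tested; they are counted and labelled,
and all percentages of significant variants are computed among
polymorphic variants only.

## Scan pipeline

Filtering drops, in order: variants without an RS identifier; all
variants sharing a duplicated identifier; all variants sharing one
(chrom, pos) — dropping *all* rather than all-but-one is the symmetric,
conservative reading when provenance cannot break the tie; and variants
with a missing-call fraction strictly above 5% (exactly 5% is retained).
Each variant is counted under the first rule that hits it.  The
missingness-bin summary is meant to be run on a scan *without* the 5%
filter, so both orders of that analysis are available.

Coordinates follow BED conventions: tracks are half-open 0-based, the
1-based VCF position is converted by pos−1, so a variant at an interval's
first base is inside and one at its end coordinate is outside.
Multi-allelic and non-SNV records are skipped (counted, never split —
splitting would change allele counts).  Male X heterozygous diploid calls
have no defensible interpretation and are set missing with a diagnostics
counter; male homozygous diploid X calls are accepted as hemizygous, the
common convention in population reference panels.

Summaries: per-chromosome (plus autosome-wide and genome-wide) rows
report variant count, % monomorphic, % significant among polymorphic at
α (default 0.001, the classical HapMap exclusion level), % of significant
variants with f < 0, medians of f and total read depth, and the
fold-enrichment %sig/(100α).  Region, missingness-bin (default width 2%),
depth-decile and annotation-strata summaries restrict or partition the
same quantities; strata always partition their parent scope exactly
(asserted).  The α sweep reports the share of significant variants inside
the union of the annotation tracks over a log-spaced grid, default
10⁻² … 10⁻¹² in 21 points.

## Band detection

Variants are grouped by minor-oriented genotypic composition
(n_AA, n_AB, n_BB); groups are segmented greedily so a band spans at most
1 Mb (configurable) and reported when they have ≥ 10 members (default).
Members need not be contiguous — interleaved monomorphic or
different-composition variants are ignored, and the grouping is invariant
to REF/ALT labelling.  A band is flagged *vector-identical* when all
members carry the same per-sample genotype vector up to global allele
relabelling.

The two-haplotype check is exact rather than EM-based: haplotypes h1, h2
explain a genotype matrix iff every individual's row equals h1+h1, h1+h2
or h2+h2.  Fully homozygous rows pin haplotypes directly (more than two
distinct ones is an immediate failure); all rows containing a
heterozygous call must share a single dosage pattern equal to h1+h2.
When every individual is heterozygous everywhere, two haplotypes exist
but the phase is ambiguous; the check returns a complementary pair.  A
single-variant matrix is trivially consistent (warned), and rows with
missing entries are excluded with a log message.

## Synthetic genome generator

The generator emulates the study conditions the scan is designed for:
104 individuals (56 males, 48 females), an 85% monomorphic baseline
fraction, and per-variant total read depth (INFO DP, summed over samples)
drawn from a negative binomial with mean 18,000 — the scale of observed
per-chromosome medians in deep catalogues — and dispersion 100, scaled by
the called fraction and by mechanism multipliers.  The folded MAF
spectrum of polymorphic baseline variants is 0.5·Beta(0.5, 2):
low-MAF-heavy, since no canonical spectrum exists for this purpose; it is
configurable.  Baseline missingness is 0.2% per call.

Mechanisms, each placed in a declared interval that is also emitted on
the segdup or repeat BED track:

- **null allele** (frequency r, default 0.2, at a locus with minor
  frequency 0.3): carriers typed homozygous, null/null typed missing,
  depth scaled by the fraction of non-null allele copies.  Expected
  called-genotype frequencies are (p²+2pr, 2pq, q²+2qr)/(1−r²), verified
  in closed form; median f̂ over such variants is positive.
- **collapsed duplication** (two paralogs, minor frequencies 0.3/0.3,
  independent): an individual is typed heterozygous whenever both alleles
  occur among its four copies; depth ×2.  Median f̂ negative.
- **fixed divergent duplication**: all individuals heterozygous, sample
  MAF exactly 0.5, the most significant variants in any scan; depth ×2.
- **band**: individuals are random pairs of two haplotypes differing at
  every member variant (or an exact planted composition, default
  (3, 4, 97) minor-oriented), giving vector-identical members interleaved
  with monomorphic filler.

An optional coupling draws per-variant missing rates uniformly up to a
configurable maximum and misclassifies heterozygotes with probability
proportional to the variant's missing rate, reproducing the qualitative
rise of %significant with missingness and its decline once sample-size
loss dominates.  It is off by default.

Variants are independent except inside band blocks; the generator does
not model genome-wide LD, population structure, relatedness, base-calling
error profiles or reads (no FASTQ/BAM).  Passing tests therefore
demonstrate that the scan recovers *these* planted mechanisms at this
sample size — not that real cohorts contain no other sources of
disequilibrium.

## Problem sizes and numerical choices

The full synthetic study used by the acceptance checks is four 50-Mb
autosomes plus an X with ~50k baseline variants and 300/300/60/329-variant
mechanism blocks, a size at which every mechanism's direction is
recovered with wide margins; unit tests use a 5% scale of the same
configuration.  The rejection-rate calibration uses 10,000 replicates at
n = 104, MAF 0.25.  pmf normalization is verified to 1e-10 up to n = 200
and against exact rational enumeration up to 8 individuals; p-value
plumbing writes full double precision because the analysis explicitly
cares about −log10 p in the range 10–30 and beyond.  All randomness flows
through one `numpy` Generator seeded from the CLI/config, making every
output byte-reproducible.

## Known limitations

- Exact tests only (no chi-square/likelihood-ratio/permutation variants,
  no Bayesian procedures, no multi-allelic tests).
- No FDR/q-value machinery: a fixed α and the Bonferroni line match the
  QC use case.
- Missing genotypes are excluded per variant, not imputed; with heavy
  missingness the conditional test can be biased, which is precisely why
  the pipeline filters at 5% and exposes the missingness-bin summary.
- BCF/gVCF/CRAM and genotype likelihoods are out of scope; the X
  reduction assumes the sex table is correct.
- The band scanner targets the two-haplotype case; general phasing with
  three or more haplotypes is detected only as a failure of consistency.
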
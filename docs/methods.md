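# Methods

## The detection model

A de novo mutation (DNM) is operationally a site where the proband's called
genotype contains the alternate allele while both parents are called
homozygous reference. A site with a missing parental genotype is never a
candidate: absence of a call cannot certify absence of the allele. The same
asymmetry drives two further conventions — a missing genotype quality fails
the quality criterion, and a parent sequenced to depth 0 fails the depth
criterion rather than counting as evidence of absence.

The four read-level criteria (depth ≥ 5 in proband and parents, GQ ≥ 10 in
all three, proband alt read fraction ≥ 10%, parental alt read fraction
≤ 10%) are evaluated independently so a report can show every failure at
once, and all boundaries are inclusive: the printed thresholds are
themselves passing values. Alt fractions are computed from the VCF AD
field. Multiallelic records are decomposed per alt allele, with the k-th AD
entry as that allele's alt depth; reads supporting other alt alleles count
toward total depth only. Coordinates are 1-based fully closed, as in VCF.
Sites on X/Y are processed with unchanged filters but flagged
non-autosomal; ploidy-aware male-X handling is deliberately out of scope.

### Confidence ranks

Passing candidates are ranked 1 (best) to 5 on a deterministic two-axis
grid. The quality axis grades the proband call: good requires GQ ≥ 50 and
alt fraction in [0.30, 0.70]; intermediate requires GQ ≥ 20; anything else
(including an implausible homozygous-alt de novo genotype) is poor. The
strand axis grades the phred-scaled two-tailed exact test on the
(ref, alt) × (forward, reverse) read table: ≤ 10 phred is unremarkable,
≤ 30 intermediate, beyond that poor; missing strand counts leave the axis
neutral. The grid maps (quality, strand) to ranks so that a worst strand
axis forces rank ≥ 4. The cutoffs are configurable; the grid preserves the
working structure of a curation workflow in which the top two ranks go
straight to orthogonal validation while ranks 3–5 are re-evaluated by a
logistic model trained on validation outcomes (probability ≥ 0.5 promotes
to rank 2). The model's features are the strand-bias phred score, the
proband GQ (doubling as the base-quality proxy) and the proband alt
fraction.

### Mosaic flag

A post-zygotic mutation is carried by a subset of cells and shows a
depressed alt fraction. The flag uses a half-open band [0.10, 0.30) —
below it the site fails the detection filters anyway; at 0.30 and above a
germline heterozygote becomes the more parsimonious reading. The band is a
package default (configurable), chosen to sit between the detection floor
and the lower tail of the binomial spread of a 50% heterozygote at ~46×.

### Consequence classes

Raw annotation strings map to classes: nonsense/stop-gain, frameshift and
splice-site (exon ± 2 bp) changes are loss-of-function; nonsynonymous SNVs
are missense; length-preserving coding indels are in-frame; synonymous SNVs
are synonymous; unrecognized strings fall to "other" with a warning. The
rare-variant filter excludes a variant only when some population database
reports a frequency strictly above the threshold (default 0.01); variants
with no database entry are by construction rare.

## Rate statistics

Per-trio DNM counts are modelled as Poisson with λ̂ the full-precision
cohort mean (also reported rounded to one decimal, the field's convention).

**Goodness of fit.** The KS statistic against Poisson(λ) is evaluated on
the integer support: both the empirical and the null CDF are step functions
with jumps only at integers, so sup|ECDF − F| over the real line is
attained there. A continuous-null KS implementation instead compares
F(x) with ECDF(x⁻) and overstates the discrepancy badly on tied counts
(on the reference cohort it reports p ≈ 0.02 where the support-evaluated
statistic gives p ≈ 0.9). The p-value uses the exact finite-n distribution
(scipy `kstwo`) for n ≤ 30 and the asymptotic Kolmogorov law otherwise;
for a discrete null either is conservative. Both λ variants (full-precision
mean and rounded) are reported, plus a chi-square goodness of fit (cells
pooled from the right to expected ≥ 1, one estimated parameter) as a
cross-check.

**Cohort comparisons.** Comparing event rates between two trio cohorts of
unequal size uses the exact conditional construction: given m total events,
under the null each falls in the case cohort with probability
π₀ = n_case/(n_case + n_ref), and the reported p is the inclusive upper
tail P(X ≥ k_case | m, π₀). This is the standard exact rate-ratio
comparison; it reproduces the published comparisons (8/24 vs 4/54 → 0.011;
8/24 vs 54/677 → 0.001) to the printed precision. m = 0 returns p = 1.

**Per-gene over-representation.** Primary mode: exact Poisson upper tail
P(X ≥ observed) at rate n_trios·μ_g, with μ_g from a sequence-context
expected-rate table; the result carries the observed per-trio rate. A gene
absent from the table yields an explicit absent result, never p = 0. A
secondary Fisher mode tests the 2×2 table
[observed, n−observed; round(n·μ), n−round(n·μ)]; the rounding makes it
approximate, and it exists only as a cross-check.

## Burden and meta-analysis

Collapsing is at the carrier level: a sample carries a gene iff it has
dosage ≥ 1 at any of the gene's rare damaging variants; missing dosages are
non-carrying. The per-study test is the asymptotic 1-df chi-square
(ad−bc)²N/(r₁r₂c₁c₂) on the carrier 2×2 table, no continuity correction by
default (a Yates flag exists). Zero-margin tables carry no information and
return p = 1, direction 0. Direction is the sign of the case−control
carrier-rate difference.

Meta-analysis is the sample-size-weighted Z-score method: per study
z_i = Φ⁻¹(1 − p_i/2)·direction_i, weights w_i = √n_i,
Z = Σw_i z_i / √Σw_i², two-sided combined p. With equal weights this is
Stouffer's method; a single study returns its own p exactly. Per-gene
results are reported uncorrected (a Bonferroni column is appended for
convenience only).

## CNV and ROH rules

Calling is purely threshold-based, honoring the printed rule parameters;
no segmentation model is fitted. A probe qualifies for loss at
LRR ≤ −0.2 and for gain at LRR ≥ +0.15. Maximal runs of qualifying probes
are built left to right, tolerating up to `gap_probes` (default 1)
interior sub-threshold probes per run, each immediately followed by a
qualifying probe. A run is emitted when (a) the run's mean LRR itself
satisfies the threshold (with a 10⁻⁹ tolerance so exact-boundary data are
inclusive), and (b) the required number of qualifying probes (5 for loss,
7 for gain) occurs within the rule's window (150 kb / 200 kb) inside the
run. The run construction itself is this package's own design — the
printed thresholds originate as settings of a GUI product whose
segmentation semantics are proprietary — and every piece of it is
configurable. Loss and gain calls cannot overlap; the larger |mean LRR|
wins a pathological clash.

ROH: probes are homozygous by genotype (AA/BB) or by BAF (≤ 0.05 or
≥ 0.95, defaults), heterozygous by AB or intermediate BAF; probes
informative by neither channel extend runs without counting. Maximal
het-free stretches are merged across interior hets while the merged span
tolerates ⌊span_Mb · 1⌋ hets (at least one). Runs spanning ≥ 2 Mb are
emitted. Output files are BED-like (0-based half-open), converted from the
1-based closed internal convention.

## The synthetic cohort

The generator emulates the study conditions the statistics assume, not raw
sequencing: 24 trios; DNM count per proband ~ Poisson(1.2); 6.5% of DNMs
post-zygotic with true alt fraction uniform on [0.08, 0.30]; per-genotype
depth negative-binomial with mean 46 and size 8 (sd ≈ 18, matching an
observed per-sample 18–74× spread); alt reads binomial at the genotype's
true fraction; GQ is the phred ratio of the emitted genotype's binomial
read likelihood to its best competitor (base error 0.005, capped at 99).
Inherited sites draw a population MAF from Beta(0.2, 2) clipped to
[10⁻⁴, 0.5], parents at Hardy–Weinberg, the child by Mendelian
transmission. The exome is abstracted as (gene, site) slots with synthetic
symbols.

Emitted genotypes are the *true* genotypes with likelihood-derived GQ, not
re-called from the reads; caller noise is opt-in via `genotyping_error`
(default 0), which replaces a genotype with a random different one.
Consequently inherited sites are exactly Mendelian by default and detection
specificity on them is 1. What the generator deliberately does not model:
alignment artifacts, capture bias, indel realignment, multiallelic sites,
and real gene lengths — so passing round-trip tests demonstrates the
correctness and calibration of the statistical pipeline under its own
assumptions, not robustness to real-data artifacts.

Under these conditions detection sensitivity is ≈ 0.98: non-mosaic DNMs
are essentially always recovered, while a mosaic with true fraction near
the bottom of its band legitimately fails the ≥ 10% alt-fraction or GQ
criterion (mosaic-only sensitivity ≈ 0.67). The fitted rate from detected
calls is therefore biased low by ≈ 2–3%; rate-recovery calibration is
asserted on the generator's truth counts (the estimator property), and the
detected-rate bias is reported alongside.

The burden generator plants per-gene case enrichment as an odds multiplier
on the per-variant carrier probability, chosen so the gene-level carrier
probability in controls equals the configured baseline (default 0.05,
cohort sizes default 48/212). The array generator writes a 200-probe track
at 20-kb spacing (a 4-Mb focused region): a pre-implementation Monte Carlo
of the rule set under Gaussian LRR noise (σ = 0.15) showed the false-call
probability per null track grows roughly linearly with track length
(≈ 1.4% at 500 probes, ≈ 3.6% at 1000), and 200 probes keeps it near 0.5%,
comfortably inside the ≤ 1% design property while still hosting a > 2-Mb
ROH. Planted losses shift LRR and remove heterozygosity; gains shift het
BAF toward 1/3 and 2/3; ROHs are homozygous with neutral LRR.

## Problem sizes and numerics

Full-scale properties run at 200 replicate cohorts (24 trios, 300
inherited sites each), 200 planted-CNV tracks, 3,000 null tracks, and
2,000 burden null replicates — sizes at which every Monte Carlo assertion
has at least a 2-σ margin to its bound. Ties in the confidence grid and
the cross-kind CNV clash are broken deterministically; study p-values are
floored at 10⁻³⁰⁰ before the probit; the Poisson tail is floored at the
smallest positive double. All generators are `numpy.random.default_rng`
seeded; identical (config, seed) reproduce byte-identical output files.

## Known limitations

The five-rank scheme's exact published cutoffs are not public; the grid
here preserves its structure, not its letter. The binomial cohort
comparison is one defensible exact construction among several; the
conditional form was chosen and is stated prominently wherever its numbers
are shown. The CMC test is the carrier-collapse + chi-square form; the
original multivariate variant, covariate adjustment, and kernel-type tests
are out of scope, as are HMM/CBS CNV segmentation, intensity
normalization, and trio-aware de novo CNV inference.
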
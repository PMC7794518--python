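# Methods

## Scope and data model

The package analyzes targeted-panel sequencing of three compartments per
patient: plasma cell-free DNA (cfDNA), tumor tissue, and leukocyte
germline DNA (gDNA). Inputs are per-sample variant tables (TSV dialect or
VCF 4.2) carrying read counts, mean mapping quality and mean read-end
distance of mutation-supporting reads, per-sample depth histograms,
per-gene normalized coverages, and a cohort manifest. All downstream
statistics operate on these summaries; alignment, deduplication and
pileup generation are upstream of this package.

## Somatic filtering

Targeted-panel calls require, jointly:

| rule | threshold | note |
|---|---|---|
| mutant reads | ≥ 8 | absolute support floor |
| VAF floor | ≥ 1% cfDNA, ≥ 8% tissue | tissue is noisier (FFPE) |
| germline ratio | VAF > 3 × gDNA VAF | gDNA VAF taken as 0 when no alt reads |
| mapping quality | mean over supporting reads > 30 | strict inequality; a tie fails |
| read-end proximity | mean distance > 25 bp | strict inequality; a tie fails |

When the gDNA has no coverage at the locus the ratio rule passes with a
`GDNA_NO_COVERAGE` warning rather than failing: the germline contrast is
applied only where germline data exists. An optional per-site background
test (one-sided binomial against a configurable error rate, default 0.1%,
α = 0.01) is available but disabled by default, because the magnitude of
the panel's background error is a free parameter of the assay rather than
a fixed constant; enabling it can only remove calls.

CHIP handling is two-layered: the 3× ratio removes most clonal
hematopoiesis, and variants in a configurable CHIP gene list (default
DNMT3A, TET2, ASXL1) with ≥ 1 gDNA alt read are flagged
`CHIP_GENE_REVIEW`. The flag is advisory by default (mirroring a manual
review step) and exclusionary in strict mode.

WES silent-mutation rules: VAF ≥ 10%, ≥ 50× the same-locus background
rate, ≥ 10× the matched-normal VAF, plus the two quality gates.

## Tumor fraction

The estimator inverts the expected VAF of a truncal mutation under
loss of heterozygosity. With tumor fraction `tf`, a clonal mutation on the
single remaining allele has VAF = tf / (2 − tf); solving for `tf` gives
TF = 2·VAF/(1+VAF). LOH is assumed deliberately: among the candidate
states (het diploid → TF = 2·VAF·... larger; LOH → smallest TF consistent
with the VAF is *not* the case — LOH yields the **largest** VAF per unit
tumor fraction, hence the smallest, i.e. conservative, TF estimate).

Stochastic read sampling is damped by replacing the observed top VAF with
the one-sided lower 95% confidence bound of the binomial proportion
(exact inversion: the largest p with P(X ≥ k | Bin(n, p)) ≤ 0.05,
computed via the Beta(k, n−k+1) quantile identity). The bound is applied
per selected variant without a multiplicity correction for "max of m
mutations"; a stricter quantile can be passed for sensitivity analysis.

Eligibility excludes chromosome 9 (frequent copy-neutral LOH), the TERT
promoter (systematically low depth), amplified regions (VAF inflated by
mutant-allele copy gain), sex chromosomes and mitochondrial contigs. Ties
at the maximum VAF break deterministically to the lowest
(chrom, pos, alt). Detection is declared at TF > 1%; a sample is
"evaluable" if at least one protein-altering mutation survives filtering.
Subclonality is VAF < 25% of TF (strict), on raw VAFs; purity-normalized
VAF ratios above 1 are reported with an amplification flag rather than
truncated.

## TMB

TMB = 1e6 · Σ 1/B_m over kept protein-altering mutations (silent calls
includable by flag for WES inputs), with B_m the number of panel sites at
depth ≥ ⌈8/VAF_m⌉. The required depth uses the *observed* VAF because
detectability depends on the observed allele fraction, not the
purity-normalized one. The ceiling is computed as ⌈8/v − 1e−9⌉ so that
count-derived VAFs (v = 8/d) reproduce d exactly despite float rounding.
Mutations whose required depth exceeds the deepest histogram bin have
B_m = 0, cannot be extrapolated, and are excluded with a report entry.
The estimator is scale-invariant in the footprint and reduces to
count/footprint·1e6 under uniform adequate coverage.

## Copy number

Observed normalized coverage is modeled as the two-population mixture
ratio = (tf·CN + 2(1−tf))/2, the standard purity correction; it keeps
high-level amplifications visible at low tumor fractions. Gene log2
ratios are taken against the per-gene geometric mean of baseline samples
(gDNA plus any tumor sample estimated at TF = 0; at least three
required). Confidence intervals are computed on the log-ratio scale
(± z₀.₉₇₅ × per-gene baseline SD) and transformed through the
copy-number formula — the log scale is where coverage noise is
approximately Gaussian and guarantees a positive interval before the
floor at 0 copies. Amplification is called at ≥ 5 copies (boundary
inclusive, configurable); there is no segment-level or subclonal copy
number modeling.

## Concordance

Pairing rule: per patient, the evaluable cfDNA sample with the highest
tumor fraction and the most recent evaluable tissue sample; ties resolve
by sample id. Variant identity is exact (chrom, pos, ref, alt) — no fuzzy
indel matching, so the accounting is strictly auditable. An exclusive
call is "coverage explained" when the paired sample shows ≥ 3 mutant
reads at the locus (deeper sequencing could plausibly have called it);
loci absent from the paired sample's table are reported unknown, not
false. Depth sufficiency for truncal detection uses expected mutant reads
depth·tf/2 ≥ 8 under the diploid-heterozygous truncal VAF tf/2.

Per-variant clonality within a pair is classified in the detecting sample
with the higher tumor fraction (the more reliable normalization); the
resulting subclonal/clonal × shared/not-shared 2×2 table is tested with a
two-sided Fisher exact test. The test sums hypergeometric probabilities
of all tables no more likely than the observed one, with probabilities
compared as exact rationals (`fractions.Fraction`), eliminating floating
tie ambiguity; it matches an independent enumeration oracle exactly and
mainstream float implementations to ~1e−9. Degenerate stratified tables
(an empty row or column) are reported as not applicable rather than
tested. Serial concordance is |intersection| / |union| of call sets
across ≥ 2 same-compartment samples; it is order-invariant and bounded by
the minimum pairwise sharing fraction.

## Synthetic cohort generator

The generator emulates the paired-compartment study design: per patient
one gDNA sample, `serial_timepoints` cfDNA and tissue samples; mean
unique depths 1040× (cfDNA), 370× (tissue), 300× (gDNA) with per-site
negative-binomial dispersion (size 10) to make the TMB depth correction
non-trivial. Plasma tumor fractions are drawn log-uniform on
[0.005, 0.6] — giving the right-skewed distribution (median a few
percent) typical of metastatic cohorts — and tissue purities on
[0.05, 0.9]; serial tumor fractions jitter log-normally (σ = 0.4) around
the baseline draw.

Clonal structure is a star tree: a truncal clone at CCF 1 in every
tumor-bearing sample plus up to three subclones with uniform base CCFs,
each subclone optionally restricted to one compartment
(`subclone_private_prob`, default 0.35, which makes subclonal sharing
lower than clonal sharing by construction) and optionally dropped at
later timepoints (`drift_prob`, default 0.5) in the drift compartments
(default tissue only, emulating re-biopsies of different tumor foci
against plasma's integrated sampling). Half of truncal mutations sit on
one-copy LOH loci (total = mutant = 1) so that the LOH assumption of the
TF estimator is exactly satisfied for the top VAF; the rest are
diploid-heterozygous. Mutations on configured amplified genes carry
mutant multiplicity CN−1, exercising the amplified-region exclusion.

Confounders: ~10 germline heterozygous variants per patient (true VAF 0.5
in every compartment), 2 CHIP variants (VAF uniform on [0.5%, 5%],
correlated between gDNA and cfDNA, absent from tissue), and
Poisson-distributed FFPE-like artifacts per tissue sample (VAF uniform on
[0.5%, 5%], mean read-end distance drawn in [4, 15] bp so the proximity
gate is the rule that removes them). Loci absent from a sample's truth
still receive binomial read support at a background error rate (default
5e−4), so matched-sample pileup queries behave realistically. Read counts
are binomial in the true VAF throughout; per-site error profiles,
fragment-length biology and UMI behavior are *not* modeled, so passing
tests demonstrate estimator correctness under the stated sampling model,
not robustness to real error modes.

Every emitted sample reports all of the patient's truth loci (alt reads
possibly 0), which is what makes coverage-explained queries answerable
from the written files. One global seed drives the cohort;
per-patient streams are spawned from it, making cohorts byte-reproducible.

## Problem sizes and numerical choices

Unit and property tests run the generator with reduced panel footprints
(2–20 kb instead of the 300 kb default) and 1–3 patients, sizes at which
every statistic is exercised end-to-end; calibration suites use 100–500
replicates (TF recovery: 200 cohorts per true TF; CI coverage: 500
replicates; TMB density: 100 replicates), which bound Monte-Carlo error
well inside the asserted tolerances. Filters use strict inequalities at
the 30/25 quality boundaries. The Fisher test and the binomial lower
bound are exact; everything else is float with explicit tolerances in the
tests.

## Known limitations

- The generator's clone CCFs are drawn independently per sample given the
  star tree; sibling CCFs may sum above the parent's, which real
  phylogenies forbid but no downstream statistic here depends on.
- Tumor-fraction estimation assumes at least one truncal LOH-like
  mutation dominates the VAF distribution; in tumors without LOH at any
  panel gene the estimate is biased low (by design, conservatively).
- Copy-number CIs assume log-normal coverage noise shared between
  baseline and tumor samples; GC/size normalization must happen upstream.
- The WES silent-mutation path filters observations but there is no
  exome-scale simulator; it is exercised on constructed cases only.
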
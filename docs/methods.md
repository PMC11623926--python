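# Methods

This note documents the models behind `chipcall`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer should know about.

## CHIP calling model

The unit of analysis is one candidate somatic variant in one sample,
carrying read evidence (total depth, alt-supporting depth, per-strand
alt-supporting read pairs), population annotation (gnomAD global allele
frequency, COSMIC recurrence count), a protein consequence, and the ±6 bp
reference context. The cascade evaluates seven criteria on every record
without short-circuiting, so rejected records retain a complete
per-criterion audit; a call passes iff all flags pass.

Interpretation choices that the criteria leave open:

- **Depth is total site depth**, not alt-read depth. A panel with median
  ~600× cannot yield 500 alt reads at VAF ≤ 35%, so the >500× bound only
  makes sense on site depth. The bound is strict (a site at exactly 500×
  fails), as are the population-frequency and cohort-recurrence bounds;
  the VAF range endpoints (2%, 35%) are inclusive.
- **VAF is computed as an exact rational** (`Fraction(alt, total)`) and
  the range endpoints are parsed as decimals, so a clone at exactly
  12/600 = 2% passes; no binary-float boundary leakage.
- **Homopolymer signature** means a run of ≥ 4 identical bases within the
  6 bp immediately flanking the variant on either side. Four is the
  conventional run length at which indel/slippage artifacts concentrate;
  it is configurable (`homopolymer_min_run`) because the definition is a
  package decision, not an established constant. `N` bases never extend a
  run, and runs do not bridge the variant position.
- **Cohort recurrence** is a panel-of-normals-style filter: the identical
  chrom:pos:ref:alt seen in ≥ 5% of all processed samples is treated as a
  systematic artifact or germline leakage. The denominator is the full
  run, which is why the cascade requires all samples' records together.
  The 5% bound compares exact rationals (5/100 fails, 4/100 passes).
- **Unknown consequence terms fail closed** (not protein-altering) with a
  warning, so a typo in upstream annotation cannot admit a call.
- Duplicate (sample, variant) records collapse to the highest-alt-depth
  one before filtering; output order is canonical (sample, then locus),
  making the cascade order-independent by construction.

CHIP-PD classification consults a driver catalog TSV
(gene, protein-change prefix pattern, recurrence count, predefined flag).
A passing call is CHIP-PD when its best-matching entry has recurrence
count strictly greater than 10 or is flagged predefined; pattern matching
is by HGVS.p prefix so `p.Arg882` covers `p.Arg882His/Cys`. The bundled
catalog seeds canonical CHIP hotspots (DNMT3A R882, JAK2 V617F, SF3B1
K700E, SRSF2 P95, PPM1D truncations, ASXL1 G646fs, …) and is meant to be
replaced or extended by the user; curation of driver lists is outside the
package. Manual read-level (IGV-style) review is represented only by a
`needs_review` flag on passing calls.

## Burden and prevalence statistics

Burden categories: `negative` (no passing call), `chip`, `high_burden`
(max clone VAF strictly > 10%; a clone at exactly 10% is `chip`). The
three categories partition any cohort.

The two-group prevalence comparison uses the conditional exact test on
the 2×2 table (hypergeometric null, minimum-likelihood two-sided rule;
`scipy.stats.fisher_exact` provides the computation and the test suite
checks it against full enumeration). The reported odds ratio is the
sample OR (ad)/(bc) with explicit infinity/NaN flags for degenerate
margins. Age adjustment uses plain maximum-likelihood logistic
regression (Newton/IRLS, tolerance 1e-8, ≤ 100 iterations) — no
penalization, because a flagged complete separation is more transparent
than a silently shrunk estimate at cohort sizes of tens to hundreds;
separation is detected from the optimizer and from diverging
coefficients (|β| > 15 on standardized-scale covariates) and returned as
a flag, never an exception. Multiple comparisons within one run are BH
adjusted together. Pre/post-treatment VAF concordance inner-joins calls
on (sample, chrom, pos, ref, alt); variants present at one timepoint
only are reported as gained/lost and never imputed; correlations are
undefined (None) below 3 matched pairs.

## Exclusive-detection power

With per-carrier variant frequency *p* (e.g. 0.10 for the DNMT3A R882
share of DNMT3A CHIP), the conditional probability of detecting the
variant in at least one of *n* carriers — given it is absent from the
comparison group — is 1 − (1 − p)ⁿ, evaluated as `-expm1(n·log1p(-p))`
for stability at small *p*. `min_group_size` inverts this in closed form
and then verifies by direct evaluation at n and n−1, eliminating
floating ceil-off-by-one; `required_cohort_size` divides by gene-level
prevalence in exact integer arithmetic when prevalence is a count ratio
(16 carriers at 8/50 → exactly 100, never 101). The general engine is an
exact Poisson-binomial pmf by O(n²) iterative convolution, plus the
unconditional two-group exclusive-detection probability
P(≥1 in A)·P(0 in B) + P(0 in A)·P(≥1 in B). No normal approximations
are used anywhere; the n involved are small.

## AUC ranking and preranked GSEA

Within a cluster, each gene's AUC between two cell groups is
U/(n₁n₂) with midranks for ties — the probability that a random cell of
group 1 expresses the gene higher than a random cell of group 2, ties
counted half. Genes detected in < 5% of cells in both groups are
dropped (configurable; sparser genes carry almost no rank information
and inflate the multiple-testing burden). P-values come from the
Mann–Whitney test (exact for small tie-free samples, otherwise the
tie-corrected normal approximation with continuity correction; exhaustive
enumeration under ties is combinatorially infeasible and the AUC itself,
not the p-value, is the ranking metric). The preranked metric is the
centered AUC (auc − 0.5): centering makes the metric antisymmetric under
group swap, which the enrichment sign convention requires.

The enrichment score is the classical weighted Kolmogorov–Smirnov
statistic (weight exponent 1 by default): walking the ranking, in-set
genes add |score|ʷ normalized by the in-set total, out-of-set genes
subtract 1/(N−K); ES is the extremum of the larger excursion and the
leading edge is the in-set genes up to (ES > 0) or after (ES < 0) it.
The null permutes gene labels preserving set size — the appropriate null
for a single preranked list — rather than re-deriving rankings from
permuted sample labels. NES divides ES by the mean |null ES| of matching
sign; p = (1 + #{same-sign null at least as extreme})/(1 + #same-sign
null), floored and flagged when no null shares the sign; BH adjustment
spans the sets tested in one call. Defaults: ≥ 5 overlapping genes per
set, 1000 permutations. Per-cell group comparison (not pseudobulk) is
used; with hundreds of cells per group the AUC is estimated per cell,
which treats cells of one sample as independent — a known simplification
to keep the stage self-contained.

## Synthetic data: what it emulates, what it does not

The cohort generator reproduces the statistical structure the analysis
consumes, with defaults chosen as study conditions, not tuning knobs:

- ages Normal(64, 8) clipped to [35, 95] — an older solid-tumor cohort;
- CHIP incidence logistic in age, logit p = −5.32 + 0.08·age (≈ 45%
  at age 64 with a plausible age gradient — CHIP burden rises steeply
  with age, and that coupling is what the age-adjusted statistics must
  handle);
- clones per carrier: 1 + Poisson(0.9·e^{0.03(age−64)}) truncated at 4;
- gene assignment from a frequency table dominated by DNMT3A (30%),
  PPM1D (16%), TET2 (13%); 10% of DNMT3A clones are the R882 hotspot at
  a fixed locus (so hotspot recurrence across samples is exercised);
- clone VAFs log-normal (median 8%, σ = 0.7) truncated to [3%, 30%] —
  inside the filter's [2%, 35%] acceptance range so that sensitivity
  measures the cascade, not the truncation;
- site depths negative-binomial around 600× (panel) or 80× (WES),
  dispersion 500; reads Binomial(depth, VAF), strand split
  Binomial(alt, 0.5).

Artifact classes are planted with construction margins that trip their
targeted criterion in ≥ 99% of instances: homopolymer contexts carry a
5-base run; the gnomAD class sits at 10⁻⁴ (10× the threshold, no
COSMIC); the recurrent variant is planted in ~8% of samples; germline
leaks at true VAF 0.5; strand-biased artifacts split 98:2 at VAF ~5%
(a 95:5 split leaves a several-percent leak past the ≥ 4-pairs rule at
panel depth, defeating the class's purpose as a guaranteed negative
control). Not emulated: sequencing error, mapping bias, CNV-distorted
VAFs, tumor-derived contamination, clonal phylogenies — passing recovery
tests therefore demonstrates that the cascade implements its criteria
correctly, not that those criteria suffice on real data.

The expression generator draws negative-binomial counts (gamma-Poisson,
dispersion 2) over a 300-gene universe, two clusters, and multiplies the
planted 30-gene set's means by an effect factor only in the
myeloid-like cluster's high-burden cells. It does not emulate library
size variation, dropout structure beyond NB sparsity, batch effects, or
per-sample correlation of cells.

All generators are pure functions of (config, seed): the same seed gives
byte-identical files.

## Problem sizes and tolerances in the test suite

Recovery and calibration tests run at sizes where the checked property
has small Monte-Carlo error yet the suite stays fast: 300-sample cohorts
for cascade recovery (sensitivity bound 0.95 against a ≈ 99% expected
value), 1000 replicates of n = 150 for logistic null calibration (±3
binomial SE around 0.05), n = 2000 for coefficient recovery (±3 SE), 500
random sets × 200 permutations for GSEA null calibration, and 1000
permutations for the planted-pathway power check. Exact oracles
(Poisson-binomial enumeration at n ≤ 12, hypergeometric 2×2 enumeration,
pairwise AUC counting, the 12-gene hand-computed GSEA fixture) assert
equality to 1e-10 or better; float-free comparisons (VAF, recurrence
fractions) assert exact equality.

## Known limitations

- The cascade assumes annotation (gene, consequence, HGVS.p, gnomAD,
  COSMIC, context) arrives in the VCF; it never computes annotation.
- `write_chip_vcf` emits one sample per file because FILTER status is
  per (sample, variant); merged multi-sample output would lose audit
  flags.
- The gnomAD allele frequency round-trips through a String INFO field:
  htslib stores Float INFO as 32-bit, which would corrupt thresholds
  like 10⁻⁵ on re-read.
- The logistic separation heuristic (|β| > 15) is a pragmatic flag, not
  a formal test of separation.
- Per-cell GSEA inherits the pseudoreplication caveat above; treat
  cross-sample generalization claims with per-sample replication.
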